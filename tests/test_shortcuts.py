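import itertools

import pytest
from rdflib.plugins.sparql import prepareQuery

from sparqlpipe.errors import GenerationError
from sparqlpipe.fixtures import evaluate
from sparqlpipe.shortcuts import (ShortcutSpec, Term, build_query, classify_term,
                                  serialize_term)


@pytest.mark.parametrize("token,position,kind", [
    ("uniprot:P02649", "subject", "prefixed_name"),
    ("up:organism/up:scientificName", "predicate", "property_path"),
    ("up:organism|up:encodedBy", "predicate", "property_path"),
    ("rdfs:label", "predicate", "prefixed_name"),
    ("1", "subject", "column_ref"),
    ("42", "object", "column_ref"),
    ("^apolipoprotein", "object", "literal"),
    ("apolipoprotein E", "object", "literal"),
    ('"123"', "object", "literal"),
    ("<http://example.org/x>", "subject", "iri"),
    ("http://example.org/x", "subject", "iri"),
])
def test_classify_term(token, position, kind, prefixes):
    term = classify_term(token, position, prefixes)
    assert term.kind == kind
    if kind == "column_ref":
        assert term.column == int(token)


def test_undeclared_prefix_is_an_error_not_a_literal(prefixes):
    with pytest.raises(GenerationError, match="nopfx"):
        classify_term("nopfx:abc", "subject", prefixes)


def test_zero_is_not_a_valid_column(prefixes):
    with pytest.raises(GenerationError, match="1-based"):
        classify_term("0", "subject", prefixes)


def test_serialize_term(prefixes):
    assert serialize_term(Term("iri", "http://ex.org/a"), prefixes) == "<http://ex.org/a>"
    assert serialize_term(Term("prefixed_name", "rdfs:label"), prefixes) == "rdfs:label"
    assert serialize_term(Term("literal", 'say "hi"\t'), prefixes) == '"say \\"hi\\"\\t"'
    assert serialize_term(Term("property_path", "a:b/c:d"), prefixes) == "a:b/c:d"
    assert serialize_term(Term("variable", "x"), prefixes) == "?x"


def test_subject_only_query_projects_p_o(prefixes):
    spec = ShortcutSpec(subject=classify_term("uniprot:P02649", "subject", prefixes))
    q = build_query(spec, prefixes)
    assert "uniprot:P02649 ?p ?o ." in q
    assert "SELECT ?p ?o" in q
    prepareQuery(q)


def test_empty_spec_projects_all_three(prefixes):
    q = build_query(ShortcutSpec(), prefixes)
    assert "?s ?p ?o ." in q
    assert "SELECT ?s ?p ?o" in q
    assert "PREFIX" not in q
    prepareQuery(q)


def test_property_path_kept_verbatim_and_projects_object(prefixes):
    spec = ShortcutSpec(
        subject=classify_term("uniprot:P02649", "subject", prefixes),
        predicate=classify_term("up:organism/up:scientificName", "predicate", prefixes))
    q = build_query(spec, prefixes)
    assert "up:organism/up:scientificName" in q
    assert "SELECT ?o" in q
    prepareQuery(q)


def test_declared_prefixes_equal_those_used_in_body(prefixes):
    """Prefix minimality: exactly the labels appearing in the pattern are
    declared, no more."""
    spec = ShortcutSpec(
        subject=classify_term("uniprot:P02649", "subject", prefixes),
        predicate=classify_term("up:organism", "predicate", prefixes))
    q = build_query(spec, prefixes)
    declared = {line.split()[1].rstrip(":") for line in q.splitlines()
                if line.startswith("PREFIX")}
    assert declared == {"uniprot", "up"}


def test_all_constant_pattern_emits_count(prefixes):
    spec = ShortcutSpec(
        subject=classify_term("uniprot:P02649", "subject", prefixes),
        predicate=classify_term("rdfs:label", "predicate", prefixes),
        object=classify_term('"apolipoprotein E"', "object", prefixes))
    q = build_query(spec, prefixes)
    assert "COUNT(*)" in q
    prepareQuery(q)


def test_limit_and_distinct(prefixes):
    q = build_query(ShortcutSpec(limit=5, distinct=True), prefixes)
    assert q.rstrip().endswith("LIMIT 5")
    assert "SELECT DISTINCT ?s ?p ?o" in q
    with pytest.raises(GenerationError):
        build_query(ShortcutSpec(limit=0), prefixes)


def test_limit_caps_rows_on_fixture(protein_graph, prefixes):
    total = len(evaluate(protein_graph, build_query(ShortcutSpec(), prefixes)).solutions)
    for k in (1, 3, total + 10):
        got = len(evaluate(protein_graph,
                           build_query(ShortcutSpec(limit=k), prefixes)).solutions)
        assert got == min(k, total)


def test_column_refs_become_variables_and_project(prefixes):
    spec = ShortcutSpec(subject=classify_term("1", "subject", prefixes),
                        predicate=classify_term("rdfs:label", "predicate", prefixes))
    q = build_query(spec, prefixes)
    assert "?s rdfs:label ?o ." in q
    assert "SELECT ?s ?o" in q


def test_duplicate_column_refs_rejected(prefixes):
    spec = ShortcutSpec(subject=classify_term("1", "subject", prefixes),
                        object=classify_term("1", "object", prefixes))
    with pytest.raises(GenerationError, match="distinct"):
        build_query(spec, prefixes)


def test_every_fixed_unfixed_combination_parses(prefixes):
    """All 8 S/P/O combinations yield grammatical SPARQL (independent
    parser check)."""
    s = classify_term("uniprot:P02649", "subject", prefixes)
    p = classify_term("rdfs:label", "predicate", prefixes)
    o = classify_term('"x"', "object", prefixes)
    for fs, fp, fo in itertools.product((None, s), (None, p), (None, o)):
        prepareQuery(build_query(ShortcutSpec(subject=fs, predicate=fp, object=fo),
                                 prefixes))
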