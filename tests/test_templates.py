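import random

import pytest
from hypothesis import given, settings, strategies as st

from oracles import max_placeholder
from sparqlpipe.errors import GenerationError, ResolutionError, TransportError
from sparqlpipe.templates import (Template, count_placeholders, resolve_template,
                                  substitute)


@pytest.mark.parametrize("text,expected", [
    ("SELECT ?x WHERE { ?x <http://p> $1 . ?x <http://q> $1 , $2 }", 2),
    ('SELECT ?x WHERE { ?x <http://p> "$1" }', 0),
    ("SELECT ?x WHERE { ?x ?p ?o }", 0),
    ("ask { <http://a> <http://b> $12 }", 12),
    ("# $9 in a comment\nSELECT ?x WHERE { ?x <http://p> $3 }", 3),
    ("SELECT ?x WHERE { ?x <http://p$5/x> $2 }", 2),  # $ inside an IRI is data
    ("SELECT ?x WHERE { ?x <http://p> '''multi $4 line''' }", 0),
])
def test_count_placeholders(text, expected):
    assert count_placeholders(text) == expected
    assert max_placeholder(text) == expected  # independent tokenizer agrees


def test_count_agrees_with_tokenizer_oracle_on_generated_texts():
    rng = random.Random(20)
    pieces_outside = ["SELECT ?x WHERE { ", "?x <http://p> ", " . ", "}", " $%d ",
                      "# note $%d\n", "?y "]
    pieces_inside = ['"lit $%d"', "'s $%d'", '"""long\n$%d"""', "<http://e/$%d>"]
    for _ in range(200):
        text, expected = "", 0
        for _ in range(rng.randint(1, 12)):
            n = rng.randint(1, 30)
            if rng.random() < 0.5:
                piece = rng.choice(pieces_outside)
                if "%d" in piece:
                    piece = piece % n
                    if "#" not in piece:  # comments and strings hide placeholders
                        expected = max(expected, n)
                else:
                    piece = piece
            else:
                piece = rng.choice(pieces_inside) % n
            text += piece
        assert count_placeholders(text) == max_placeholder(text)
        assert count_placeholders(text) == expected


def test_substitute_basic():
    t = Template.from_text(
        "PREFIX ent: <http://example.org/fixture/entry/>\n"
        "SELECT ?p ?o WHERE { ent:$1 ?p ?o }")
    q = substitute(t, ["P02649"])
    assert "ent:P02649 ?p ?o" in q
    assert "$1" not in q


def test_substitute_identity_without_placeholders():
    text = "SELECT ?x WHERE { ?x ?p ?o }"
    assert substitute(Template.from_text(text), []) == text


def test_substitute_arity_error():
    t = Template.from_text("SELECT * WHERE { ?x <http://p> $1 , $12 }")
    with pytest.raises(GenerationError, match="12 parameter"):
        substitute(t, ["only-one"])


def test_substitute_is_index_exact():
    t = Template.from_text("SELECT * WHERE { ?x <http://p> $1 , $12 }")
    params = [f"<http://v/{i}>" for i in range(1, 13)]
    q = substitute(t, params)
    assert "<http://v/1>" in q and "<http://v/12>" in q
    assert "<http://v/1>2" not in q


def test_substitute_leaves_placeholders_inside_strings():
    t = Template.from_text('SELECT * WHERE { ?x <http://p> "$1" . ?x <http://q> $1 }')
    q = substitute(t, ['"value"'])
    assert '"$1"' in q and '<http://q> "value"' in q


def test_substitution_is_position_faithful():
    t = Template.from_text("SELECT * WHERE { $1 <http://p> $2 }")
    a, b = "<http://x/a>", "<http://x/b>"
    assert substitute(t, [a, b]).index(a) < substitute(t, [a, b]).index(b)
    swapped = substitute(t, [b, a])
    assert swapped.index(b) < swapped.index(a)


@settings(derandomize=True, max_examples=100)
@given(perm=st.permutations(["<http://v/a>", "<http://v/b>", "<http://v/c>"]))
def test_substitution_permutes_with_params(perm):
    t = Template.from_text("SELECT * WHERE { $1 <http://p> $2 . $3 <http://q> $1 }")
    q = substitute(t, list(perm))
    assert q == ("SELECT * WHERE { %s <http://p> %s . %s <http://q> %s }"
                 % (perm[0], perm[1], perm[2], perm[0]))


def test_unparseable_instantiation_is_a_generation_error():
    t = Template.from_text("SELECT ?x WHERE { ?x <http://p> $1 }")
    with pytest.raises(GenerationError, match="does not parse"):
        substitute(t, ["^not-a-term"])


def test_resolve_builtin_library_template(config):
    t = resolve_template("uniprot_annot", config)
    assert t.placeholder_count == 1
    assert t.source.endswith("uniprot_annot.rq")


def test_local_file_wins_over_library(config, tmp_path, monkeypatch):
    f = tmp_path / "uniprot_annot"
    f.write_text("SELECT * WHERE { ?s ?p $1 }")
    monkeypatch.chdir(tmp_path)
    t = resolve_template("uniprot_annot", config)
    assert t.text == "SELECT * WHERE { ?s ?p $1 }"


def test_missing_template_lists_search_locations(config):
    with pytest.raises(ResolutionError, match="no_such_template"):
        resolve_template("no_such_template", config)


def test_remote_template_via_library_prefix(config, server):
    cfg = config.copy()
    cfg.apply_text(f"LIBRARY mbgd_test {server.url('/library/')} mbgdl:")
    t = resolve_template("mbgdl:get_ortholog", cfg)
    assert "fx:member" in t.text
    assert t.source.startswith("http://127.0.0.1:")


def test_remote_template_by_full_uri(config, server):
    t = resolve_template(server.url("/library/get_ortholog.rq"), config)
    assert t.placeholder_count == 1


def test_remote_fetch_failure_is_transport_error(config, server):
    with pytest.raises(TransportError, match="404"):
        resolve_template(server.url("/library/absent_template"), config)


def test_cache_dir_avoids_refetching(config, server, tmp_path):
    from sparqlpipe.templates import default_fetcher
    calls = []

    class CountingTransport:
        def request(self, method, url, headers, body=None):
            calls.append(url)
            from sparqlpipe.client import UrllibTransport
            return UrllibTransport(10.0).request(method, url, headers, body)

    fetch = default_fetcher(transport=CountingTransport(), cache_dir=str(tmp_path))
    url = server.url("/library/diff_expr.rq")
    first = fetch(url)
    second = fetch(url)
    assert first == second and "diffExprIn" in first
    assert len(calls) == 1
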