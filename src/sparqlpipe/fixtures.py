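"""Seeded synthetic RDF fixtures and an offline SPARQL endpoint.

Three toy graph kinds emulate, at desk scale, the shape of the public
databases a protein-centric SPARQL pipeline touches:

* ``protein_annot`` — entries with a label, an organism (with scientific
  name), 1–3 GO-style classification links and 0–2 cross-references
  tagged with a target database.
* ``ortholog_db`` — the same entry identifier space partitioned into
  ortholog groups with member links.
* ``expression_db`` — microarray-style probes linked to a disease
  condition (labelled) and to protein entries.

All vocabulary lives under a project-owned namespace
(``http://example.org/fixture/``): these graphs are synthetic stand-ins
and make no claim of fidelity to UniProt, MBGD or Expression Atlas
schemas.  A few well-known accessions (P02649, Q9Y2J0, K9Z723,
EFO_0000249, GO_0045202) are planted deterministically so documented
walkthroughs have stable anchors.

``evaluate`` runs SPARQL in-process via rdflib; ``serve_loopback`` wraps
graphs in a real HTTP server speaking the SPARQL 1.1 Protocol with JSON
and XML result formats, so end-to-end tests exercise the wire path
without any network.  ``oracle_join`` is the brute-force nested-loop
reference for pipe-composed two-stage queries.
"""

from __future__ import annotations

import json
import random
import threading
import urllib.parse
from collections import Counter
from dataclasses import dataclass
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path
from typing import Optional
from xml.sax.saxutils import escape, quoteattr

from rdflib import Graph, Literal, Namespace, URIRef, Variable
from rdflib.namespace import RDFS

from .client import (ResultSet, resultset_from_rdflib, serialize_field,
                     term_to_rdflib)
from .errors import GenerationError

FIXTURE_NS = "http://example.org/fixture/"
ENT = Namespace(FIXTURE_NS + "entry/")
FX = Namespace(FIXTURE_NS + "vocab/")
TAX = Namespace(FIXTURE_NS + "taxon/")
GO = Namespace(FIXTURE_NS + "go/")
GRP = Namespace(FIXTURE_NS + "group/")
PROBE = Namespace(FIXTURE_NS + "probe/")
COND = Namespace(FIXTURE_NS + "condition/")
DB = Namespace(FIXTURE_NS + "database/")
XR = Namespace(FIXTURE_NS + "xref/")

_TAXA = [("T9606", "Homo sapiens"), ("T10090", "Mus musculus"),
         ("T7227", "Drosophila melanogaster"), ("T4932", "Saccharomyces cerevisiae"),
         ("T562", "Escherichia coli")]
_GO_TERMS = [("GO_0045202", "synapse"), ("GO_0005634", "nucleus"),
             ("GO_0005737", "cytoplasm"), ("GO_0016020", "membrane"),
             ("GO_0005576", "extracellular region"), ("GO_0005739", "mitochondrion")]
_DATABASES = ["PDB", "RefSeq", "EMBL"]
_FAMILIES = ["kinase", "transporter", "receptor", "phosphatase", "lipoprotein",
             "hydrolase"]
_CONDITIONS = [("EFO_0000249", "Alzheimer's disease"),
               ("EFO_0000400", "diabetes mellitus"),
               ("EFO_0000571", "lung adenocarcinoma")]

# planted anchors: accession, label, taxon, GO terms, number of xrefs
_ANCHORS = [
    ("P02649", "apolipoprotein E", "T9606", ["GO_0005576", "GO_0016020"], 1),
    ("Q9Y2J0", "rabphilin-3A", "T9606", ["GO_0045202", "GO_0005737"], 0),
]


@dataclass(frozen=True)
class FixtureSpec:
    kind: str  # protein_annot | ortholog_db | expression_db
    n_entities: int
    seed: int
    prefix_namespace: str = FIXTURE_NS
    group_sizes: Optional[tuple[int, ...]] = None  # ortholog_db only

    def __post_init__(self):
        if self.kind not in ("protein_annot", "ortholog_db", "expression_db"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.n_entities < 1:
            raise ValueError("n_entities must be >= 1")


def protein_accessions(n: int) -> list[str]:
    """Deterministic shared identifier space for the protein-like graphs."""
    accs = [a[0] for a in _ANCHORS][:n]
    accs += [f"P{i:05d}" for i in range(1, n - len(accs) + 1)]
    return accs[:n]


def _bind_namespaces(g: Graph) -> None:
    for label, ns in (("ent", ENT), ("fx", FX), ("tax", TAX), ("go", GO),
                      ("grp", GRP), ("probe", PROBE), ("cond", COND),
                      ("db", DB), ("xr", XR), ("rdfs", RDFS)):
        g.bind(label, ns)


def build_fixture_with_stats(spec: FixtureSpec) -> tuple[Graph, Counter]:
    """Build the graph plus a per-predicate triple tally kept during
    generation (used to cross-check the generator against a recount)."""
    rng = random.Random(spec.seed)
    g = Graph()
    _bind_namespaces(g)
    stats: Counter = Counter()

    def add(s, p, o, key):
        if (s, p, o) not in g:
            g.add((s, p, o))
            stats[key] += 1

    if spec.kind == "protein_annot":
        anchors = {a[0]: a for a in _ANCHORS}
        for acc in protein_accessions(spec.n_entities):
            if acc in anchors:
                _, label, taxon, gos, n_xref = anchors[acc]
            else:
                label = f"{rng.choice(_FAMILIES)} {rng.randint(1, 999)}"
                taxon = rng.choice(_TAXA)[0]
                gos = [t[0] for t in rng.sample(_GO_TERMS, rng.randint(1, 3))]
                n_xref = rng.randint(0, 2)
            ent = ENT[acc]
            add(ent, RDFS.label, Literal(label), "entry_label")
            add(ent, FX.organism, TAX[taxon], "organism")
            tax_name = dict(_TAXA)[taxon]
            add(TAX[taxon], FX.scientificName, Literal(tax_name), "scientific_name")
            for go_id in gos:
                add(ent, FX.classifiedWith, GO[go_id], "classified_with")
                add(GO[go_id], RDFS.label, Literal(dict(_GO_TERMS)[go_id]), "go_label")
            for j in range(n_xref):
                xref = XR[f"{acc}_X{j + 1}"]
                add(ent, FX.xref, xref, "xref")
                # anchor entries get a stable PDB xref for documented walkthroughs
                target = "PDB" if acc in anchors and j == 0 else rng.choice(_DATABASES)
                add(xref, FX.database, DB[target], "xref_database")

    elif spec.kind == "ortholog_db":
        members = ["K9Z723"] + protein_accessions(max(spec.n_entities - 1, 0))
        members = members[:spec.n_entities]
        sizes = list(spec.group_sizes) if spec.group_sizes else []
        while sum(sizes) < len(members):
            sizes.append(rng.randint(3, 6))
        idx = 0
        for gi, size in enumerate(sizes, start=1):
            chunk = members[idx:idx + size]
            idx += size
            if not chunk:
                break
            group = GRP[f"G{gi:03d}"]
            for acc in chunk:
                add(group, FX.member, ENT[acc], "member")

    else:  # expression_db
        for efo_id, label in _CONDITIONS:
            add(COND[efo_id], RDFS.label, Literal(label), "condition_label")
        proteins = protein_accessions(max(spec.n_entities, len(_ANCHORS)))
        planted = [("A-0001", "Q9Y2J0", "EFO_0000249"),
                   ("A-0002", "P02649", "EFO_0000249")]
        for i in range(1, spec.n_entities + 1):
            probe_id = f"A-{i:04d}"
            plant = next((p for p in planted if p[0] == probe_id), None)
            if plant:
                _, acc, efo_id = plant
            else:
                acc = rng.choice(proteins)
                efo_id = rng.choice(_CONDITIONS)[0]
            probe = PROBE[probe_id]
            add(probe, FX.diffExprIn, COND[efo_id], "diff_expr_in")
            add(probe, FX.refersTo, ENT[acc], "refers_to")

    return g, stats


def build_fixture(spec: FixtureSpec) -> Graph:
    return build_fixture_with_stats(spec)[0]


def evaluate(graph: Graph, query: str, sort_solutions: bool = False) -> ResultSet:
    """In-process SPARQL evaluation; the offline counterpart of a remote
    endpoint and the oracle side of protocol-equivalence tests."""
    try:
        res = graph.query(query)
    except Exception as e:
        raise GenerationError(f"query failed to parse or evaluate: {e}") from None
    rs = resultset_from_rdflib(res)
    if sort_solutions:
        rs.solutions.sort(key=lambda sol: tuple(
            serialize_field(sol.get(v), False, None, raw_terms=True)
            for v in rs.variables))
    return rs


def oracle_join(graph_a: Graph, query_a: str, graph_b: Graph,
                query_b_with_var: str, join_variable: str,
                column: int = 1) -> ResultSet:
    """Nested-loop reference semantics for a two-stage pipe: evaluate the
    first query, then re-evaluate the second once per distinct value of
    the feeding column with the join variable pre-bound, and union all
    solutions."""
    first = evaluate(graph_a, query_a)
    if column > len(first.variables):
        raise GenerationError(f"first query projects {len(first.variables)} "
                              f"column(s); column {column} requested")
    col_var = first.variables[column - 1]
    distinct = []
    seen = set()
    for sol in first.solutions:
        term = sol.get(col_var)
        if term is not None and term not in seen:
            seen.add(term)
            distinct.append(term)
    out: Optional[ResultSet] = None
    for term in distinct:
        res = graph_b.query(query_b_with_var,
                            initBindings={Variable(join_variable): term_to_rdflib(term)})
        rs = resultset_from_rdflib(res)
        if out is None:
            out = ResultSet(rs.variables, [])
        out.solutions.extend(rs.solutions)
    return out if out is not None else ResultSet([], [])


# --- SPARQL results writers (server side) ---------------------------------

def results_to_json(rs: ResultSet) -> bytes:
    def enc(term):
        if term.kind == "iri":
            return {"type": "uri", "value": term.value}
        if term.kind == "bnode":
            return {"type": "bnode", "value": term.value}
        d = {"type": "literal", "value": term.value}
        if term.language:
            d["xml:lang"] = term.language
        elif term.datatype:
            d["datatype"] = term.datatype
        return d

    doc = {"head": {"vars": rs.variables},
           "results": {"bindings": [{v: enc(t) for v, t in sol.items()}
                                    for sol in rs.solutions]}}
    return json.dumps(doc).encode("utf-8")


def results_to_xml(rs: ResultSet) -> bytes:
    parts = ['<?xml version="1.0"?>',
             '<sparql xmlns="http://www.w3.org/2005/sparql-results#">', "<head>"]
    parts += [f'<variable name={quoteattr(v)}/>' for v in rs.variables]
    parts.append("</head><results>")
    for sol in rs.solutions:
        parts.append("<result>")
        for v, t in sol.items():
            parts.append(f"<binding name={quoteattr(v)}>")
            if t.kind == "iri":
                parts.append(f"<uri>{escape(t.value)}</uri>")
            elif t.kind == "bnode":
                parts.append(f"<bnode>{escape(t.value)}</bnode>")
            else:
                attrs = ""
                if t.language:
                    attrs = f" xml:lang={quoteattr(t.language)}"
                elif t.datatype:
                    attrs = f" datatype={quoteattr(t.datatype)}"
                parts.append(f"<literal{attrs}>{escape(t.value)}</literal>")
            parts.append("</binding>")
        parts.append("</result>")
    parts.append("</results></sparql>")
    return "".join(parts).encode("utf-8")


# --- loopback HTTP endpoint -------------------------------------------------

def _pick_format(accept: Optional[str]) -> Optional[str]:
    if not accept or not accept.strip():
        return "json"
    for item in accept.split(","):
        mt = item.split(";")[0].strip().lower()
        if mt in ("application/sparql-results+json", "application/json", "*/*"):
            return "json"
        if mt in ("application/sparql-results+xml", "application/xml", "text/xml"):
            return "xml"
    return None


class LoopbackEndpoint:
    """A real SPARQL Protocol endpoint on 127.0.0.1, answering for one or
    more graphs (one per URL path) and optionally serving template files
    from local directories (path prefix → directory)."""

    def __init__(self, graphs: dict[str, Graph],
                 files: Optional[dict[str, Path]] = None, port: int = 0):
        self._graphs = dict(graphs)
        self._files = {k.rstrip("/"): Path(v) for k, v in (files or {}).items()}
        endpoint = self

        class Handler(BaseHTTPRequestHandler):
            def log_message(self, *args):  # keep test output quiet
                pass

            def _reply(self, status: int, content_type: str, body: bytes):
                self.send_response(status)
                self.send_header("Content-Type", content_type)
                self.send_header("Content-Length", str(len(body)))
                self.end_headers()
                self.wfile.write(body)

            def _answer_query(self, path: str, query: Optional[str]):
                graph = endpoint._graphs.get(path)
                if graph is None:
                    return self._reply(404, "text/plain", b"no such graph")
                if not query:
                    return self._reply(400, "text/plain", b"missing query parameter")
                fmt = _pick_format(self.headers.get("Accept"))
                if fmt is None:
                    return self._reply(406, "text/plain", b"unsupported Accept")
                try:
                    rs = evaluate(graph, query, sort_solutions=True)
                except GenerationError as e:
                    return self._reply(400, "text/plain", str(e).encode())
                if fmt == "json":
                    self._reply(200, "application/sparql-results+json",
                                results_to_json(rs))
                else:
                    self._reply(200, "application/sparql-results+xml",
                                results_to_xml(rs))

            def do_GET(self):
                parsed = urllib.parse.urlparse(self.path)
                for prefix, directory in endpoint._files.items():
                    if parsed.path.startswith(prefix + "/"):
                        name = parsed.path[len(prefix) + 1:]
                        if "/" in name or name.startswith("."):
                            return self._reply(404, "text/plain", b"not found")
                        for candidate in (directory / name, directory / f"{name}.rq"):
                            if candidate.is_file():
                                return self._reply(
                                    200, "application/sparql-query",
                                    candidate.read_text(encoding="utf-8").encode())
                        return self._reply(404, "text/plain", b"not found")
                params = urllib.parse.parse_qs(parsed.query)
                self._answer_query(parsed.path, (params.get("query") or [None])[0])

            def do_POST(self):
                parsed = urllib.parse.urlparse(self.path)
                length = int(self.headers.get("Content-Length", "0"))
                body = self.rfile.read(length).decode("utf-8")
                ctype = (self.headers.get("Content-Type") or "").split(";")[0].strip()
                if ctype == "application/sparql-query":
                    query = body
                else:
                    params = urllib.parse.parse_qs(body)
                    query = (params.get("query") or [None])[0]
                self._answer_query(parsed.path, query)

        try:
            self._server = ThreadingHTTPServer(("127.0.0.1", port), Handler)
        except OSError as e:
            raise RuntimeError(f"cannot bind loopback endpoint: {e}") from None
        self._thread = threading.Thread(target=self._server.serve_forever, daemon=True)
        self._thread.start()

    @property
    def port(self) -> int:
        return self._server.server_address[1]

    def url(self, path: str) -> str:
        return f"http://127.0.0.1:{self.port}{path}"

    def close(self) -> None:
        self._server.shutdown()
        self._server.server_close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def serve_loopback(graphs: dict[str, Graph],
                   files: Optional[dict[str, Path]] = None,
                   port: int = 0) -> LoopbackEndpoint:
    return LoopbackEndpoint(graphs, files=files, port=port)
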