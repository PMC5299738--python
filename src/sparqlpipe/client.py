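"""SPARQL Protocol client and TSV serialization of result sets.

Queries go out per the SPARQL 1.1 Protocol: GET with a ``query=``
parameter when the encoded form fits in 2000 bytes, POST
(form-urlencoded) otherwise.  Results are requested as SPARQL Results
JSON first, XML as fallback (the endpoint's configured preference can
reorder this), and parsed with rdflib's result parsers.

TSV output is deliberately lossy: plain literal values are emitted bare
so the stream is directly usable by line-oriented Unix tools; IRIs are
bracketed or, with abbreviation on, rendered as prefixed names.  The
``raw_terms`` flag preserves full SPARQL lexical forms instead.
"""

from __future__ import annotations

import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from io import BytesIO
from typing import Optional

from rdflib import BNode, Literal, URIRef
from rdflib.query import Result

from .config import EndpointSpec, PrefixMap, abbreviate_uri
from .errors import FormatError, TransportError

_MAX_GET_BYTES = 2000
_ACCEPT_TYPES = {
    "json": "application/sparql-results+json",
    "xml": "application/sparql-results+xml",
}


@dataclass(frozen=True)
class RDFTerm:
    kind: str  # iri | literal | bnode
    value: str
    datatype: Optional[str] = None
    language: Optional[str] = None


@dataclass
class ResultSet:
    variables: list[str]
    solutions: list[dict[str, RDFTerm]] = field(default_factory=list)


def term_from_rdflib(t) -> RDFTerm:
    if isinstance(t, URIRef):
        return RDFTerm("iri", str(t))
    if isinstance(t, Literal):
        dt = str(t.datatype) if t.datatype else None
        return RDFTerm("literal", str(t), datatype=dt, language=t.language)
    if isinstance(t, BNode):
        return RDFTerm("bnode", str(t))
    raise FormatError(f"unsupported RDF term {t!r}")


def term_to_rdflib(t: RDFTerm):
    if t.kind == "iri":
        return URIRef(t.value)
    if t.kind == "bnode":
        return BNode(t.value)
    return Literal(t.value,
                   datatype=URIRef(t.datatype) if t.datatype else None,
                   lang=t.language)


def resultset_from_rdflib(res) -> ResultSet:
    variables = [str(v) for v in (res.vars or [])]
    solutions = []
    for binding in res.bindings:
        sol = {str(var): term_from_rdflib(term)
               for var, term in binding.items() if term is not None}
        solutions.append(sol)
    return ResultSet(variables, solutions)


class UrllibTransport:
    """Thin HTTP capability; swapped out for spies/mocks in tests."""

    def __init__(self, timeout: float = 60.0):
        self.timeout = timeout

    def request(self, method: str, url: str, headers: dict,
                body: Optional[bytes] = None):
        req = urllib.request.Request(url, data=body, headers=headers, method=method)
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                return resp.status, {k.lower(): v for k, v in resp.headers.items()}, resp.read()
        except urllib.error.HTTPError as e:
            return e.code, {k.lower(): v for k, v in e.headers.items()}, e.read()
        except urllib.error.URLError as e:
            raise TransportError(f"cannot reach {url}: {e.reason}") from None


def parse_results(body: bytes, content_type: str) -> ResultSet:
    ct = (content_type or "").lower()
    if "json" in ct:
        fmt = "json"
    elif "xml" in ct:
        fmt = "xml"
    else:
        raise FormatError(f"cannot parse results of content type {content_type!r}")
    try:
        res = Result.parse(BytesIO(body), format=fmt)
    except Exception as e:
        raise FormatError(
            f"unparseable {fmt} results (content type {content_type!r}): {e}") from None
    return resultset_from_rdflib(res)


def execute(endpoint: EndpointSpec, query: str, transport=None,
            timeout: float = 60.0) -> ResultSet:
    if not query.strip():
        raise TransportError("refusing to send an empty query")
    transport = transport or UrllibTransport(timeout)
    accept = ", ".join(_ACCEPT_TYPES[f] for f in endpoint.result_format_preference
                       if f in _ACCEPT_TYPES) or _ACCEPT_TYPES["json"]
    encoded = urllib.parse.urlencode({"query": query})
    if len(encoded) <= _MAX_GET_BYTES:
        sep = "&" if "?" in endpoint.url else "?"
        status, headers, body = transport.request(
            "GET", endpoint.url + sep + encoded, {"Accept": accept})
    else:
        status, headers, body = transport.request(
            "POST", endpoint.url,
            {"Accept": accept, "Content-Type": "application/x-www-form-urlencoded"},
            encoded.encode("ascii"))
    if not 200 <= status < 300:
        snippet = body[:500].decode("utf-8", "replace")
        raise TransportError(f"endpoint {endpoint.url} returned HTTP {status}: {snippet}")
    return parse_results(body, headers.get("content-type", ""))


def _raw_lexical(term: RDFTerm) -> str:
    if term.kind == "iri":
        return f"<{term.value}>"
    if term.kind == "bnode":
        return f"_:{term.value}"
    from .shortcuts import escape_literal
    lex = f'"{escape_literal(term.value)}"'
    if term.language:
        return f"{lex}@{term.language}"
    if term.datatype:
        return f"{lex}^^<{term.datatype}>"
    return lex


def serialize_field(term: Optional[RDFTerm], abbreviate: bool,
                    prefixes: Optional[PrefixMap], raw_terms: bool = False) -> str:
    if term is None:
        return ""
    if raw_terms:
        return _raw_lexical(term)
    if term.kind == "iri":
        if abbreviate and prefixes is not None:
            return abbreviate_uri(term.value, prefixes)
        return f"<{term.value}>"
    if term.kind == "bnode":
        return f"_:{term.value}"
    if "\t" in term.value or "\n" in term.value or "\r" in term.value:
        raise FormatError(
            f"literal contains a tab or newline and cannot be written as TSV: "
            f"{term.value!r}")
    return term.value


def serialize_tsv(result: ResultSet, abbreviate: bool = False,
                  prefixes: Optional[PrefixMap] = None, with_header: bool = True,
                  raw_terms: bool = False) -> str:
    lines = []
    if with_header:
        lines.append("\t".join(result.variables))
    for sol in result.solutions:
        lines.append("\t".join(
            serialize_field(sol.get(v), abbreviate, prefixes, raw_terms)
            for v in result.variables))
    return "".join(line + "\n" for line in lines)
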