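"""Binding transfer between piped queries.

A previous pipeline stage (or any Unix tool) writes TSV on standard
output; this module reads it back as a table of RDF term strings and
injects selected columns into the next query as a ``VALUES`` block, the
SPARQL construct for inlining an explicit binding table.  Rows are
deduplicated (first occurrence wins) and split into chunks so each
outgoing query stays below endpoint size limits; concatenating chunk
results is the logical result and is independent of the chunk size.

TSV erases RDF term types, so input tokens are re-classified: bracketed
or ``http(s)://`` tokens become IRIs, ``label:local`` with a declared
label stays a prefixed name (abbreviated output from a previous ``-a``
stage round-trips), anything else becomes a plain literal.  An empty
field becomes ``UNDEF``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import IO, Optional

from ._textscan import find_group_open, referenced_variables
from .config import PrefixMap
from .errors import FormatError, GenerationError
from .shortcuts import escape_literal

_PNAME_RE = re.compile(r"^([A-Za-z_][A-Za-z0-9_.\-]*):(\S*)$")
_VARNAME_RE = re.compile(r"^\??[A-Za-z_][A-Za-z0-9_]*$")


@dataclass
class BindingTable:
    header: Optional[list[str]]
    rows: list[list[str]]

    @property
    def arity(self) -> int:
        if self.header is not None:
            return len(self.header)
        return len(self.rows[0]) if self.rows else 0


@dataclass(frozen=True)
class ColumnBinding:
    column: int  # 1-based
    variable: str


def read_tsv(stream: IO[str], expect_header: bool = False) -> BindingTable:
    text = stream.read()
    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    rows: list[list[str]] = []
    arity: Optional[int] = None
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if arity is None:
            arity = len(fields)
        elif len(fields) != arity:
            raise FormatError(
                f"ragged TSV input: line {lineno} has {len(fields)} field(s), "
                f"expected {arity}")
        rows.append(fields)
    header: Optional[list[str]] = None
    if expect_header and rows:
        header = [f.lstrip("?") for f in rows.pop(0)]
    return BindingTable(header, rows)


def looks_like_header(fields: list[str], query_variables: set[str]) -> bool:
    """Heuristic used when the caller did not say whether a header is
    present: every field is a plausible variable name and the downstream
    query references at least one of them."""
    if not fields:
        return False
    if not all(_VARNAME_RE.match(f) for f in fields):
        return False
    return any(f.lstrip("?") in query_variables for f in fields)


def autodetect_header(table: BindingTable, query: str) -> BindingTable:
    if table.header is None and table.rows and \
            looks_like_header(table.rows[0], referenced_variables(query)):
        return BindingTable([f.lstrip("?") for f in table.rows[0]], table.rows[1:])
    return table


def serialize_input_token(token: str, prefixes: PrefixMap) -> str:
    if token == "":
        return "UNDEF"
    if token.startswith("<") and token.endswith(">") and len(token) > 2:
        return token
    if token.startswith(("http://", "https://")):
        return f"<{token}>"
    m = _PNAME_RE.match(token)
    if m and "://" not in token and m.group(1) in prefixes:
        return token
    return f'"{escape_literal(token)}"'


def inject_values(query: str, bindings: list[ColumnBinding], table: BindingTable,
                  prefixes: PrefixMap, chunk_size: int = 100) -> list[str]:
    """One query per chunk, each with a VALUES block as the first element
    of the outermost group pattern.  Zero input rows yield zero queries."""
    if chunk_size < 1:
        raise GenerationError("chunk size must be >= 1")
    if not bindings:
        raise GenerationError("no column bindings given")
    qvars = referenced_variables(query)
    for b in bindings:
        if b.variable not in qvars:
            raise GenerationError(
                f"bound variable ?{b.variable} does not occur in the query")
    if not table.rows:
        return []
    arity = table.arity
    for b in bindings:
        if b.column > arity:
            raise FormatError(
                f"column {b.column} referenced but input has only {arity} column(s)")

    tuples: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    for row in table.rows:
        t = tuple(row[b.column - 1] for b in bindings)
        if t not in seen:
            seen.add(t)
            tuples.append(t)

    pos = find_group_open(query)
    if pos < 0:
        raise GenerationError("query has no group pattern to inject VALUES into")
    var_list = " ".join(f"?{b.variable}" for b in bindings)

    queries = []
    for start in range(0, len(tuples), chunk_size):
        chunk = tuples[start:start + chunk_size]
        rows_text = "\n".join(
            "    ( " + " ".join(serialize_input_token(v, prefixes) for v in t) + " )"
            for t in chunk)
        block = f"\n  VALUES ( {var_list} ) {{\n{rows_text}\n  }}"
        queries.append(query[:pos + 1] + block + query[pos + 1:])
    return queries
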