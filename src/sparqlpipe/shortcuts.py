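"""Shortcut mode: turn -S/-P/-O/-L style options into a SPARQL SELECT
query over a single triple pattern.

Classification of a command-line token, in order:

1. bare decimal integer            → reference to a column of standard input
2. ``<...>`` or ``http(s)://...``  → IRI
3. explicitly quoted ``"..."``     → literal (lets users pass numeric literals)
4. contains a path operator, in predicate position → property path, verbatim
5. ``label:local`` with a declared label → prefixed name
6. anything else                   → plain literal

A ``label:local`` token with an undeclared label is an error rather than a
literal, so prefix typos surface immediately.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal as TLiteral, Optional

from ._textscan import protected_mask
from .config import PrefixMap
from .errors import GenerationError

TermKind = TLiteral["iri", "prefixed_name", "literal", "property_path", "variable", "column_ref"]

_PNAME_RE = re.compile(r"^([A-Za-z_][A-Za-z0-9_.\-]*):(\S*)$")
_PATH_OPS = set("/|^*+?()")
_POSITIONS = ("subject", "predicate", "object")
_POSITION_VARS = {"subject": "s", "predicate": "p", "object": "o"}

_ESCAPES = {"\\": "\\\\", '"': '\\"', "\n": "\\n", "\r": "\\r", "\t": "\\t"}


@dataclass(frozen=True)
class Term:
    kind: TermKind
    text: str
    column: Optional[int] = None


@dataclass
class ShortcutSpec:
    subject: Optional[Term] = None
    predicate: Optional[Term] = None
    object: Optional[Term] = None
    limit: Optional[int] = None
    abbreviate_output: bool = False
    show_query_only: bool = False
    distinct: bool = False


def _has_path_operator(token: str) -> bool:
    mask = protected_mask(token)
    return any(ch in _PATH_OPS and not mask[i] for i, ch in enumerate(token))


def classify_term(token: str, position: str, prefixes: PrefixMap) -> Term:
    if position not in _POSITIONS:
        raise ValueError(f"bad position {position!r}")
    if not token:
        raise GenerationError(f"empty {position} term")
    if token.isdigit():
        col = int(token)
        if col < 1:
            raise GenerationError("input column references are 1-based")
        return Term("column_ref", token, col)
    if token.startswith("<") and token.endswith(">") and len(token) > 2:
        return Term("iri", token[1:-1])
    if token.startswith(("http://", "https://")):
        return Term("iri", token)
    for q in ('"', "'"):
        if len(token) >= 2 and token.startswith(q) and token.endswith(q):
            return Term("literal", token[1:-1])
    if position == "predicate" and _has_path_operator(token):
        return Term("property_path", token)
    m = _PNAME_RE.match(token)
    if m and "://" not in token:
        label = m.group(1)
        if label not in prefixes:
            raise GenerationError(
                f"cannot classify {token!r}: prefix label '{label}:' is not declared")
        return Term("prefixed_name", token)
    return Term("literal", token)


def escape_literal(text: str) -> str:
    return "".join(_ESCAPES.get(c, c) for c in text)


def serialize_term(term: Term, prefixes: PrefixMap) -> str:
    if term.kind == "iri":
        return f"<{term.text}>"
    if term.kind == "prefixed_name":
        return term.text
    if term.kind == "literal":
        return f'"{escape_literal(term.text)}"'
    if term.kind == "property_path":
        return term.text
    if term.kind == "variable":
        return f"?{term.text}"
    if term.kind == "column_ref":
        return f"?c{term.column}"
    raise ValueError(f"unknown term kind {term.kind!r}")


def _labels_in_path(path: str, prefixes: PrefixMap) -> set[str]:
    """Prefix labels used by prefixed names inside a property path."""
    mask = protected_mask(path)
    labels = set()
    for m in re.finditer(r"([A-Za-z_][A-Za-z0-9_.\-]*):", path):
        if mask[m.start()] or path.startswith("//", m.end()):
            continue
        label = m.group(1)
        if label not in prefixes:
            raise GenerationError(
                f"property path {path!r} uses undeclared prefix label '{label}:'")
        labels.add(label)
    return labels


def _used_prefix_labels(spec: ShortcutSpec, prefixes: PrefixMap) -> list[str]:
    labels: set[str] = set()
    for term in (spec.subject, spec.predicate, spec.object):
        if term is None:
            continue
        if term.kind == "prefixed_name":
            label = term.text.split(":", 1)[0]
            if label not in prefixes:
                raise GenerationError(f"undeclared prefix label '{label}:'")
            labels.add(label)
        elif term.kind == "property_path":
            labels |= _labels_in_path(term.text, prefixes)
    # emit in declaration order for stable output
    order = {lab: i for i, (lab, _) in enumerate(prefixes.items())}
    return sorted(labels, key=lambda l: order[l])


def column_bindings_of(spec: ShortcutSpec) -> list[tuple[int, str]]:
    """(column, variable) pairs for the column-reference positions."""
    out = []
    for pos in _POSITIONS:
        term = getattr(spec, {"subject": "subject", "predicate": "predicate",
                              "object": "object"}[pos])
        if term is not None and term.kind == "column_ref":
            out.append((term.column, _POSITION_VARS[pos]))
    cols = [c for c, _ in out]
    if len(set(cols)) != len(cols):
        raise GenerationError("input column references must name distinct columns")
    return out


def build_query(spec: ShortcutSpec, prefixes: PrefixMap) -> str:
    """Assemble the SELECT query for one triple pattern.

    Unspecified and column-reference positions become the fixed variables
    ?s/?p/?o and are projected in S,P,O order; column-reference variables
    are bound later via a VALUES block.  With all three positions fixed,
    a COUNT query is emitted so presence/absence is still observable in
    TSV (0 vs >= 1).
    """
    if spec.limit is not None and spec.limit < 1:
        raise GenerationError("LIMIT must be >= 1")
    column_bindings_of(spec)  # validates distinctness
    tokens: list[str] = []
    projected: list[str] = []
    for pos, term in (("subject", spec.subject), ("predicate", spec.predicate),
                      ("object", spec.object)):
        var = _POSITION_VARS[pos]
        if term is None or term.kind in ("variable", "column_ref"):
            tokens.append(f"?{var}")
            projected.append(var)
        else:
            tokens.append(serialize_term(term, prefixes))
    lines = [f"PREFIX {lab}: <{prefixes.lookup(lab)}>"
             for lab in _used_prefix_labels(spec, prefixes)]
    if projected:
        head = "SELECT " + ("DISTINCT " if spec.distinct else "") \
               + " ".join(f"?{v}" for v in projected)
    else:
        head = "SELECT (COUNT(*) AS ?n)"
    lines += [head, "WHERE {", f"  {tokens[0]} {tokens[1]} {tokens[2]} .", "}"]
    if spec.limit is not None:
        lines.append(f"LIMIT {spec.limit}")
    return "\n".join(lines) + "\n"
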