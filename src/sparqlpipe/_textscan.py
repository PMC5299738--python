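"""Lexical scanning helpers for SPARQL text manipulation.

Placeholder substitution, prefix harvesting and VALUES injection all need
to know which character positions of a query sit inside string literals,
IRIREFs or comments — the regions where tokens like ``$1`` or ``?x`` are
data, not syntax.  Nothing here is a SPARQL parser; full validation is
delegated to rdflib.
"""

from __future__ import annotations

import re
from typing import Iterator

_VAR_RE = re.compile(r"[?$]([A-Za-z_][A-Za-z0-9_]*)")


def protected_mask(text: str) -> list[bool]:
    """Boolean mask over ``text``: True where the character belongs to a
    string literal (short or long, single or double quoted), an IRIREF,
    or a ``#`` comment."""
    n = len(text)
    mask = [False] * n
    i = 0
    while i < n:
        c = text[i]
        if c in "\"'":
            if text.startswith(c * 3, i):
                close = text.find(c * 3, i + 3)
                end = n if close < 0 else close + 3
            else:
                j = i + 1
                while j < n and text[j] != c:
                    if text[j] == "\\":
                        j += 1
                    j += 1
                end = min(j + 1, n)
            for k in range(i, end):
                mask[k] = True
            i = end
        elif c == "<":
            close = text.find(">", i + 1)
            inner = text[i + 1 : close] if close >= 0 else None
            # IRIREFs contain no whitespace or nested '<'
            if inner is not None and not re.search(r"[\s<]", inner):
                for k in range(i, close + 1):
                    mask[k] = True
                i = close + 1
            else:
                i += 1
        elif c == "#":
            nl = text.find("\n", i)
            end = n if nl < 0 else nl
            for k in range(i, end):
                mask[k] = True
            i = end
        else:
            i += 1
    return mask


def unmasked_finditer(pattern: re.Pattern[str], text: str) -> Iterator[re.Match[str]]:
    """Matches of ``pattern`` whose start lies outside protected regions."""
    mask = protected_mask(text)
    for m in pattern.finditer(text):
        if not mask[m.start()]:
            yield m


def referenced_variables(query: str) -> set[str]:
    """Names of all variables (``?x`` / ``$x``) used outside strings/IRIs."""
    return {m.group(1) for m in unmasked_finditer(_VAR_RE, query)}


def find_group_open(query: str) -> int:
    """Index of the first ``{`` outside strings/IRIs/comments — the opening
    brace of the outermost group pattern of a SELECT query.  Returns -1 if
    absent."""
    mask = protected_mask(query)
    for i, ch in enumerate(query):
        if ch == "{" and not mask[i]:
            return i
    return -1
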