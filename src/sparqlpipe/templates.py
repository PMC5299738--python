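"""Template mode: resolve a SPARQL template and substitute positional
parameters.

Placeholders are ``$N`` (one or more digits, longest run wins, so ``$12``
is parameter 12 and never parameter 1 followed by "2") occurring outside
string literals, IRIREFs and comments.  Parameters are inserted verbatim:
a parameter may be a bare local name the template embeds in a prefixed
name (``ent:$1``), a full IRI, or an already-quoted literal such as
``"^alzheimer"`` — the template author decides the lexical context.

Resolution order for a template name: existing local file path, then the
configured local library directories (``<name>.rq`` before ``<name>``),
then a prefixed name whose label matches a configured library prefix
(expanded against the library base IRI and fetched), then a full IRI.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

from rdflib.plugins.sparql import prepareQuery

from ._textscan import unmasked_finditer
from .config import Config
from .errors import GenerationError, ResolutionError, TransportError

_PLACEHOLDER_RE = re.compile(r"\$(\d+)")
_PNAME_RE = re.compile(r"^([A-Za-z_][A-Za-z0-9_.\-]*):(\S+)$")

Fetcher = Callable[[str], str]


@dataclass
class Template:
    source: str  # file path or IRI the text came from
    text: str
    placeholder_count: int

    @classmethod
    def from_text(cls, text: str, source: str = "<inline>") -> "Template":
        return cls(source, text, count_placeholders(text))


def count_placeholders(text: str) -> int:
    """Largest N of any ``$N`` outside strings/IRIs/comments; 0 if none."""
    best = 0
    for m in unmasked_finditer(_PLACEHOLDER_RE, text):
        n = int(m.group(1))
        if n > best:
            best = n
    return best


def validate_query(text: str) -> None:
    """Check against an independent SPARQL 1.1 grammar."""
    try:
        prepareQuery(text)
    except Exception as e:  # pyparsing raises several exception types
        raise GenerationError(f"instantiated query does not parse: {e}\n---\n{text}") from None


def substitute(template: Template, params: list[str]) -> str:
    """Replace every unprotected ``$N`` with ``params[N-1]``, simultaneously
    and index-exactly, then validate the result parses as SPARQL."""
    if len(params) < template.placeholder_count:
        raise GenerationError(
            f"template {template.source} expects {template.placeholder_count} "
            f"parameter(s), {len(params)} given")
    text = template.text
    out = []
    last = 0
    for m in unmasked_finditer(_PLACEHOLDER_RE, text):
        n = int(m.group(1))
        if n == 0:
            continue  # $0 is never a placeholder
        out.append(text[last:m.start()])
        out.append(params[n - 1])
        last = m.end()
    out.append(text[last:])
    result = "".join(out)
    validate_query(result)
    return result


def default_fetcher(transport=None, cache_dir: Optional[str] = None) -> Fetcher:
    """HTTP GET fetcher with optional content-addressed caching."""

    def fetch(url: str) -> str:
        if cache_dir is not None:
            key = hashlib.sha256(url.encode()).hexdigest()
            cached = Path(cache_dir) / key
            if cached.is_file():
                return cached.read_text(encoding="utf-8")
        from .client import UrllibTransport  # local import avoids a cycle
        tr = transport or UrllibTransport()
        status, _, body = tr.request("GET", url, {"Accept": "*/*"})
        if not 200 <= status < 300:
            raise TransportError(f"fetching template {url} failed with HTTP {status}")
        text = body.decode("utf-8")
        if cache_dir is not None:
            Path(cache_dir).mkdir(parents=True, exist_ok=True)
            (Path(cache_dir) / key).write_text(text, encoding="utf-8")
        return text

    return fetch


def _fetch_with_rq_fallback(url: str, fetch: Fetcher) -> str:
    try:
        return fetch(url)
    except TransportError:
        if url.endswith(".rq"):
            raise
        return fetch(url + ".rq")


def resolve_template(name: str, config: Config, fetcher: Optional[Fetcher] = None) -> Template:
    if not name:
        raise ResolutionError("empty template name")
    searched: list[str] = []

    p = Path(name)
    searched.append(str(p))
    if p.is_file():
        return Template.from_text(p.read_text(encoding="utf-8"), str(p))

    # later-declared (user) libraries shadow earlier (builtin) ones
    for lib in reversed(config.libraries):
        if lib.is_remote:
            continue
        for candidate in (Path(lib.root) / f"{name}.rq", Path(lib.root) / name):
            searched.append(str(candidate))
            if candidate.is_file():
                return Template.from_text(candidate.read_text(encoding="utf-8"),
                                          str(candidate))

    m = _PNAME_RE.match(name)
    if m and "://" not in name:
        label, local = m.groups()
        for lib in reversed(config.libraries):
            if lib.prefix_label == label:
                if not lib.is_remote:
                    candidate = Path(lib.root) / local
                    searched.append(str(candidate))
                    for c in (Path(lib.root) / f"{local}.rq", candidate):
                        if c.is_file():
                            return Template.from_text(c.read_text(encoding="utf-8"), str(c))
                    continue
                url = lib.root + local
                fetch = fetcher or default_fetcher()
                return Template.from_text(_fetch_with_rq_fallback(url, fetch), url)
        searched.append(f"{label}: (no library declares this prefix)")

    if "://" in name:
        fetch = fetcher or default_fetcher()
        return Template.from_text(_fetch_with_rq_fallback(name, fetch), name)

    raise ResolutionError(
        "template %r not found; searched: %s" % (name, "; ".join(searched)))
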