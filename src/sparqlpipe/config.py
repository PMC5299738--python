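"""Layered configuration: prefix declarations, endpoint nicknames, template
library roots.

Configuration is line-oriented text with three directives::

    PREFIX label: <iri>          # SPARQL-compatible prefix declaration
    ENDPOINT nickname url [fmts] # fmts: comma list from json,xml,tsv
    LIBRARY name root [label:]   # root: directory or base IRI

Layers merge last-writer-wins per key: package builtins, then
``$HOME/.sparqlpipe/config``, then ``./sparqlpipe.config``, then any
``--config`` files in order.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError, ResolutionError

_SCHEME_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.\-]*:")
_PNAME_RE = re.compile(r"^([A-Za-z_][A-Za-z0-9_.\-]*):(\S*)$")
# conservative PN_LOCAL: no whitespace, '/', '#', quotes or angle brackets
_BAD_LOCAL_RE = re.compile(r"[\s/#<>\"']")

_FORMATS = ("json", "xml", "tsv")

BUILTIN_CONFIG_PATH = Path(__file__).parent / "data" / "builtin.config"
BUILTIN_LIBRARY_DIR = Path(__file__).parent / "library"


def _is_absolute_iri(s: str) -> bool:
    return bool(_SCHEME_RE.match(s)) and not re.search(r"[\s<>]", s)


class PrefixMap:
    """Ordered label → namespace-IRI mapping.

    Later declarations override earlier ones and win longest-match ties
    during abbreviation.
    """

    def __init__(self) -> None:
        self._iris: dict[str, str] = {}
        self._seq: dict[str, int] = {}
        self._counter = 0

    def declare(self, label: str, iri: str) -> None:
        if not _is_absolute_iri(iri):
            raise ConfigError(f"namespace for prefix '{label}:' is not an absolute IRI: {iri!r}")
        self._iris[label] = iri
        self._counter += 1
        self._seq[label] = self._counter

    def lookup(self, label: str) -> str:
        try:
            return self._iris[label]
        except KeyError:
            raise ConfigError(f"undeclared prefix label '{label}:'") from None

    def __contains__(self, label: str) -> bool:
        return label in self._iris

    def __len__(self) -> int:
        return len(self._iris)

    def items(self):
        return self._iris.items()

    def copy(self) -> "PrefixMap":
        new = PrefixMap()
        new._iris = dict(self._iris)
        new._seq = dict(self._seq)
        new._counter = self._counter
        return new

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PrefixMap) and self._iris == other._iris

    def expand(self, token: str) -> str:
        """Expand a prefixed name, bracketed IRI or bare absolute IRI to an
        absolute IRI string."""
        if token.startswith("<") and token.endswith(">"):
            return token[1:-1]
        if "://" in token:
            return token
        m = _PNAME_RE.match(token)
        if not m:
            raise ConfigError(f"cannot expand {token!r}: not a prefixed name or IRI")
        return self.lookup(m.group(1)) + m.group(2)

    def abbreviate(self, iri: str) -> str:
        """Abbreviate an absolute IRI to ``label:local`` using the longest
        declared namespace whose remainder is a safe local part; ties on
        namespace length go to the later declaration.  Falls back to the
        bracketed IRI."""
        best: tuple[int, int, str, str] | None = None
        for label, ns in self._iris.items():
            if iri.startswith(ns):
                local = iri[len(ns):]
                if _BAD_LOCAL_RE.search(local):
                    continue
                key = (len(ns), self._seq[label], label, local)
                if best is None or key[:2] > best[:2]:
                    best = key
        if best is None:
            return f"<{iri}>"
        return f"{best[2]}:{best[3]}"


def expand_term(token: str, prefixes: PrefixMap) -> str:
    return prefixes.expand(token)


def abbreviate_uri(iri: str, prefixes: PrefixMap) -> str:
    return prefixes.abbreviate(iri)


@dataclass
class EndpointSpec:
    nickname: str
    url: str
    result_format_preference: tuple[str, ...] = ("json", "xml")

    def __post_init__(self) -> None:
        if re.search(r"\s", self.nickname) or "://" in self.nickname:
            raise ConfigError(f"bad endpoint nickname {self.nickname!r}")
        if not re.match(r"^https?://\S+$", self.url):
            raise ConfigError(f"endpoint url must be absolute http(s): {self.url!r}")


@dataclass
class TemplateLibrary:
    name: str
    root: str  # local directory path or absolute base IRI
    prefix_label: str | None = None

    @property
    def is_remote(self) -> bool:
        return "://" in self.root


@dataclass
class Config:
    prefixes: PrefixMap = field(default_factory=PrefixMap)
    endpoints: dict[str, EndpointSpec] = field(default_factory=dict)
    libraries: list[TemplateLibrary] = field(default_factory=list)

    def copy(self) -> "Config":
        return Config(self.prefixes.copy(), dict(self.endpoints), list(self.libraries))

    def _add_library(self, lib: TemplateLibrary) -> None:
        # last-writer-wins by library name, declaration order otherwise
        self.libraries = [l for l in self.libraries if l.name != lib.name]
        self.libraries.append(lib)

    def apply_text(self, text: str, source: str = "<config>") -> None:
        """Apply directives from one configuration layer on top of this one."""
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            word = line.split(None, 1)[0].upper()
            if word == "PREFIX":
                m = re.match(r"^PREFIX\s+([A-Za-z_][A-Za-z0-9_.\-]*):\s*<([^<>\s]+)>\s*$",
                             line, re.I)
                if not m:
                    raise ConfigError(f"{source}:{lineno}: malformed PREFIX line: {raw!r}")
                self.prefixes.declare(m.group(1), m.group(2))
            elif word == "ENDPOINT":
                parts = line.split()
                if len(parts) not in (3, 4):
                    raise ConfigError(f"{source}:{lineno}: ENDPOINT needs nickname and url")
                fmts: tuple[str, ...] = ("json", "xml")
                if len(parts) == 4:
                    fmts = tuple(parts[3].split(","))
                    if not fmts or any(f not in _FORMATS for f in fmts):
                        raise ConfigError(f"{source}:{lineno}: bad format list {parts[3]!r}")
                try:
                    spec = EndpointSpec(parts[1], parts[2], fmts)
                except ConfigError as e:
                    raise ConfigError(f"{source}:{lineno}: {e}") from None
                self.endpoints[parts[1]] = spec
            elif word == "LIBRARY":
                parts = line.split()
                if len(parts) not in (3, 4):
                    raise ConfigError(f"{source}:{lineno}: LIBRARY needs name and root")
                name, root = parts[1], parts[2]
                label = None
                if len(parts) == 4:
                    if not parts[3].endswith(":"):
                        raise ConfigError(f"{source}:{lineno}: library prefix must end with ':'")
                    label = parts[3][:-1]
                if not ("://" in root and _is_absolute_iri(root)) and not os.path.isdir(root):
                    raise ConfigError(
                        f"{source}:{lineno}: library root is neither a directory "
                        f"nor an absolute IRI: {root!r}")
                self._add_library(TemplateLibrary(name, root, label))
            else:
                raise ConfigError(f"{source}:{lineno}: unknown directive {word!r}")

    def apply_file(self, path: str | Path) -> None:
        p = Path(path)
        try:
            text = p.read_text(encoding="utf-8")
        except OSError as e:
            raise ConfigError(f"cannot read configuration file {p}: {e}") from None
        self.apply_text(text, source=str(p))


def load_config(paths: list[str | Path] | tuple = (), include_builtins: bool = True) -> Config:
    """Merge configuration layers; later paths override earlier ones and the
    builtin layer."""
    cfg = Config()
    if include_builtins:
        cfg.apply_file(BUILTIN_CONFIG_PATH)
        cfg._add_library(TemplateLibrary("builtin", str(BUILTIN_LIBRARY_DIR)))
    for p in paths:
        cfg.apply_file(p)
    return cfg


def default_config_paths() -> list[Path]:
    """Existing user-level config files, in precedence order."""
    candidates = [Path.home() / ".sparqlpipe" / "config", Path.cwd() / "sparqlpipe.config"]
    return [p for p in candidates if p.is_file()]


def resolve_endpoint(name_or_url: str, config: Config) -> EndpointSpec:
    """A string containing ``://`` is used as-is; anything else is a
    nickname looked up in the configuration."""
    if not name_or_url:
        raise ResolutionError("empty endpoint reference")
    if "://" in name_or_url:
        return EndpointSpec("", name_or_url)
    try:
        return config.endpoints[name_or_url]
    except KeyError:
        known = ", ".join(sorted(config.endpoints)) or "(none)"
        raise ResolutionError(
            f"unknown endpoint nickname {name_or_url!r}; known nicknames: {known}") from None
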