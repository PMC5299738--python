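from collections import Counter
from io import StringIO

import pytest

from sparqlpipe import load_config
from sparqlpipe.client import UrllibTransport
from sparqlpipe.cli import parse_args, run
from sparqlpipe.config import BUILTIN_LIBRARY_DIR
from sparqlpipe.fixtures import FixtureSpec, build_fixture, serve_loopback


@pytest.fixture(scope="session")
def config():
    return load_config()


@pytest.fixture(scope="session")
def prefixes(config):
    return config.prefixes


@pytest.fixture(scope="session")
def protein_graph():
    return build_fixture(FixtureSpec("protein_annot", 30, seed=7))


@pytest.fixture(scope="session")
def ortholog_graph():
    return build_fixture(FixtureSpec("ortholog_db", 18, seed=7))


@pytest.fixture(scope="session")
def expression_graph():
    return build_fixture(FixtureSpec("expression_db", 15, seed=7))


@pytest.fixture(scope="session")
def server(protein_graph, ortholog_graph, expression_graph):
    srv = serve_loopback(
        {"/protein": protein_graph, "/ortholog": ortholog_graph,
         "/expression": expression_graph},
        files={"/library": BUILTIN_LIBRARY_DIR})
    yield srv
    srv.close()


class SpyTransport(UrllibTransport):
    """Real HTTP transport that records every request it makes."""

    def __init__(self):
        super().__init__(timeout=10.0)
        self.calls = []

    def request(self, method, url, headers, body=None):
        self.calls.append((method, url))
        return super().request(method, url, headers, body)


class ForbiddenTransport:
    """Transport that fails the test if any request is attempted."""

    def request(self, method, url, headers, body=None):
        raise AssertionError(f"unexpected network activity: {method} {url}")


@pytest.fixture
def spy_transport():
    return SpyTransport()


@pytest.fixture
def forbidden_transport():
    return ForbiddenTransport()


@pytest.fixture
def run_cli():
    """Invoke the CLI in-process: returns (exit_code, stdout, stderr)."""

    def invoke(argv, stdin_text="", transport=None):
        out, err = StringIO(), StringIO()
        code = run(parse_args(argv), stdin=StringIO(stdin_text),
                   stdout=out, stderr=err, transport=transport)
        return code, out.getvalue(), err.getvalue()

    return invoke


def tsv_rows(text, with_header=True):
    """Parse CLI TSV output into (header, multiset of row tuples)."""
    lines = text.splitlines()
    header = None
    if with_header and lines:
        header = tuple(lines.pop(0).split("\t"))
    return header, Counter(tuple(line.split("\t")) for line in lines)
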