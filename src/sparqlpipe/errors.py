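"""Exception hierarchy with stable CLI exit codes.

Every error raised by the library maps to one of five classes so that
shell pipelines can branch on the exit status of the ``spq`` command.
"""


class SparqlPipeError(Exception):
    """Base class; generic failures exit with code 1."""

    exit_code = 1


class UsageError(SparqlPipeError):
    """Bad command line (unknown flag, ambiguous mode)."""

    exit_code = 1


class ConfigError(SparqlPipeError):
    """Unreadable or malformed configuration, undeclared prefix on expansion."""

    exit_code = 2


class GenerationError(SparqlPipeError):
    """Query generation failed: term classification, template arity,
    or an instantiated query that does not parse as SPARQL."""

    exit_code = 3


class ResolutionError(SparqlPipeError):
    """Unknown endpoint nickname or template not found anywhere."""

    exit_code = 4


class TransportError(SparqlPipeError):
    """HTTP-level failure talking to an endpoint or template library."""

    exit_code = 5


class FormatError(SparqlPipeError):
    """Malformed input/output data: ragged TSV, unparseable result set,
    or a value that cannot be represented in TSV."""

    exit_code = 6
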