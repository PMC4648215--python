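"""Exception hierarchy.

Every error raised by this package derives from :class:`TcrskinError`,
so callers can catch one type at pipeline level.
"""


class TcrskinError(Exception):
    """Base class for all tcrskin errors."""


class DialectError(TcrskinError):
    """Clone-table file does not conform to the declared TSV dialect."""


class ValidationError(TcrskinError):
    """A record, repertoire, or table violates a domain invariant."""


class ParameterError(TcrskinError):
    """Invalid simulation or analysis parameter."""


class GenerationError(TcrskinError):
    """Synthetic clone generation could not satisfy its constraints."""


class ComparisonError(TcrskinError):
    """Two repertoires cannot be compared (e.g. chain mismatch)."""


class PairingError(TcrskinError):
    """Samples offered as a within-patient pair do not form one."""


class InferenceError(TcrskinError):
    """Group-statistics input is degenerate or incomplete."""


class PipelineError(TcrskinError):
    """A pipeline stage failed; message carries stage and sample context."""
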