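"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigurationError -> 2,
ParseError -> 3, InternalError -> 4.
"""


class SpliceFansError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SpliceFansError):
    """Invalid configuration or unsatisfiable parameter combination."""


class ParseError(SpliceFansError):
    """Malformed input file; carries file and line context when known."""

    def __init__(self, message: str, path=None, line_no=None):
        ctx = ""
        if path is not None:
            ctx = f" [{path}" + (f":{line_no}" if line_no is not None else "") + "]"
        super().__init__(message + ctx)
        self.path = path
        self.line_no = line_no


class ConsistencyError(SpliceFansError):
    """Inputs that disagree with each other (e.g. conflicting replicate metadata)."""


class InternalError(SpliceFansError):
    """Invariant violation inside the pipeline; indicates a bug, not bad input."""
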