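"""Exception hierarchy shared across the toolkit.

All toolkit-raised errors derive from :class:`BgcMinerError` so callers (and
the command-line layer) can distinguish input problems from genuine bugs.
"""


class BgcMinerError(Exception):
    """Base class for all toolkit errors."""


class ParseError(BgcMinerError):
    """A file or expression could not be parsed; message names the position."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        parts = []
        if line is not None:
            parts.append(f"line {line}")
        if column is not None:
            parts.append(f"column {column}")
        loc = f" ({', '.join(parts)})" if parts else ""
        super().__init__(message + loc)
        self.line = line
        self.column = column


class ValidationError(BgcMinerError):
    """Input parsed but violates a documented invariant."""


class CoordinateError(ValidationError):
    """A feature or region lies outside its contig."""


class QueryError(BgcMinerError):
    """A user-supplied search pattern is invalid."""


class DegenerateMatrixError(BgcMinerError):
    """A PWM with max_score == min_score cannot be tiered."""


class LowConfidenceAlignmentError(BgcMinerError):
    """Query/reference alignment identity too low to trust signature extraction."""
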