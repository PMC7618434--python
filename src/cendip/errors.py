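"""Exception hierarchy for cendip.

Every error raised on malformed input or degenerate data derives from
:class:`CendipError` so callers can catch pipeline problems in one place.
"""


class CendipError(Exception):
    """Base class for all cendip errors."""


class ParseError(CendipError):
    """A line in an input file could not be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class RangeError(CendipError):
    """A numeric value fell outside its permitted range."""


class ConsistencyError(CendipError):
    """Internally inconsistent record (e.g. block count != number of blocks)."""


class CoordinateError(CendipError):
    """A coordinate fell outside the span it must lie in."""


class NoDataError(CendipError):
    """An operation needed signal but the input was entirely missing."""


class ConfigurationError(CendipError):
    """Invalid configuration (unknown mod code, missing input, bad parameter)."""


class IncompatibilityError(CendipError):
    """Two inputs that must share a frame (region, bin size) do not."""


class NoPeakError(CendipError):
    """A profile contained no signal above background."""


class NoSignalError(CendipError):
    """A seed region carried zero or missing signal everywhere."""


class DegenerateDomainError(CendipError):
    """Seeded expansion could not leave the seed midpoint.

    Carries the zero-width interval at the midpoint in ``interval``.
    """

    def __init__(self, message: str, interval=None):
        super().__init__(message)
        self.interval = interval


class UndefinedRatioError(CendipError):
    """A ratio with a zero denominator was requested without a fallback."""
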