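"""Exception hierarchy shared across maskqc modules.

Everything raised deliberately by the library derives from :class:`MaskqcError`,
so the CLI can map library failures to a single data-error exit code while
programming errors still surface as ordinary exceptions.
"""


class MaskqcError(Exception):
    """Base class for all errors raised by maskqc."""


class FastqParseError(MaskqcError):
    """Malformed FASTQ input. Carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class EncodingError(MaskqcError):
    """Quality string inconsistent with the declared PHRED encoding."""


class QualityRangeError(MaskqcError):
    """PHRED score outside the representable range of an encoding."""


class UndefinedRateError(MaskqcError):
    """A rate whose denominator is zero."""


class DegenerateTableError(MaskqcError):
    """A contingency table with a zero margin or no observations."""


class SimulationError(MaskqcError):
    """Invalid simulation configuration or insufficient eligible sites."""


class EvaluationError(MaskqcError):
    """Inconsistent inputs to pileup/calling (missing placement, bad offset)."""
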