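"""Exception hierarchy for the gammase pipeline.

Every error raised by the package derives from :class:`GammaseError` so
callers can catch pipeline failures with a single except clause while the
concrete subclasses keep the failure modes distinguishable in tests.
"""


class GammaseError(Exception):
    """Base class for all gammase errors."""


class ParseError(GammaseError):
    """A text input could not be parsed; the message names the line."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class DuplicateSampleError(ParseError):
    """The same (channel, sample index) pair appeared twice in a trial file."""


class IncompleteChannelError(GammaseError):
    """A channel is missing samples (or the file contains no data at all)."""


class FormatError(GammaseError):
    """An on-disk container violates the gammase text format."""


class InvariantError(GammaseError):
    """An in-memory object violates one of its declared invariants."""


class CalibrationError(GammaseError):
    """The requested synthetic effect size cannot be realized."""


class DesignError(GammaseError):
    """A digital filter design is infeasible or unstable."""


class LengthError(GammaseError):
    """An input sequence is too short for the requested operation."""


class DegenerateSpectrumError(GammaseError):
    """All in-band spectral power is zero; entropy is undefined."""


class BandTooNarrowError(GammaseError):
    """Fewer than two spectral bins fall inside the requested band."""


class DegenerateSamplesError(GammaseError):
    """A statistic is undefined for the given samples (e.g. zero variance)."""


class SizeError(GammaseError):
    """Too few samples/epochs for the requested computation."""


class GroupingError(GammaseError):
    """Both subject groups must be present with at least two epochs each."""


class ParameterError(GammaseError):
    """An evaluation parameter (N, d, k, split fraction) is out of range."""
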