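"""Exception types raised across the pipeline.

Every failure mode that a caller can reasonably branch on gets its own
class; generic ValueError is reserved for programming errors.
"""


class SpectrodictError(Exception):
    """Base class for all package-specific errors."""


class AudioDecodeError(SpectrodictError):
    """The audio file could not be read or decoded."""


class EmptyAudioError(SpectrodictError):
    """The audio file decoded to zero samples."""


class TooShortError(SpectrodictError):
    """Input has too few samples/frames for the requested operation."""


class DegenerateInputError(SpectrodictError):
    """Input is valid in shape but degenerate in content (e.g. all zeros)."""


class ZeroNormError(SpectrodictError):
    """A direction-based computation received a zero-norm vector."""


class DimensionMismatchError(SpectrodictError):
    """Model/dictionary dimensionality does not match the supplied data."""


class ModeMismatchError(SpectrodictError):
    """Classifier label mode is incompatible with the annotations."""


class UndefinedMetricError(SpectrodictError):
    """An evaluation statistic is undefined for the given labels."""
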