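"""Exception hierarchy for kindleeg."""


class KindleEGError(Exception):
    """Base class for all kindleeg errors."""


class ConfigurationError(KindleEGError):
    """Invalid simulation or analysis configuration."""


class CalibrationError(KindleEGError):
    """Invalid generator calibration (e.g. band fractions not summing to 1)."""


class SchedulingError(KindleEGError):
    """Overlapping or otherwise inconsistent event schedule."""


class InsufficientDataError(KindleEGError):
    """Record shorter than the analysis window requires."""


class ParameterError(KindleEGError):
    """Out-of-range analysis parameter."""


class AnnotationError(KindleEGError):
    """Malformed event annotations (unsorted or overlapping intervals)."""


class DegenerateInputError(KindleEGError):
    """Statistical input with no usable variation (constant sample, n too small)."""


class UndefinedRatioError(KindleEGError):
    """Theta/alpha ratio requested with zero alpha power."""


class UndefinedFractionError(KindleEGError):
    """Band fractions requested for a spectrum with zero total power."""
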