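"""Exception and warning types used across the package."""


class TofDepthError(Exception):
    """Base class for all package-specific errors."""


class AxisError(TofDepthError, ValueError):
    """Invalid or inconsistent gate-time axis."""


class ScanFormatError(TofDepthError, ValueError):
    """A scan file is missing metadata or its shape disagrees with it."""


class DegenerateProfileError(TofDepthError, ValueError):
    """A temporal profile carries no usable pulse (flat, inverted, empty)."""


class EdgeFitError(TofDepthError, ValueError):
    """A pulse edge cannot be located or fitted unambiguously."""


class CalibrationError(TofDepthError, ValueError):
    """The calibration chain cannot be built or applied."""


class ModelResolutionWarning(UserWarning):
    """The requested model is under-resolved on the gate-step grid."""


class DataQualityWarning(UserWarning):
    """Inputs look implausible (swapped frames, empty masks, ...)."""
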