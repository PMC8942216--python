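"""Exception hierarchy shared across the pipeline stages."""


class WoundmetryError(Exception):
    """Base class for all package errors."""


class ConfigurationError(WoundmetryError):
    """A stage was configured inconsistently (bad pattern, leaky split, ...)."""


class InputError(WoundmetryError, ValueError):
    """An input array/series violates a stage precondition."""


class AnnotationError(WoundmetryError, ValueError):
    """A polygon annotation or annotation document is invalid."""


class CalibrationError(WoundmetryError):
    """Area calibration is impossible (no splint-inner pixels available)."""


class ImputationError(WoundmetryError):
    """Splint imputation is impossible (no record has a detected splint)."""


class UndefinedCorrelationError(WoundmetryError):
    """Correlation requested on a constant series."""
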