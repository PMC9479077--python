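"""Exception types raised across the package."""


class FlimRedoxError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(FlimRedoxError, ValueError):
    """A model or acquisition parameter is out of range or non-finite."""


class PlacementError(FlimRedoxError, RuntimeError):
    """Cell layout could not be realised without overlap within the attempt budget."""


class LowPhotonError(FlimRedoxError, ValueError):
    """Histogram has too few photons for a reliable bi-exponential fit."""


class EmptyMaskError(FlimRedoxError, ValueError):
    """ROI mask contains no pixels."""


class EmptyGroupError(FlimRedoxError, ValueError):
    """No usable (converged) records in a group."""


class InsufficientSampleError(FlimRedoxError, ValueError):
    """Group too small for the statistical decision tree (needs n >= 3)."""


class UndefinedRatioError(FlimRedoxError, ValueError):
    """A redox ratio has a zero denominator."""
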