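"""Exception types shared across the package."""


class PnnQuantError(Exception):
    """Base class for all package errors."""


class GeometryError(PnnQuantError, ValueError):
    """Invalid or infeasible geometry (degenerate contour, out-of-bounds, ...)."""


class ValidationError(PnnQuantError, ValueError):
    """Invalid parameter or input structure."""


class SaturationError(PnnQuantError, ValueError):
    """All samples of a profile are at or above the saturation level."""


class UndefinedCorrelationError(PnnQuantError, ValueError):
    """Pearson correlation undefined (zero variance in a channel)."""


class DegenerateHistogramError(PnnQuantError, ValueError):
    """Otsu thresholding impossible (fewer than two distinct values)."""


class QCError(PnnQuantError, ValueError):
    """Sweep quality control left fewer sweeps than the required minimum."""
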