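"""Exception and warning types shared across the pipeline."""


class CollateralTimeError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(CollateralTimeError, ValueError):
    """Invalid parameter value or inconsistent configuration."""


class GridMismatchError(CollateralTimeError, ValueError):
    """Volumes that must share a voxel grid do not."""


class GeometryError(CollateralTimeError, ValueError):
    """A region of interest does not intersect the image grid."""


class FormatError(CollateralTimeError, ValueError):
    """On-disk data is structurally inconsistent (frames vs. timestamps, ...)."""


class ArrivalNotFoundError(CollateralTimeError):
    """The arterial curve never rises above baseline by the required margin."""


class EquilibriumNotFoundError(CollateralTimeError):
    """The AV enhancement ratio never crosses 1 after its peak."""


class DegenerateCurveError(CollateralTimeError):
    """The AV ratio curve is too flat to normalize (peak ratio at 1)."""


class LandmarkNotFoundError(CollateralTimeError):
    """A time-intensity curve has no valid sample to place a landmark on."""


class AlignmentInfeasibleError(CollateralTimeError):
    """No candidate offset keeps all mCTA volumes inside the valid CTP range."""


class DegenerateAlignmentWarning(UserWarning):
    """The CTP AV-ratio curve is flat; the alignment offset is arbitrary."""
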