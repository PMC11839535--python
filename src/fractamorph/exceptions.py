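"""Exception hierarchy used across the package."""


class FractamorphError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FractamorphError, ValueError):
    """Invalid parameter or input contract violation."""


class EmptyMaskError(FractamorphError, ValueError):
    """An operation requiring foreground voxels received an empty mask."""


class VoxelBudgetError(ValidationError):
    """A requested synthetic volume exceeds the configured voxel budget."""


class DegenerateSeriesError(FractamorphError, ValueError):
    """No usable box sizes for the given mask."""


class SingularFitError(FractamorphError, ValueError):
    """The log-log regression is not identifiable."""


class EmptyROIError(FractamorphError, ValueError):
    """A requested atlas label has no voxels."""


class ShapeMismatchError(FractamorphError, ValueError):
    """Scalar map and atlas do not share a voxel grid."""


class UndefinedStatisticError(FractamorphError, ValueError):
    """A test statistic is undefined for the given summary inputs."""


class DegenerateModelError(FractamorphError, ValueError):
    """Cross-block covariance has no signal to decompose."""
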