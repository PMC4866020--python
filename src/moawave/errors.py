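"""Exception hierarchy shared across the package."""


class MoawaveError(Exception):
    """Base class for all package-specific errors."""


class EmptyInputError(MoawaveError, ValueError):
    """An operation received an empty vector or list."""


class InvalidBackgroundError(MoawaveError, ValueError):
    """Background impedance is non-positive at some frequency."""


class NonPositiveReferenceError(MoawaveError, ValueError):
    """Cell index at the treatment time point is not strictly positive."""


class InsufficientDataError(MoawaveError, ValueError):
    """Too few samples for the requested operation (e.g. spline fitting)."""


class ExtrapolationError(MoawaveError, ValueError):
    """Requested grid extends beyond the observed time span."""


class GridError(MoawaveError, ValueError):
    """A time point does not lie on the curve's sampling grid."""


class RangeError(MoawaveError, ValueError):
    """A parameter is outside its documented range."""


class ShapeError(MoawaveError, ValueError):
    """Array dimensionalities or lengths do not line up."""


class DegenerateLabelsError(MoawaveError, ValueError):
    """Training labels contain a single class."""


class StratificationError(MoawaveError, ValueError):
    """A cluster is too small to be split into train and test parts."""


class CoverageError(MoawaveError, ValueError):
    """A tree grouping references a cluster label absent from the data."""


class StructureSpecError(MoawaveError, ValueError):
    """A nested grouping specification is malformed."""


class ConfigError(MoawaveError, ValueError):
    """A configuration value violates a module precondition."""
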