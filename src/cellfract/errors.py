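"""Exception hierarchy for cellfract.

All package-specific failures derive from :class:`CellfractError` so callers
can catch one base class at pipeline boundaries.
"""


class CellfractError(Exception):
    """Base class for all cellfract errors."""


class FormatError(CellfractError):
    """An input raster or file has the wrong dtype/format."""


class SchemaError(CellfractError):
    """A tabular input is missing required columns or has bad values."""


class DimensionError(CellfractError):
    """Raster shapes or frame counts are inconsistent across a series."""


class DegenerateInputError(CellfractError):
    """An operation received input it cannot meaningfully process
    (e.g. an empty point set where two populations are required)."""


class InsufficientScaleError(CellfractError):
    """The raster is too small to support at least two box sizes."""


class UndefinedDimensionError(CellfractError):
    """Box-counting dimension requested for an empty boundary."""


class UndefinedDisplacementError(CellfractError):
    """Boundary displacement requested for an empty boundary image."""


class NoContactError(CellfractError):
    """The two populations never come within the contact threshold."""


class UndefinedSlopeError(CellfractError):
    """A regression slope is undefined (zero variance in the regressor)."""


class FitError(CellfractError):
    """Non-linear least squares failed to converge from every start."""


class ConfigurationError(CellfractError):
    """A parameter combination violates its invariants."""
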