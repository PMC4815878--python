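"""Exception hierarchy shared across the pipeline stages."""


class VsaxsError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(VsaxsError, ValueError):
    """A parameter or input object violates a precondition."""


class InsufficientDataError(VsaxsError):
    """Too few usable data points (pixels, pairs, bins) for the operation."""


class GridMismatchError(VsaxsError):
    """Profiles on different q grids cannot be combined."""


class EmptyProfileError(VsaxsError):
    """Azimuthal integration found no usable pixels."""


class FitError(VsaxsError):
    """A least-squares or Guinier fit could not be performed."""


class NoGuinierRegionError(FitError):
    """ln I vs q^2 has non-negative slope: no Guinier regime in the data."""


class DegenerateModelError(VsaxsError):
    """A model profile is identically zero on the fitted range."""


class RangeError(VsaxsError):
    """Requested q*r range falls outside the database's dimensionless grid."""


class ParseError(VsaxsError):
    """A structure or profile file could not be parsed."""
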