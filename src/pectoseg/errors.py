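"""Exception hierarchy for pectoseg.

All domain errors derive from :class:`PectosegError` so callers can catch one
type; most also derive from the matching builtin (ValueError / IOError) so the
library behaves like any numpy-adjacent package when used casually.
"""


class PectosegError(Exception):
    """Base class for all pectoseg errors."""


class ImageFormatError(PectosegError, IOError):
    """File does not parse as the expected raster format."""


class ChannelError(PectosegError, ValueError):
    """Input raster is not single-channel grayscale."""


class ShapeMismatchError(PectosegError, ValueError):
    """Two rasters that must share a shape do not."""


class ConfigurationError(PectosegError, ValueError):
    """A parameter is outside its documented domain."""


class EmptyForegroundError(PectosegError, ValueError):
    """Binarization produced no foreground component."""


class DegenerateGradientError(PectosegError, ValueError):
    """Gradient magnitude is constant; no threshold separates edges."""


class DegenerateGeometryError(PectosegError, ValueError):
    """Fewer than 3 points, or all collinear: no 2-D convex hull exists."""


class EmptySilhouetteError(PectosegError, ValueError):
    """Silhouette extraction removed every foreground pixel."""


class EmptyPointSetError(PectosegError, ValueError):
    """Hausdorff distance is undefined for an empty point set."""


class EmptyCohortError(PectosegError, ValueError):
    """A cohort summary needs at least one report."""


class UndefinedRegionError(PectosegError, ValueError):
    """A percentage is undefined because its reference region is empty."""
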