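"""Binary morphology with a disk structuring element.

Closing (dilation followed by erosion with the same disk) seals the broken
edge boundaries left by thresholding. Border policy: pixels outside the
image count as background for dilation and as foreground for erosion — the
convention under which a full mask erodes to itself and closing stays
extensive and idempotent at the image frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk as _disk_footprint

from .errors import ConfigurationError
from .image import BinaryMask


@dataclass(frozen=True)
class StructuringElement:
    """Disk-shaped structuring element ``{(r, c): r^2 + c^2 <= radius^2}``."""

    radius: int
    shape: str = "disk"
    footprint: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.shape != "disk":
            raise ConfigurationError(f"only 'disk' elements are supported, got {self.shape!r}")
        if self.radius < 1:
            raise ConfigurationError(f"radius must be >= 1, got {self.radius}")
        object.__setattr__(self, "footprint", _disk_footprint(self.radius).astype(bool))


def disk(radius: int) -> StructuringElement:
    """Convenience constructor for a disk element."""
    return StructuringElement(radius=radius)


def dilate(mask: BinaryMask, se: StructuringElement) -> BinaryMask:
    """Union of translates of the mask by every element offset (output >= input)."""
    out = ndimage.binary_dilation(mask.pixels, structure=se.footprint, border_value=0)
    return BinaryMask(out)


def erode(mask: BinaryMask, se: StructuringElement) -> BinaryMask:
    """Pixels whose entire (in-image) translated footprint lies in the mask.

    Off-image footprint positions count as foreground, so a full mask erodes
    to itself; away from borders this is the exact dual of :func:`dilate`.
    """
    out = ndimage.binary_erosion(mask.pixels, structure=se.footprint, border_value=1)
    return BinaryMask(out)


def close(mask: BinaryMask, se: StructuringElement) -> BinaryMask:
    """Morphological closing: erode(dilate(mask)). Extensive and idempotent."""
    return erode(dilate(mask, se), se)
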