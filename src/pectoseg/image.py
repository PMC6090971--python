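"""In-memory raster containers.

Two carriers run through the whole pipeline: :class:`GrayImage`, a 2-D
float64 intensity raster normalized to [0, 1], and :class:`BinaryMask`, a 2-D
boolean raster of the same shape. Coordinates are 0-based ``(row, col)`` with
row 0 at the top, matching raster file order; every module shares this
convention. All intensity computation happens in the normalized [0, 1]
domain so that edge thresholds tau in (0, 1) are meaningful across sources
of different bit depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ChannelError, ShapeMismatchError


@dataclass(frozen=True)
class GrayImage:
    """2-D grayscale image with intensities in [0, 1].

    Parameters
    ----------
    pixels
        2-D array-like of intensities; cast to float64. Values must already
        lie in [0, 1] (readers divide by ``2**source_depth - 1``).
    source_depth
        Bit depth of the originating file (8 or 16); retained so the image
        can be written back at its native quantization.
    """

    pixels: np.ndarray
    source_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ChannelError(
                f"GrayImage requires a 2-D single-channel raster, got ndim={px.ndim}"
            )
        if px.size == 0:
            raise ValueError("GrayImage cannot be empty")
        lo, hi = float(px.min()), float(px.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError(f"intensities must lie in [0, 1], got [{lo}, {hi}]")
        if self.source_depth not in (8, 16):
            raise ValueError(f"source_depth must be 8 or 16, got {self.source_depth}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def mirrored(self) -> "GrayImage":
        """Horizontally flipped copy (left/right MLO normalization)."""
        return GrayImage(np.fliplr(self.pixels), self.source_depth)


@dataclass(frozen=True)
class BinaryMask:
    """2-D boolean raster annotating a :class:`GrayImage` of the same shape."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ChannelError(f"BinaryMask requires a 2-D raster, got ndim={px.ndim}")
        if px.size == 0:
            raise ValueError("BinaryMask cannot be empty")
        if px.dtype != np.bool_:
            uniq = np.unique(px)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError(f"mask values must be exactly 0 or 1, got {uniq[:8]}")
            px = px.astype(bool)
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def count(self) -> int:
        """Number of foreground pixels."""
        return int(self.pixels.sum())

    def mirrored(self) -> "BinaryMask":
        return BinaryMask(np.fliplr(self.pixels))

    def __eq__(self, other: object) -> bool:  # masks compare by content
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.shape == other.shape and bool((self.pixels == other.pixels).all())

    def __hash__(self) -> int:  # content equality => not hashable by identity
        raise TypeError("BinaryMask is not hashable")


def require_same_shape(*rasters: GrayImage | BinaryMask | np.ndarray) -> None:
    """Raise :class:`ShapeMismatchError` unless all rasters share one shape."""
    shapes = [
        r.shape if isinstance(r, (GrayImage, BinaryMask)) else np.asarray(r).shape
        for r in rasters
    ]
    if len(set(shapes)) > 1:
        raise ShapeMismatchError(f"rasters must share one shape, got {shapes}")


def as_array(raster: GrayImage | BinaryMask | np.ndarray) -> np.ndarray:
    """Unwrap a container to its ndarray (pass arrays through)."""
    if isinstance(raster, (GrayImage, BinaryMask)):
        return raster.pixels
    return np.asarray(raster)
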