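"""Radiopaque label / marker / artifact removal.

MLO mammograms carry high-intensity machine labels and markers in the
background. The breast body is by far the largest bright connected region,
while labels are small disjoint blobs, so the clean image is obtained by
binarizing, keeping the largest connected component(s), and multiplying the
resulting mask back onto the original intensities — pixels inside the kept
region are preserved bit-exactly, everything else is set to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .errors import ConfigurationError, EmptyForegroundError
from .image import BinaryMask, GrayImage


@dataclass(frozen=True)
class LabelRemovalConfig:
    """Parameters of the label-removal binarization.

    binarize_method
        ``"otsu"`` (default, data-driven) or ``"fixed"`` (use
        ``fixed_threshold``; handy for phantoms with known intensities).
    fixed_threshold
        Intensity cut in [0, 1] used when ``binarize_method == "fixed"``.
    keep_components
        How many connected components, ranked by area, survive. The breast is
        one region, so the default is 1.
    min_area_fraction
        Components smaller than this fraction of the image area are discarded
        even if ranked within ``keep_components``.
    """

    binarize_method: str = "otsu"
    fixed_threshold: float = 0.5
    keep_components: int = 1
    min_area_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.binarize_method not in ("otsu", "fixed"):
            raise ConfigurationError(
                f"binarize_method must be 'otsu' or 'fixed', got {self.binarize_method!r}"
            )
        if not 0.0 <= self.fixed_threshold <= 1.0:
            raise ConfigurationError("fixed_threshold must lie in [0, 1]")
        if self.keep_components < 1:
            raise ConfigurationError("keep_components must be >= 1")
        if not 0.0 <= self.min_area_fraction < 1.0:
            raise ConfigurationError("min_area_fraction must lie in [0, 1)")


def remove_labels(
    image: GrayImage, cfg: LabelRemovalConfig | None = None
) -> tuple[BinaryMask, GrayImage]:
    """Strip labels and artifacts, returning ``(body_mask, clean_image)``.

    The mask is the union of the ``keep_components`` largest 8-connected
    components of the binarized image (components touching the border are
    kept — the breast always touches one border). The clean image preserves
    the original intensities inside the mask and is exactly 0 outside.

    Raises
    ------
    EmptyForegroundError
        If binarization yields no foreground component (e.g. an all-zero or
        constant image).
    """
    cfg = cfg or LabelRemovalConfig()
    px = image.pixels
    if cfg.binarize_method == "otsu":
        if float(px.max()) == float(px.min()):
            raise EmptyForegroundError("constant image: nothing to binarize")
        thr = float(threshold_otsu(px))
    else:
        thr = cfg.fixed_threshold
    fg = px > thr
    if not fg.any():
        raise EmptyForegroundError(f"no pixel exceeds threshold {thr:.4g}")

    labels = cc_label(fg, connectivity=2)
    areas = np.bincount(labels.ravel())
    areas[0] = 0  # background
    order = np.argsort(areas)[::-1]
    min_area = cfg.min_area_fraction * px.size
    keep = [
        lbl for lbl in order[: cfg.keep_components] if areas[lbl] > 0 and areas[lbl] >= min_area
    ]
    if not keep:
        raise EmptyForegroundError("every component fell below min_area_fraction")
    mask = np.isin(labels, keep)
    clean = np.where(mask, px, 0.0)
    return BinaryMask(mask), GrayImage(clean, image.source_depth)
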