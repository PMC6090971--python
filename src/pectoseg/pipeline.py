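"""End-to-end orchestration of the segmentation flow.

Stage order: label/artifact removal -> gradient -> threshold selection ->
edge map -> morphological closing -> topographic map -> convex hull ->
pectoral boundary -> shape-shift -> intensity mapping. Every intermediate
raster is retained on the result object so the exact stage panel sequence
can be dumped for inspection.

Orientation: processing assumes the pectoral corner is top-left. Right-MLO
inputs are mirrored before processing and every output raster is mirrored
back, so results are reported in the input's own frame. ``auto`` detection
compares foreground mass in the left vs right image halves.

One detail the closed edge map forces: the breast skin line is itself an
edge path from the top border to the left border, and the strongest one. The
pectoral boundary search is therefore restricted to edges in the *interior*
of the body mask (mask eroded by ``close_radius + 4``), which excludes the
skin line — the outer boundary is recovered by the convex hull instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np
from skimage.measure import label as cc_label

from . import gradient as grad_mod
from . import morphology, silhouette
from .errors import ConfigurationError, PectosegError
from .gradient import EdgeMap, GradientField
from .image import BinaryMask, GrayImage
from .preprocess import LabelRemovalConfig, remove_labels

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Every free parameter of the pipeline in one place.

    close_radius
        Disk radius of the closing element; ``None`` scales the 5 px /
        1024-row default proportionally to the image height (min 1).
    interior_margin
        Erosion radius restricting the pectoral-boundary search to the body
        interior; ``None`` means ``close_radius + 4``.
    min_region_fraction
        Connected components of the removed (pectoral) region smaller than
        this fraction of the image area are treated as rasterization specks
        and dropped.
    seed
        Reserved for stochastic tie-breaking; the default path is fully
        deterministic.
    """

    label_cfg: LabelRemovalConfig = field(default_factory=LabelRemovalConfig)
    operator: str = "prewitt"
    tau: float | None = None
    edge_fraction: float = 0.10
    close_radius: int | None = None
    orientation: str = "auto"  # {"auto", "left", "right"}
    interior_margin: int | None = None
    min_region_fraction: float = 0.002
    seed: int = 0

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        """Build a config from a YAML/JSON-style mapping."""
        data = dict(data)
        label_data = data.pop("label_cfg", None)
        cfg = cls(**data)
        if label_data is not None:
            cfg = replace(cfg, label_cfg=LabelRemovalConfig(**label_data))
        return cfg


@dataclass(frozen=True)
class SegmentationResult:
    """All intermediate and final rasters of one pipeline run."""

    original: GrayImage
    label_mask: BinaryMask
    clean: GrayImage
    gradient: GradientField
    edge_raw: EdgeMap
    edge_closed: BinaryMask
    hull: silhouette.HullImage
    pectoral_curve: np.ndarray
    silhouette: BinaryMask
    segmented: GrayImage
    pectoral_mask: BinaryMask
    mirrored: bool
    config: PipelineConfig


def _auto_mirror(image: GrayImage) -> bool:
    """True if the breast sits on the right half (image needs mirroring)."""
    px = image.pixels
    thr = px.mean()
    fg = px > thr
    half = image.width // 2
    return bool(fg[:, half:].sum() > fg[:, :half].sum())


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, PectosegError):
                exc.args = (f"stage '{name}': {exc.args[0] if exc.args else ''}",)
            return False

    return _Ctx()


def _prune_specks(mask: np.ndarray, min_area: float) -> np.ndarray:
    if not mask.any():
        return mask
    labels = cc_label(mask, connectivity=2)
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    keep = np.flatnonzero(areas >= min_area)
    return np.isin(labels, keep)


def segment(image: GrayImage, cfg: PipelineConfig | None = None) -> SegmentationResult:
    """Run the full pectoral-removal pipeline on one MLO image.

    Deterministic: identical input and config give bit-identical results.
    Stage failures propagate as the stage's own error type with the stage
    name attached to the message.
    """
    cfg = cfg or PipelineConfig()
    if cfg.orientation == "auto":
        mirrored = _auto_mirror(image)
    elif cfg.orientation in ("left", "right"):
        mirrored = cfg.orientation == "right"
    else:
        raise ConfigurationError(
            f"orientation must be 'auto', 'left' or 'right', got {cfg.orientation!r}"
        )
    work = image.mirrored() if mirrored else image

    close_radius = cfg.close_radius
    if close_radius is None:
        close_radius = max(1, round(5 * work.height / 1024))
    interior_margin = cfg.interior_margin
    if interior_margin is None:
        interior_margin = close_radius + 4

    with _stage("remove_labels"):
        label_mask, clean = remove_labels(work, cfg.label_cfg)
    logger.info("remove_labels: %d foreground px", label_mask.count())

    with _stage("gradient"):
        grad = grad_mod.gradient(clean, cfg.operator)
    with _stage("select_threshold"):
        tau = cfg.tau if cfg.tau is not None else grad_mod.select_threshold(
            grad, cfg.edge_fraction
        )
    with _stage("edge_map"):
        edges = grad_mod.edge_map(grad, tau)
    logger.info("edge_map: tau=%.4g, %d edge px", tau, edges.pixels.count())

    with _stage("close"):
        se = morphology.disk(close_radius)
        edge_closed = morphology.close(edges.pixels, se)
    logger.info("close: radius=%d, %d px", close_radius, edge_closed.count())

    with _stage("topographic_map"):
        # Border-replicated convolution is gradient-silent where the breast
        # is flush with the image frame, so the skin line's continuation
        # along the frame never appears in the edge map. Add the body-mask
        # pixels on the frame as hull features; without them the hull clips
        # border-flush breast margins.
        frame = np.zeros(work.shape, dtype=bool)
        frame[[0, -1], :] = True
        frame[:, [0, -1]] = True
        hull_features = BinaryMask(edge_closed.pixels | (label_mask.pixels & frame))
        tmap = silhouette.topographic_map(hull_features)
    with _stage("convex_hull"):
        hull = silhouette.convex_hull(tmap)
    logger.info("convex_hull: %d vertices, %d px", len(hull.polygon), hull.filled.count())

    with _stage("pectoral_boundary"):
        interior = morphology.erode(label_mask, morphology.disk(interior_margin))
        internal_edges = BinaryMask(edge_closed.pixels & interior.pixels)
        curve = silhouette.pectoral_boundary(
            internal_edges,
            orientation="left",
            support=grad.magnitude,
            border_margin=interior_margin + 2,
        )
    logger.info("pectoral_boundary: %d curve rows", len(curve))

    with _stage("shape_shift"):
        sil = silhouette.shape_shift(hull, label_mask, curve)
    with _stage("apply_silhouette"):
        segmented = silhouette.apply_silhouette(sil, clean)

    # Removed (pectoral) region: body-mask pixels outside the silhouette, but
    # only components that overlap the wedge the pectoral curve actually cut
    # away — pixels lost purely to hull rasterization at border-flush breast
    # margins are not pectoral muscle.
    removed = label_mask.pixels & ~sil.pixels
    wedge = np.zeros_like(removed)
    for r, c in curve:
        wedge[r, :c] = True
    if removed.any() and wedge.any():
        labels = cc_label(removed, connectivity=2)
        keep = np.unique(labels[wedge & (labels > 0)])
        pect = np.isin(labels, keep[keep > 0])
    else:
        pect = np.zeros_like(removed)
    pect = _prune_specks(pect, cfg.min_region_fraction * work.pixels.size)
    logger.info("pectoral_mask: %d px", int(pect.sum()))

    result = SegmentationResult(
        original=work,
        label_mask=label_mask,
        clean=clean,
        gradient=grad,
        edge_raw=edges,
        edge_closed=edge_closed,
        hull=hull,
        pectoral_curve=curve,
        silhouette=sil,
        segmented=segmented,
        pectoral_mask=BinaryMask(pect),
        mirrored=mirrored,
        config=cfg,
    )
    if mirrored:
        result = _mirror_result(result, image)
    return result


def _mirror_result(res: SegmentationResult, original: GrayImage) -> SegmentationResult:
    """Flip every raster back into the input's frame."""
    w = original.width
    curve = res.pectoral_curve.copy()
    if len(curve):
        curve[:, 1] = w - 1 - curve[:, 1]
    flipped_grad = GradientField(
        gx=-np.fliplr(res.gradient.gx),
        gy=np.fliplr(res.gradient.gy),
        magnitude=np.fliplr(res.gradient.magnitude),
        l1_magnitude=np.fliplr(res.gradient.l1_magnitude),
        angle=np.fliplr(res.gradient.angle),
        scale=res.gradient.scale,
    )
    return SegmentationResult(
        original=original,
        label_mask=res.label_mask.mirrored(),
        clean=res.clean.mirrored(),
        gradient=flipped_grad,
        edge_raw=EdgeMap(res.edge_raw.pixels.mirrored(), res.edge_raw.tau),
        edge_closed=res.edge_closed.mirrored(),
        hull=silhouette.HullImage(
            polygon=np.column_stack(
                [res.hull.polygon[:, 0], w - 1 - res.hull.polygon[:, 1]]
            ),
            filled=res.hull.filled.mirrored(),
        ),
        pectoral_curve=curve,
        silhouette=res.silhouette.mirrored(),
        segmented=res.segmented.mirrored(),
        pectoral_mask=res.pectoral_mask.mirrored(),
        mirrored=res.mirrored,
        config=res.config,
    )
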