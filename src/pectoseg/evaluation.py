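"""Scoring a segmentation against ground truth.

The ground truth and the prediction each partition the image into a
pectoral and a non-pectoral region. Overlap cardinalities of the 2x2
partition pairs give TP / TN / FP / FN; FP% is the false-positive count
relative to the ground-truth *negative* region, FN% relative to the
ground-truth *positive* (pectoral) region. (fp%, fn%) pairs fall into seven
mutually exclusive category bins, boundary values binned left-closed.
Boundary agreement is measured by the symmetric Hausdorff distance in mm
(Euclidean, default pixel spacing 0.2 mm/px — 200-micron digitization); the
one-directional variant is available via ``directed=``. Visual quality maps
to a three-level grade from the residual pectoral fraction left inside the
silhouette: <= 1% successful, < 50% acceptable, >= 50% unacceptable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import directed_hausdorff
from skimage.segmentation import find_boundaries

from .errors import EmptyCohortError, EmptyPointSetError, UndefinedRegionError
from .image import BinaryMask, require_same_shape
from .pipeline import SegmentationResult

CATEGORY_LABELS: dict[int, str] = {
    1: "FP < 5% and FN < 5%",
    2: "min(FP,FN) < 5% and 5% <= max(FP,FN) < 10%",
    3: "min(FP,FN) < 5% and max(FP,FN) >= 10%",
    4: "5% <= FP < 10% and 5% <= FN < 10%",
    5: "5% <= min(FP,FN) < 10% and max(FP,FN) >= 10%",
    6: "FP >= 10% and FN >= 10%",
    7: "uncategorized",
}

GRADES = ("successful", "acceptable", "unacceptable")


@dataclass(frozen=True)
class ConfusionCells:
    """Pixel overlap cardinalities of the ground-truth vs predicted partitions."""

    w11: int  # TP: pectoral in both
    w12: int  # TN: pectoral in neither
    w21: int  # FP: predicted pectoral, ground truth negative
    w22: int  # FN: ground-truth pectoral, prediction negative
    fp_pct: float
    fn_pct: float


@dataclass(frozen=True)
class EvalReport:
    """Per-image evaluation: cells, Hausdorff (mm), category bin, grade."""

    cells: ConfusionCells
    hausdorff_mm: float
    category: int
    grade: str


@dataclass(frozen=True)
class CohortSummary:
    """Cohort aggregate mirroring the per-category performance table layout."""

    n_images: int
    fp_mean: float
    fn_mean: float
    bin_percentages: tuple[float, ...]  # 7 entries, summing to 100
    hd_mean: float
    hd_std: float


def confusion(gt: BinaryMask, seg: BinaryMask) -> ConfusionCells:
    """Overlap counts of the 2x2 partition pairs plus FP% / FN%.

    Raises
    ------
    UndefinedRegionError
        Empty ground-truth positive (or negative) region — the corresponding
        percentage is undefined.
    """
    require_same_shape(gt, seg)
    g, s = gt.pixels, seg.pixels
    tp = int((g & s).sum())
    tn = int((~g & ~s).sum())
    fp = int((s & ~g).sum())
    fn = int((g & ~s).sum())
    n_pos = tp + fn
    n_neg = tn + fp
    if n_pos == 0:
        raise UndefinedRegionError("empty ground-truth pectoral region: FN% undefined")
    if n_neg == 0:
        raise UndefinedRegionError("empty ground-truth negative region: FP% undefined")
    return ConfusionCells(
        w11=tp, w12=tn, w21=fp, w22=fn,
        fp_pct=100.0 * fp / n_neg,
        fn_pct=100.0 * fn / n_pos,
    )


def hausdorff(a: np.ndarray, b: np.ndarray, directed: bool = False) -> float:
    """Hausdorff distance between two finite point sets (Euclidean metric).

    Symmetric by default: max of the two directed max-min distances. Points
    are (N, 2) arrays of coordinates.
    """
    a = np.asarray(a, dtype=float).reshape(-1, 2)
    b = np.asarray(b, dtype=float).reshape(-1, 2)
    if a.size == 0 or b.size == 0:
        raise EmptyPointSetError("Hausdorff distance needs two nonempty point sets")
    d_ab = directed_hausdorff(a, b)[0]
    if directed:
        return float(d_ab)
    d_ba = directed_hausdorff(b, a)[0]
    return float(max(d_ab, d_ba))


def boundary_points(mask: BinaryMask) -> np.ndarray:
    """(N, 2) coordinates of the inner boundary pixels of a mask."""
    return np.argwhere(find_boundaries(mask.pixels, mode="inner"))


def categorize(cells: ConfusionCells | tuple[float, float]) -> int:
    """Map (FP%, FN%) to its category bin 1..7 (left-closed boundaries)."""
    if isinstance(cells, ConfusionCells):
        fp, fn = cells.fp_pct, cells.fn_pct
    else:
        fp, fn = cells
    lo, hi = min(fp, fn), max(fp, fn)
    if hi < 5:
        return 1
    if lo < 5 and hi < 10:
        return 2
    if lo < 5:  # hi >= 10
        return 3
    if hi < 10:  # both in [5, 10)
        return 4
    if lo < 10:  # hi >= 10
        return 5
    if lo >= 10:
        return 6
    return 7  # unreachable by construction; kept so the bins are total


def grade(result: SegmentationResult | BinaryMask, gt_pectoral: BinaryMask) -> str:
    """Three-level visual grade from the residual pectoral fraction.

    ``result`` may be a full :class:`SegmentationResult` or the silhouette
    mask itself. The residual is the fraction of the ground-truth pectoral
    region still inside the silhouette: <= 1% -> successful (no undesired
    parts, up to rasterization), >= 50% (half or more of the muscle left) ->
    unacceptable, in between -> acceptable.
    """
    sil = result.silhouette if isinstance(result, SegmentationResult) else result
    require_same_shape(sil, gt_pectoral)
    n_gt = gt_pectoral.count()
    if n_gt == 0:
        raise UndefinedRegionError("empty ground-truth pectoral region: grade undefined")
    residual = (sil.pixels & gt_pectoral.pixels).sum() / n_gt
    if residual <= 0.01:
        return "successful"
    if residual < 0.5:
        return "acceptable"
    return "unacceptable"


def evaluate(
    result: SegmentationResult,
    gt_pectoral: BinaryMask,
    pixel_spacing_mm: float = 0.2,
) -> EvalReport:
    """Score one pipeline run against a ground-truth pectoral mask."""
    cells = confusion(gt_pectoral, result.pectoral_mask)
    hd_px = hausdorff(
        boundary_points(gt_pectoral), boundary_points(result.pectoral_mask)
    )
    return EvalReport(
        cells=cells,
        hausdorff_mm=hd_px * pixel_spacing_mm,
        category=categorize(cells),
        grade=grade(result, gt_pectoral),
    )


def summarize(reports: Sequence[EvalReport] | Iterable[EvalReport]) -> CohortSummary:
    """Aggregate per-image reports: means, bin percentages, HD mean +- std.

    FP/FN means are per-image means of the pixel percentages; the Hausdorff
    std is the population standard deviation.
    """
    reports = list(reports)
    if not reports:
        raise EmptyCohortError("cannot summarize an empty cohort")
    fp = np.array([r.cells.fp_pct for r in reports])
    fn = np.array([r.cells.fn_pct for r in reports])
    hd = np.array([r.hausdorff_mm for r in reports])
    cats = np.array([r.category for r in reports])
    bins = tuple(100.0 * float((cats == k).sum()) / len(reports) for k in range(1, 8))
    return CohortSummary(
        n_images=len(reports),
        fp_mean=float(fp.mean()),
        fn_mean=float(fn.mean()),
        bin_percentages=bins,
        hd_mean=float(hd.mean()),
        hd_std=float(hd.std()),
    )
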