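"""Topographic feature map, convex hull, and silhouette extraction.

This is the heart of the method. From the closed edge map a *topographic
map* is built: for every occupied row its leftmost and rightmost foreground
pixel, and for every occupied column its topmost and bottommost one (the
"four-corner" feature set). The convex hull of that point set rasterizes to
a hull image with a shape-shifting property: intersected with the breast
body mask it reproduces the breast outline, and removing the chest-wall side
of the detected pectoral boundary curve leaves the silhouette of the breast
body without the pectoral muscle. Mapping the silhouette back onto the clean
grayscale image restores the original intensities inside the breast area.

Orientation convention: all operations assume the pectoral corner is
top-left (right-MLO inputs are mirrored by the pipeline before this stage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import label as cc_label
from skimage.morphology import convex_hull_image

from .errors import (
    DegenerateGeometryError,
    EmptySilhouetteError,
)
from .image import BinaryMask, GrayImage, require_same_shape


@dataclass(frozen=True)
class TopographicMap:
    """Extremal foreground feature points of a binary image.

    ``points`` is an (N, 2) integer array of (row, col) coordinates in raster
    order; ``source_shape`` the shape of the mask it came from.
    """

    points: np.ndarray
    source_shape: tuple[int, int]


@dataclass(frozen=True)
class HullImage:
    """Convex hull of a topographic map: vertex polygon + filled raster."""

    polygon: np.ndarray  # (V, 2) float (row, col), counter-clockwise
    filled: BinaryMask


def _collinear(points: np.ndarray) -> bool:
    p0 = points[0].astype(float)
    d = points[1:].astype(float) - p0
    cross = d[0, 0] * d[:, 1] - d[0, 1] * d[:, 0]
    if not np.allclose(cross, 0.0):
        return False
    # first direction may itself be degenerate; check all pairs against any
    # nonzero direction
    for i in range(len(d)):
        if d[i].any():
            cross = d[i, 0] * d[:, 1] - d[i, 1] * d[:, 0]
            return bool(np.allclose(cross, 0.0))
    return True


def topographic_map(mask: BinaryMask) -> TopographicMap:
    """Per-row/per-column extremal pixels of the foreground, deduplicated.

    Raises
    ------
    DegenerateGeometryError
        Fewer than 3 foreground pixels, or all foreground collinear (no 2-D
        hull exists).
    """
    m = mask.pixels
    rows, cols = np.nonzero(m)
    if rows.size < 3:
        raise DegenerateGeometryError(f"need >= 3 foreground pixels, got {rows.size}")
    pts: set[tuple[int, int]] = set()
    for r in np.unique(rows):
        cr = cols[rows == r]
        pts.add((int(r), int(cr.min())))
        pts.add((int(r), int(cr.max())))
    for c in np.unique(cols):
        rc = rows[cols == c]
        pts.add((int(rc.min()), int(c)))
        pts.add((int(rc.max()), int(c)))
    points = np.array(sorted(pts), dtype=int)
    if len(points) < 3 or _collinear(points):
        raise DegenerateGeometryError("foreground is collinear; no 2-D hull exists")
    return TopographicMap(points=points, source_shape=mask.shape)


def convex_hull(tmap: TopographicMap) -> HullImage:
    """Minimal convex polygon containing the map, with its filled raster.

    The filled raster is the rasterization of the hull polygon and covers
    every input point.
    """
    try:
        hull = ConvexHull(tmap.points.astype(float))
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point set: {exc}") from exc
    polygon = tmap.points[hull.vertices].astype(float)
    canvas = np.zeros(tmap.source_shape, dtype=bool)
    canvas[tmap.points[:, 0], tmap.points[:, 1]] = True
    filled = convex_hull_image(canvas)
    return HullImage(polygon=polygon, filled=BinaryMask(filled))


def pectoral_boundary(
    edges: BinaryMask,
    orientation: str = "left",
    support: np.ndarray | None = None,
    border_margin: int = 3,
) -> np.ndarray:
    """Locate the pectoral boundary curve in a closed edge map.

    Candidates are 8-connected edge components that reach both the top image
    border and the left image border (within ``border_margin`` pixels) and
    whose row span covers at least 1/8 of the image height — the pectoral
    boundary always descends a substantial fraction of the view, and the
    span floor rejects corner noise specks that touch both borders
    trivially. Among candidates the one with the largest mean gradient
    ``support`` wins, ties going to the smaller (shorter-path) component. The curve is returned
    top-to-bottom as an (K, 2) array of (row, col): for each row the
    component spans, its rightmost column. An empty (0, 2) array means no
    pectoral boundary exists (pectoral-free image) — a valid outcome, not an
    error.

    The boundary is a free curve, not a fitted straight line, so bowed
    pectoral edges are followed as-is.
    """
    flip = orientation == "right"
    m = np.fliplr(edges.pixels) if flip else edges.pixels
    sup = None
    if support is not None:
        require_same_shape(edges, support)
        sup = np.fliplr(support) if flip else np.asarray(support, dtype=float)

    labels = cc_label(m, connectivity=2)
    n = labels.max()
    min_span = max(4, edges.height // 8)
    best_curve: np.ndarray | None = None
    best_key: tuple[float, float] | None = None
    for lbl in range(1, n + 1):
        comp = labels == lbl
        rr, cc = np.nonzero(comp)
        if rr.min() >= border_margin or cc.min() >= border_margin:
            continue  # does not connect top border to left border
        if rr.max() - rr.min() < min_span:
            continue  # corner speck, not a descending boundary
        score = float(sup[comp].mean()) if sup is not None else 0.0
        key = (-score, float(rr.size))  # max support, then shorter
        if best_key is None or key < best_key:
            best_key = key
            rows = np.unique(rr)
            curve = np.array([(int(r), int(cc[rr == r].max())) for r in rows], dtype=int)
            best_curve = curve
    if best_curve is None:
        return np.empty((0, 2), dtype=int)
    if flip:
        best_curve = best_curve.copy()
        best_curve[:, 1] = edges.width - 1 - best_curve[:, 1]
    return best_curve


def shape_shift(
    hull: HullImage, binary: BinaryMask, pectoral: np.ndarray
) -> BinaryMask:
    """Superimpose the hull on the body mask and cut away the pectoral side.

    The silhouette is (filled hull AND body mask), minus — for every row the
    pectoral curve spans — the pixels strictly left of the curve. The largest
    connected component is returned so the silhouette is a single region.

    Raises
    ------
    EmptySilhouetteError
        Everything was removed.
    """
    require_same_shape(hull.filled, binary)
    sil = hull.filled.pixels & binary.pixels
    pect = np.asarray(pectoral, dtype=int).reshape(-1, 2)
    for r, c in pect:
        sil[r, :c] = False
    if not sil.any():
        raise EmptySilhouetteError("silhouette is empty after pectoral removal")
    labels = cc_label(sil, connectivity=2)
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    return BinaryMask(labels == int(areas.argmax()))


def apply_silhouette(sil: BinaryMask, clean: GrayImage) -> GrayImage:
    """Map the silhouette onto the clean image, preserving intensities.

    Pixelwise product: intensities are kept bit-exactly inside the
    silhouette and are 0 outside.
    """
    require_same_shape(sil, clean)
    return GrayImage(np.where(sil.pixels, clean.pixels, 0.0), clean.source_depth)
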