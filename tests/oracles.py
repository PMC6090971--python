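"""Independent brute-force oracles used by the test suite.

Every function here is a direct transcription of the defining formula —
double loops, set unions, exhaustive enumeration — deliberately sharing no
code with the library implementations they check.
"""

from __future__ import annotations

import math

import numpy as np


def conv3x3_replicate(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """True convolution (flipped kernel) with edge replication, by loops."""
    h, w = image.shape
    out = np.zeros((h, w), dtype=float)
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for a in (-1, 0, 1):
                for b in (-1, 0, 1):
                    ii = min(max(i - a, 0), h - 1)  # minus: kernel flipped
                    jj = min(max(j - b, 0), w - 1)
                    acc += kernel[a + 1, b + 1] * image[ii, jj]
            out[i, j] = acc
    return out


def disk_offsets(radius: int) -> list[tuple[int, int]]:
    """Offsets of the discrete disk {(a, b): a^2 + b^2 <= radius^2}."""
    return [
        (a, b)
        for a in range(-radius, radius + 1)
        for b in range(-radius, radius + 1)
        if a * a + b * b <= radius * radius
    ]


def dilate_bruteforce(mask: np.ndarray, radius: int) -> np.ndarray:
    """Union of in-bounds translates of the mask by every disk offset."""
    h, w = mask.shape
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            if mask[i, j]:
                for a, b in disk_offsets(radius):
                    ii, jj = i + a, j + b
                    if 0 <= ii < h and 0 <= jj < w:
                        out[ii, jj] = True
    return out


def erode_bruteforce(mask: np.ndarray, radius: int) -> np.ndarray:
    """Pixels whose whole in-bounds footprint is foreground (outside = fg)."""
    h, w = mask.shape
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            ok = True
            for a, b in disk_offsets(radius):
                ii, jj = i + a, j + b
                if 0 <= ii < h and 0 <= jj < w and not mask[ii, jj]:
                    ok = False
                    break
            out[i, j] = ok
    return out


def hull_vertices_bruteforce(points: np.ndarray) -> set[tuple[float, float]]:
    """Hull vertex set by the O(n^3) edge test.

    A directed pair (i, j) is a hull edge iff every other point lies
    (weakly) on one side of the line through them; hull vertices are the
    endpoints of such edges. Assumes the points are in general position
    (no 3 collinear), which the random float fixtures guarantee.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    verts: set[tuple[float, float]] = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts[j] - pts[i]
            side_pos = side_neg = False
            for k in range(n):
                if k in (i, j):
                    continue
                cross = d[0] * (pts[k][1] - pts[i][1]) - d[1] * (pts[k][0] - pts[i][0])
                if cross > 1e-12:
                    side_pos = True
                elif cross < -1e-12:
                    side_neg = True
            if not (side_pos and side_neg):
                verts.add(tuple(pts[i]))
                verts.add(tuple(pts[j]))
    return verts


def hausdorff_bruteforce(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance by the all-pairs double loop."""

    def directed(u, v):
        worst = 0.0
        for p in u:
            best = math.inf
            for q in v:
                d = math.hypot(p[0] - q[0], p[1] - q[1])
                best = min(best, d)
            worst = max(worst, best)
        return worst

    return max(directed(a, b), directed(b, a))


def mse_bruteforce(x: np.ndarray, y: np.ndarray) -> float:
    total = 0.0
    h, w = x.shape
    for i in range(h):
        for j in range(w):
            total += (x[i, j] - y[i, j]) ** 2
    return total / (h * w)


def ssim_global_bruteforce(
    x: np.ndarray, y: np.ndarray, e1: float, e2: float, e3: float
) -> float:
    """Direct evaluation of the three terms (unclamped product)."""
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    sx, sy = math.sqrt(vx), math.sqrt(vy)
    cov = ((x - mx) * (y - my)).mean()
    lum = (2 * mx * my + e1) / (mx**2 + my**2 + e1)
    con = (2 * sx * sy + e2) / (vx + vy + e2)
    struct = (cov + e3) / (sx * sy + e3)
    return lum * con * struct
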