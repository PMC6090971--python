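"""Topographic map, convex hull, pectoral boundary and shape-shifting."""

import numpy as np
import pytest

import oracles
from pectoseg import (
    BinaryMask,
    GrayImage,
    apply_silhouette,
    convex_hull,
    pectoral_boundary,
    shape_shift,
    topographic_map,
)
from pectoseg.errors import DegenerateGeometryError, EmptySilhouetteError, ShapeMismatchError


class TestTopographicMap:
    def test_filled_square_gives_boundary_extremes(self):
        m = np.zeros((10, 10), dtype=bool)
        m[3:6, 4:7] = True  # 3x3 square at offset (3, 4)
        tm = topographic_map(BinaryMask(m))
        # enumeration: per-row left/right + per-col top/bottom extremes
        expected = {
            (3, 4), (3, 5), (3, 6),
            (4, 4), (4, 6),
            (5, 4), (5, 5), (5, 6),
        }
        assert set(map(tuple, tm.points)) == expected

    def test_single_row_is_degenerate(self):
        m = np.zeros((8, 8), dtype=bool)
        m[4, 1:7] = True
        with pytest.raises(DegenerateGeometryError):
            topographic_map(BinaryMask(m))

    def test_too_few_points(self):
        m = np.zeros((8, 8), dtype=bool)
        m[2, 2] = m[5, 5] = True
        with pytest.raises(DegenerateGeometryError):
            topographic_map(BinaryMask(m))

    def test_disk_map_lies_on_boundary_ring(self):
        m = np.zeros((16, 16), dtype=bool)
        rr, cc = np.mgrid[0:16, 0:16]
        inside = (rr - 8) ** 2 + (cc - 8) ** 2 <= 25
        m[inside] = True
        ring = inside & ~((rr - 8) ** 2 + (cc - 8) ** 2 <= 9)
        tm = topographic_map(BinaryMask(m))
        assert all(ring[r, c] for r, c in tm.points)

    def test_points_are_foreground(self, rng):
        m = rng.random((12, 12)) < 0.4
        m[2, 2] = m[9, 3] = m[5, 9] = True  # ensure non-degenerate
        tm = topographic_map(BinaryMask(m))
        assert all(m[r, c] for r, c in tm.points)


class TestConvexHull:
    @staticmethod
    def _map_from_points(points, shape=(32, 32)):
        m = np.zeros(shape, dtype=bool)
        for r, c in points:
            m[r, c] = True
        return topographic_map(BinaryMask(m))

    def test_rectangle_corners(self):
        tm = self._map_from_points([(2, 3), (2, 10), (9, 3), (9, 10)])
        hull = convex_hull(tm)
        assert len(hull.polygon) == 4
        assert set(map(tuple, hull.polygon)) == {(2, 3), (2, 10), (9, 3), (9, 10)}

    def test_interior_point_not_a_vertex(self):
        tm = self._map_from_points([(2, 2), (2, 12), (12, 2), (12, 12), (7, 7)])
        hull = convex_hull(tm)
        assert (7.0, 7.0) not in set(map(tuple, hull.polygon))

    def test_filled_raster_covers_points(self):
        tm = self._map_from_points([(3, 4), (3, 14), (14, 4), (14, 14), (8, 9)])
        hull = convex_hull(tm)
        assert all(hull.filled.pixels[r, c] for r, c in tm.points)

    def test_polygon_is_convex(self, rng):
        pts = rng.integers(2, 28, size=(15, 2))
        m = np.zeros((32, 32), dtype=bool)
        m[pts[:, 0], pts[:, 1]] = True
        hull = convex_hull(topographic_map(BinaryMask(m)))
        poly = hull.polygon
        n = len(poly)
        crosses = []
        for i in range(n):
            a, b, c = poly[i], poly[(i + 1) % n], poly[(i + 2) % n]
            u, v = b - a, c - b
            crosses.append(u[0] * v[1] - u[1] * v[0])
        crosses = np.array(crosses)
        assert (crosses >= 0).all() or (crosses <= 0).all()

    def test_vertices_match_bruteforce_oracle(self, rng):
        from scipy.spatial import ConvexHull as QHull

        for _ in range(10):
            pts = rng.random((30, 2)) * 100
            qh = QHull(pts)
            got = set(map(tuple, pts[qh.vertices]))
            assert got == oracles.hull_vertices_bruteforce(pts)


class TestPectoralBoundary:
    @staticmethod
    def _chord_edges(shape=(256, 256), top=(0, 200), bottom=(200, 0), width=2):
        """Rasterized straight chord band from a top-border to a left-border point."""
        m = np.zeros(shape, dtype=bool)
        n = 4 * max(shape)
        rr = np.linspace(top[0], bottom[0], n).round().astype(int)
        cc = np.linspace(top[1], bottom[1], n).round().astype(int)
        for dr in range(width):
            m[np.clip(rr + dr, 0, shape[0] - 1), cc] = True
        return m

    def test_straight_chord_endpoints_recovered(self):
        edges = BinaryMask(self._chord_edges(bottom=(200, 0), top=(0, 200)))
        curve = pectoral_boundary(edges)
        assert len(curve) > 0
        r0, c0 = curve[0]
        r1, c1 = curve[-1]
        assert abs(r0 - 0) <= 3 and abs(c0 - 200) <= 3
        assert abs(r1 - 200) <= 3 and abs(c1 - 0) <= 3

    def test_no_bridging_path_gives_empty(self):
        m = np.zeros((64, 64), dtype=bool)
        m[30:50, 30:50] = True  # interior blob touching no border
        assert len(pectoral_boundary(BinaryMask(m))) == 0

    def test_high_support_path_wins(self):
        a = self._chord_edges((128, 128), top=(0, 40), bottom=(60, 0))
        b = self._chord_edges((128, 128), top=(0, 100), bottom=(120, 0))
        support = np.zeros((128, 128))
        support[a] = 0.9
        support[b] = 0.2
        curve = pectoral_boundary(BinaryMask(a | b), support=support)
        assert abs(curve[0][1] - 40) <= 3  # the strong-gradient chord chosen

    def test_right_orientation_mirrors_columns(self):
        edges = self._chord_edges((128, 128), top=(0, 50), bottom=(80, 0))
        left = pectoral_boundary(BinaryMask(edges))
        right = pectoral_boundary(BinaryMask(np.fliplr(edges)), orientation="right")
        np.testing.assert_array_equal(left[:, 0], right[:, 0])
        np.testing.assert_array_equal(127 - left[:, 1], right[:, 1])


class TestShapeShift:
    def test_empty_curve_is_hull_intersection(self):
        body = np.zeros((20, 20), dtype=bool)
        body[4:16, 4:16] = True
        hull = convex_hull(topographic_map(BinaryMask(body)))
        sil = shape_shift(hull, BinaryMask(body), np.empty((0, 2), dtype=int))
        np.testing.assert_array_equal(sil.pixels, hull.filled.pixels & body)

    def test_silhouette_subset_of_body(self, rng):
        body = np.zeros((30, 30), dtype=bool)
        body[2:28, 2:28] = True
        hull = convex_hull(topographic_map(BinaryMask(body)))
        curve = np.array([(r, 10 - r // 3) for r in range(12)])
        sil = shape_shift(hull, BinaryMask(body), curve)
        assert (sil.pixels & ~body).sum() == 0

    def test_rows_left_of_curve_removed(self):
        body = np.ones((10, 10), dtype=bool)
        hull = convex_hull(topographic_map(BinaryMask(body)))
        curve = np.array([(r, 5) for r in range(10)])
        sil = shape_shift(hull, BinaryMask(body), curve)
        assert not sil.pixels[:, :5].any()
        assert sil.pixels[:, 5:].all()

    def test_everything_removed_raises(self):
        body = np.ones((6, 6), dtype=bool)
        hull = convex_hull(topographic_map(BinaryMask(body)))
        curve = np.array([(r, 6) for r in range(6)])
        with pytest.raises(EmptySilhouetteError):
            shape_shift(hull, BinaryMask(body), curve)


class TestApplySilhouette:
    def test_full_mask_identity(self, rng):
        img = GrayImage(rng.random((8, 8)))
        sil = BinaryMask(np.ones((8, 8), dtype=bool))
        np.testing.assert_array_equal(apply_silhouette(sil, img).pixels, img.pixels)

    def test_empty_mask_zero(self, rng):
        img = GrayImage(rng.random((8, 8)))
        sil = BinaryMask(np.zeros((8, 8), dtype=bool))
        assert apply_silhouette(sil, img).pixels.sum() == 0.0

    def test_matches_loop_oracle(self, rng):
        img = GrayImage(rng.random((8, 8)))
        sil = BinaryMask(rng.random((8, 8)) < 0.5)
        out = apply_silhouette(sil, img).pixels
        for i in range(8):
            for j in range(8):
                assert out[i, j] == (img.pixels[i, j] if sil.pixels[i, j] else 0.0)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ShapeMismatchError):
            apply_silhouette(BinaryMask(np.ones((4, 4), dtype=bool)), GrayImage(rng.random((5, 5))))
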