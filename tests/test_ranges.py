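import numpy as np
import pytest

from migraphen.ranges import (DegenerateGeometryError, convex_hull_range,
                              isopleth_polygon, kernel_ud, point_in_range,
                              reference_bandwidth)


def _standardized(rng, n):
    pts = rng.normal(size=(n, 2))
    return (pts - pts.mean(axis=0)) / pts.std(axis=0, ddof=1)


class TestReferenceBandwidth:
    def test_closed_form_unit_variance_n64(self, rng):
        pts = _standardized(rng, 64)
        assert reference_bandwidth(pts) == pytest.approx(64 ** (-1 / 6), rel=1e-12)
        assert reference_bandwidth(pts) == pytest.approx(0.5, rel=1e-12)

    def test_coincident_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            reference_bandwidth(np.ones((10, 2)))

    def test_scale_homogeneity(self, rng):
        pts = rng.normal(size=(50, 2))
        assert reference_bandwidth(3.7 * pts) == pytest.approx(
            3.7 * reference_bandwidth(pts), rel=1e-12)


class TestKernelUD:
    def test_density_integrates_to_one(self, rng):
        pts = rng.normal(0, 0.5, size=(500, 2))
        ud = kernel_ud(pts[:, 0] - 95.0, pts[:, 1] + 35.0)
        assert ud.density.sum() * ud.cell_area == pytest.approx(1.0, abs=1e-6)

    def test_mode_near_true_center(self, rng):
        # standard bivariate normal scaled to ~0.1 deg sigma near (-95, 35)
        pts = rng.normal(0, 1, size=(20000, 2)) * 0.1
        ud = kernel_ud(pts[:, 0] - 95.0, pts[:, 1] + 35.0)
        mx, my = ud.mode_xy()
        x0, y0 = ud.projection.forward(-95.0, 35.0)
        sigma_km = 0.1 * 111.195
        assert np.hypot(mx - x0, my - y0) < 0.1 * sigma_km

    def test_bandwidth_scale_validated(self, rng):
        pts = rng.normal(size=(100, 2))
        with pytest.raises(ValueError):
            kernel_ud(pts[:, 0], pts[:, 1], bandwidth_scale=1.5)


class TestIsopleth:
    def test_monotone_nesting_of_levels(self, rng):
        pts = rng.normal(0, 0.2, size=(3000, 2))
        ud = kernel_ud(pts[:, 0] - 95.0, pts[:, 1] + 35.0)
        areas = [isopleth_polygon(ud, lev).geometry.area for lev in (0.5, 0.8, 0.95)]
        assert areas[0] < areas[1] < areas[2]

    def test_two_separated_clusters_give_disjoint_rings(self, rng):
        a = rng.normal(0, 0.05, size=(2000, 2))
        b = rng.normal(0, 0.05, size=(2000, 2)) + np.array([2.0, 0.0])
        pts = np.vstack([a, b])
        ud = kernel_ud(pts[:, 0] - 95.0, pts[:, 1] + 35.0)
        poly = isopleth_polygon(ud, 0.95)
        assert len(poly.geometry.geoms) >= 2

    def test_level_bounds_enforced(self, rng):
        pts = rng.normal(size=(200, 2))
        ud = kernel_ud(pts[:, 0], pts[:, 1])
        for bad in (0.0, 1.0, 1.3):
            with pytest.raises(ValueError):
                isopleth_polygon(ud, bad)


class TestConvexHull:
    def test_square_corners_with_interior_point(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]], dtype=float)
        hull = convex_hull_range(pts)
        ring = np.asarray(hull.geometry.geoms[0].exterior.coords)
        assert len(ring) - 1 == 4  # closed ring repeats the first vertex

    def test_hull_of_hull_is_hull(self, rng):
        pts = rng.normal(size=(100, 2))
        h1 = convex_hull_range(pts)
        verts = np.asarray(h1.geometry.geoms[0].exterior.coords)[:-1]
        h2 = convex_hull_range(verts)
        assert h1.geometry.equals(h2.geometry)

    def test_all_inputs_inside_and_vertices_subset(self, rng):
        pts = rng.normal(size=(1000, 2))
        hull = convex_hull_range(pts)
        assert point_in_range(pts[:, 0], pts[:, 1], hull).all()
        verts = np.asarray(hull.geometry.geoms[0].exterior.coords)[:-1]
        as_set = {tuple(p) for p in np.round(pts, 12)}
        assert all(tuple(v) in as_set for v in np.round(verts, 12))

    def test_collinear_points_raise(self):
        pts = np.column_stack([np.arange(5.0), 2.0 * np.arange(5.0)])
        with pytest.raises((ValueError, DegenerateGeometryError)):
            convex_hull_range(pts)


def _ray_cast(px, py, ring):
    """Independent even-odd ray-casting oracle for a single closed ring."""
    inside = False
    n = len(ring) - 1
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[i + 1]
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside


def test_point_in_range_matches_ray_casting_oracle(rng):
    pts = rng.normal(size=(300, 2))
    hull = convex_hull_range(pts)
    ring = np.asarray(hull.geometry.geoms[0].exterior.coords)
    test = rng.uniform(-4, 4, size=(10000, 2))
    ours = point_in_range(test[:, 0], test[:, 1], hull)
    oracle = np.array([_ray_cast(x, y, ring) for x, y in test])
    assert (ours == oracle).all()


def test_point_outside_bounding_box_is_outside(rng):
    pts = rng.normal(size=(50, 2))
    hull = convex_hull_range(pts)
    assert not point_in_range(100.0, 100.0, hull)
    # centroid of the hull is inside
    c = hull.geometry.centroid
    assert point_in_range(c.x, c.y, hull)
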