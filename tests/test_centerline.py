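"""Centerline extraction, perpendicular planes, contours and seed regions."""

import numpy as np
import pytest

from retrack import (
    Centerline,
    Grid,
    StreamlineBundle,
    compute_centerline,
    plane_at,
    resample_streamline,
    scale_contour,
    seed_points_in_contour,
    select_plane_indices,
    trace_contour,
)
from retrack.centerline import _frame_from_normal


def _polygon_area(poly):
    # shoelace on a closed polyline (first == last)
    x, y = poly[:-1, 0], poly[:-1, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestResample:
    def test_straight_segment_uniform_spacing(self):
        s = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        out = resample_streamline(s, 5)
        assert np.allclose(out[:, 0], [0, 2.5, 5, 7.5, 10])

    def test_idempotent_on_equally_spaced_line(self):
        xs = np.linspace(0, 12, 7)
        s = np.stack([xs, np.zeros(7), np.zeros(7)], axis=1)
        assert np.allclose(resample_streamline(s, 7), s)

    def test_endpoints_preserved_on_l_shape(self):
        s = np.array([[0.0, 0, 0], [3.0, 0, 0], [3.0, 4.0, 0]])
        out = resample_streamline(s, 2)
        assert np.allclose(out[0], s[0]) and np.allclose(out[-1], s[-1])

    def test_single_point_raises(self):
        with pytest.raises(ValueError):
            resample_streamline(np.zeros((1, 3)), 5)


class TestCenterline:
    def test_symmetric_pair_averages_to_midline(self):
        xs = np.linspace(0, 20, 21)
        up = np.stack([xs, np.full(21, 3.0), np.zeros(21)], axis=1)
        dn = np.stack([xs, np.full(21, -3.0), np.zeros(21)], axis=1)
        cl = compute_centerline(StreamlineBundle([up, dn]), 11)
        assert np.allclose(cl.points[:, 1], 0.0)

    def test_single_streamline_is_its_resampling(self):
        xs = np.linspace(0, 10, 6)
        s = np.stack([xs, xs**2 / 10, np.zeros(6)], axis=1)
        cl = compute_centerline(StreamlineBundle([s]), 6)
        assert np.allclose(cl.points, resample_streamline(s, 6))

    def test_orientation_alignment_flips_reversed_lines(self):
        xs = np.linspace(0, 20, 21)
        fwd = np.stack([xs, np.full(21, 2.0), np.zeros(21)], axis=1)
        rev = np.stack([xs, np.full(21, -2.0), np.zeros(21)], axis=1)[::-1]
        cl = compute_centerline(StreamlineBundle([fwd, rev]), 21)
        assert np.allclose(cl.points[:, 1], 0.0)
        assert cl.points[0, 0] < cl.points[-1, 0]

    def test_noisy_arc_average_matches_direct_oracle(self):
        # 100 jittered copies of a quarter arc; the centerline must agree with
        # an independently coded resample-then-average, and stay near the arc
        rng = np.random.default_rng(42)
        th = np.linspace(0, np.pi / 2, 50)
        arc = np.stack([30 * np.cos(th), 30 * np.sin(th), np.zeros(50)], axis=1)
        sigma = 0.5
        copies = [arc + rng.normal(0, sigma, arc.shape) for _ in range(100)]
        n = 25
        cl = compute_centerline(StreamlineBundle(copies), n)
        oracle = np.mean([resample_streamline(c, n) for c in copies], axis=0)
        assert np.allclose(cl.points, oracle, atol=1e-12)
        # distance to the analytic arc: jitter averages down as sigma/sqrt(100)
        r = np.linalg.norm(cl.points[:, :2], axis=1)
        assert np.abs(r - 30).max() <= 3 * sigma / np.sqrt(100) * 4

    def test_empty_bundle_raises(self):
        with pytest.raises(ValueError):
            compute_centerline(StreamlineBundle([]), 10)


class TestPlanes:
    def test_straight_centerline_normals(self):
        xs = np.linspace(0, 10, 11)
        cl = Centerline(np.stack([xs, np.zeros(11), np.zeros(11)], axis=1))
        for i in range(11):
            f = plane_at(cl, i)
            assert np.allclose(f.normal, [1, 0, 0])
            # right-handed orthonormal frame
            assert np.allclose(np.cross(f.u, f.v), f.normal)
            assert abs(f.u @ f.normal) < 1e-12

    def test_last_index_uses_previous_segment(self):
        cl = Centerline(np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]]))
        assert np.allclose(plane_at(cl, 2).normal, plane_at(cl, 1).normal)

    def test_quarter_arc_normals_match_analytic_tangent(self):
        th = np.linspace(0, np.pi / 2, 65)
        pts = np.stack([30 * np.cos(th), 30 * np.sin(th), np.zeros(65)], axis=1)
        cl = Centerline(pts)
        step = th[1] - th[0]
        for i in (0, 20, 40, 63):
            analytic = np.array([-np.sin(th[i]), np.cos(th[i]), 0.0])
            n = plane_at(cl, i).normal
            ang = np.arccos(np.clip(abs(n @ analytic), -1, 1))
            assert ang <= step  # within one discretization step

    def test_coincident_points_fall_back_to_distinct_neighbor(self):
        cl = Centerline(np.array([[0.0, 0, 0], [0.0, 0, 0], [2.0, 0, 0]]))
        assert np.allclose(plane_at(cl, 0).normal, [1, 0, 0])


class TestSelectIndices:
    @pytest.mark.parametrize(
        "n_seeds,expected",
        [(5, [0, 32, 64, 96, 128]), (2, [0, 128]), (129, list(range(129)))],
    )
    def test_equally_spaced_subsets_of_129(self, n_seeds, expected):
        assert select_plane_indices(129, n_seeds).tolist() == expected

    def test_too_many_seeds_raises(self):
        with pytest.raises(ValueError):
            select_plane_indices(10, 11)


class TestContour:
    @pytest.fixture
    def sphere(self):
        grid = Grid((24, 24, 24), 1.0, np.full(3, 0.5))
        centers = grid.voxel_centers()
        c = np.array([12.0, 12.0, 12.0])
        mask = (np.linalg.norm(centers - c, axis=-1) <= 5.0).astype(np.uint8)
        frame = _frame_from_normal(c, np.array([0.0, 0.0, 1.0]))
        return frame, mask, grid

    def test_sphere_section_radii(self, sphere):
        frame, mask, grid = sphere
        ctr = trace_contour(frame, mask, grid, n_rays=36, ray_step_mm=0.5)
        half_diag = np.sqrt(3) / 2 * grid.voxel_size
        assert np.all(ctr.radii >= 5.0 - half_diag - 0.5)
        assert np.all(ctr.radii <= 5.0 + 0.5 + half_diag)
        # circular section: low spread (voxelization tolerance)
        assert ctr.radii.std() / ctr.radii.mean() < 0.15

    def test_single_voxel_mask_minimal_radii(self):
        grid = Grid((9, 9, 9), 2.0, np.ones(3))
        mask = np.zeros(grid.shape, dtype=np.uint8)
        mask[4, 4, 4] = 1
        frame = _frame_from_normal(grid.voxel_to_world([4, 4, 4]), np.array([0.0, 0, 1]))
        ctr = trace_contour(frame, mask, grid, ray_step_mm=0.5)
        assert np.all(ctr.radii <= np.sqrt(3) * grid.voxel_size + 0.5)

    def test_ray_angles_equally_spaced(self, sphere):
        frame, mask, grid = sphere
        ctr = trace_contour(frame, mask, grid, n_rays=36)
        assert np.allclose(np.diff(ctr.ray_angles), np.radians(10.0))

    def test_origin_outside_mask_raises(self, sphere):
        frame, mask, grid = sphere
        bad = _frame_from_normal(np.array([1.0, 1.0, 1.0]), np.array([0.0, 0, 1]))
        with pytest.raises(ValueError, match="outside"):
            trace_contour(bad, mask, grid)

    def test_scaling_zero_is_identity(self, sphere):
        frame, mask, grid = sphere
        ctr = trace_contour(frame, mask, grid)
        out = scale_contour(ctr, 0.0)
        assert np.allclose(out.radii, ctr.radii)
        assert np.allclose(out.spline_samples, ctr.spline_samples)

    def test_scaling_one_grows_circle_by_one_mm(self, sphere):
        frame, mask, grid = sphere
        ctr = trace_contour(frame, mask, grid)
        out = scale_contour(ctr, 1.0)
        assert np.allclose(out.radii, ctr.radii + 1.0)

    def test_spline_area_strictly_increases_with_scaling(self, sphere):
        frame, mask, grid = sphere
        ctr = trace_contour(frame, mask, grid)
        areas = [_polygon_area(scale_contour(ctr, s).spline_samples)
                 for s in (0, 1, 2, 3, 4, 5)]
        assert np.all(np.diff(areas) > 0)


class TestSeedPoints:
    @pytest.fixture
    def circle_contour(self):
        frame = _frame_from_normal(np.array([10.0, 10.0, 10.0]), np.array([0.0, 0, 1]))
        angles = 2 * np.pi * np.arange(36) / 36
        radii = np.full(36, 5.0)
        from retrack.centerline import Contour, _fit_closed_spline

        return Contour(frame, angles, radii, _fit_closed_spline(angles, radii))

    def test_count_matches_area_over_spacing(self, circle_contour):
        pts = seed_points_in_contour(circle_contour, spacing_mm=1.0)
        expected = np.pi * 25.0
        assert abs(len(pts) - expected) / expected < 0.10

    def test_all_points_on_plane(self, circle_contour):
        pts = seed_points_in_contour(circle_contour, spacing_mm=1.0)
        frame = circle_contour.plane
        off = (pts - frame.origin) @ frame.normal
        assert np.abs(off).max() < 1e-9

    def test_degenerate_contour_yields_origin_only(self):
        from retrack.centerline import Contour, _fit_closed_spline

        frame = _frame_from_normal(np.zeros(3), np.array([0.0, 0, 1]))
        angles = 2 * np.pi * np.arange(36) / 36
        radii = np.full(36, 1e-6)
        ctr = Contour(frame, angles, radii, _fit_closed_spline(angles, radii))
        pts = seed_points_in_contour(ctr, spacing_mm=1.0)
        assert pts.shape == (1, 3)
        assert np.allclose(pts[0], frame.origin)
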