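import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cada.ellipsoid import (Ellipsoid, ellipsoid_roi, fit_ellipsoid,
                            mask_surface_points, point_ellipsoid_distance)
from cada.errors import DegeneracyError, EmptyROIError
from cada.volume_io import Mask, Volume


def sample_surface(rng, axes, R=np.eye(3), center=np.zeros(3), n=600):
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return (u * np.asarray(axes)) @ R + np.asarray(center)


class TestSurfacePoints:
    def test_single_voxel(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 3, 1] = True
        pts = mask_surface_points(Mask(m))
        assert pts.shape == (1, 3) and tuple(pts[0]) == (2, 3, 1)

    def test_solid_cube_surface_count(self):
        """5^3 - 3^3 = 98 voxels have a 6-connected background neighbour."""
        m = np.zeros((9, 9, 9), dtype=bool)
        m[2:7, 2:7, 2:7] = True
        assert mask_surface_points(Mask(m)).shape[0] == 98

    def test_digital_ball_near_sphere(self):
        r = 8
        g = np.arange(21) - 10.0
        x, y, z = np.meshgrid(g, g, g, indexing="ij")
        ball = x ** 2 + y ** 2 + z ** 2 <= r ** 2
        pts = mask_surface_points(Mask(ball)) - 10.0
        radii = np.linalg.norm(pts, axis=1)
        assert np.all(np.abs(radii - r) < 1.5)

    def test_empty_mask(self):
        with pytest.raises(EmptyROIError):
            mask_surface_points(Mask(np.zeros((3, 3, 3))))


class TestDistance:
    def test_sphere_closed_form(self):
        e = Ellipsoid(np.zeros(3), np.eye(3), [1.0, 1.0, 1.0])
        assert point_ellipsoid_distance([3.0, 0, 0], e) == pytest.approx(2.0)
        assert point_ellipsoid_distance([0, 0.5, 0], e) == pytest.approx(0.5)

    def test_on_surface_zero(self, rng):
        e = Ellipsoid(np.zeros(3), np.eye(3), [4.0, 2.0, 1.0])
        p = sample_surface(rng, e.semi_axes, n=50)
        for pi in p:
            assert point_ellipsoid_distance(pi, e) < 1e-8

    def test_on_axis_closed_form(self):
        e = Ellipsoid(np.zeros(3), np.eye(3), [4.0, 2.0, 1.0])
        assert point_ellipsoid_distance([6.0, 0, 0], e) == pytest.approx(2.0)

    def test_center_returns_min_axis(self):
        e = Ellipsoid(np.zeros(3), np.eye(3), [4.0, 2.0, 1.0])
        assert point_ellipsoid_distance([0, 0, 0], e) == pytest.approx(1.0)

    def test_against_dense_surface_sampling(self, rng):
        """Brute-force oracle: min distance to a dense surface sample."""
        R = Rotation.from_rotvec([0.4, -0.2, 0.7]).as_matrix()
        e = Ellipsoid([1.0, -2.0, 0.5], R, [5.0, 3.0, 2.0])
        u = rng.normal(size=(200_000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        surf = (u * e.semi_axes) @ e.orientation + e.center
        for p in rng.normal(scale=4.0, size=(20, 3)):
            exact = point_ellipsoid_distance(p, e)
            brute = np.min(np.linalg.norm(surf - p, axis=1))
            assert exact == pytest.approx(brute, abs=2e-3)


class TestFit:
    def test_known_ellipsoid_recovery(self, rng):
        R = Rotation.from_rotvec([0.3, 0.2, 0.1]).as_matrix()
        center = np.array([32.0, 30.0, 28.0])
        axes = np.array([10.0, 6.0, 4.0])
        pts = sample_surface(rng, axes, R, center)
        ell, rep = fit_ellipsoid(pts)
        assert np.allclose(ell.center, center, atol=0.25)
        assert np.allclose(ell.semi_axes, axes, atol=0.25)
        for row, axis_len in zip(ell.orientation, axes):
            truth_dir = R.T @ (np.eye(3)[list(axes).index(axis_len)])
            angle = np.degrees(np.arccos(min(1.0, abs(row @ truth_dir))))
            assert angle < 2.0
        assert rep.final_energy <= rep.initial_energy

    def test_unit_sphere(self, rng):
        pts = sample_surface(rng, [1.0, 1.0, 1.0], n=400)
        ell, rep = fit_ellipsoid(pts)
        assert np.allclose(ell.semi_axes, 1.0, atol=1e-3)
        assert rep.final_energy < 1e-6

    def test_voxelized_mask_recovery(self):
        g = np.arange(64, dtype=float)
        x, y, z = np.meshgrid(g, g, g, indexing="ij")
        axes = np.array([10.0, 6.0, 4.0])
        c = np.array([32.5, 30.5, 28.5])
        solid = (((x - c[0]) / axes[0]) ** 2 + ((y - c[1]) / axes[1]) ** 2
                 + ((z - c[2]) / axes[2]) ** 2) <= 1.0
        pts = mask_surface_points(Mask(solid))
        ell, _ = fit_ellipsoid(pts)
        assert np.allclose(ell.center, c, atol=0.6)
        assert np.allclose(ell.semi_axes, axes, atol=0.6)

    def test_rigid_motion_equivariance(self, rng):
        axes = np.array([7.0, 4.0, 2.5])
        pts = sample_surface(rng, axes, n=500)
        ell0, _ = fit_ellipsoid(pts)
        R = Rotation.from_rotvec([0.2, 0.5, -0.3]).as_matrix()
        t = np.array([5.0, -2.0, 9.0])
        ell1, _ = fit_ellipsoid(pts @ R.T + t)
        assert np.allclose(ell1.semi_axes, ell0.semi_axes, atol=1e-3)
        assert np.allclose(ell1.center, R @ ell0.center + t, atol=1e-3)

    def test_coplanar_points_rejected(self, rng):
        pts = rng.normal(size=(50, 3))
        pts[:, 2] = 0.0
        with pytest.raises(DegeneracyError):
            fit_ellipsoid(pts)

    def test_too_few_points(self):
        with pytest.raises(DegeneracyError):
            fit_ellipsoid(np.eye(3))


class TestROI:
    def test_sphere_volume_fine_grid(self):
        """A 5.2-unit sphere sampled at 0.25-unit voxels: the voxel-count
        volume matches 4/3 pi r^3 within 3%."""
        r_units, step = 5.2, 0.25
        r_vox = r_units / step
        e = Ellipsoid([32.3, 31.6, 24.2], np.eye(3), [r_vox] * 3)
        grid = Volume(np.zeros((64, 64, 48)))
        n = ellipsoid_roi(e, grid).n_voxels
        expected = 4.0 / 3.0 * np.pi * r_units ** 3
        assert n * step ** 3 == pytest.approx(expected, rel=0.03)

    def test_matches_brute_force_inequality(self):
        e = Ellipsoid([7.5, 8.0, 6.5], np.eye(3), [1.0, 1.5, 2.0])
        grid = Volume(np.zeros((16, 16, 16)))
        roi = ellipsoid_roi(e, grid)
        ii, jj, kk = np.meshgrid(*[np.arange(16)] * 3, indexing="ij")
        pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
        inside = e.quadratic_form(pts) <= 1.0
        assert np.array_equal(roi.data.ravel(), inside)

    def test_outside_grid_raises(self):
        e = Ellipsoid([100, 100, 100], np.eye(3), [2, 2, 2])
        with pytest.raises(EmptyROIError):
            ellipsoid_roi(e, Volume(np.zeros((16, 16, 16))))


class TestCanonicalForm:
    def test_axes_sorted_and_det_positive(self):
        R = Rotation.from_rotvec([0.1, 0.7, 0.3]).as_matrix()
        e = Ellipsoid(np.zeros(3), R, [2.0, 5.0, 3.0])
        assert np.all(np.diff(e.semi_axes) <= 0)
        assert np.linalg.det(e.orientation) == pytest.approx(1.0)
        assert np.allclose(e.orientation @ e.orientation.T, np.eye(3),
                           atol=1e-10)
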