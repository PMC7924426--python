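"""Reflection algebra, ICP registration, and symmetry-plane recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symslice.segmentation import PointCloud
from symslice.symmetry import (
    Plane,
    RankError,
    RigidTransform,
    SymmetryEstimationError,
    best_symmetry_plane,
    icp_register,
    reflect_points,
    reflection_about,
)
from symslice.transforms import rotation_xyz


def angle_deg(a, b):
    return float(np.degrees(np.arccos(np.clip(abs(np.dot(a, b)), -1.0, 1.0))))


unit_vectors = st.tuples(
    st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1)
).filter(lambda v: np.linalg.norm(v) > 1e-3)


class TestReflection:
    def test_unit_reflection_about_yz_plane(self):
        p = Plane((1.0, 0.0, 0.0), 0.0)
        out = reflect_points(PointCloud(np.array([[1.0, 0, 0]])), p)
        np.testing.assert_allclose(out.points, [[-1.0, 0, 0]], atol=1e-12)

    def test_points_on_the_plane_are_fixed(self, rng):
        n = np.array([1.0, 2.0, -1.0]) / np.sqrt(6)
        p = Plane(tuple(n), 3.0)
        # build points with n.x = 3
        basis = np.linalg.svd(n[None, :])[2][1:]
        pts = 3.0 * n + rng.normal(size=(50, 2)) @ basis
        out = reflect_points(PointCloud(pts), p)
        np.testing.assert_allclose(out.points, pts, atol=1e-9)

    def test_reflection_is_an_involution(self, random_cloud):
        p = Plane.from_vector((1.0, -2.0, 0.5), 4.0)
        twice = reflect_points(reflect_points(random_cloud, p), p)
        np.testing.assert_allclose(twice.points, random_cloud.points, atol=1e-9)

    @settings(deadline=None, max_examples=30)
    @given(v=unit_vectors, d=st.floats(-10, 10))
    def test_householder_matrix_properties(self, v, d):
        p = Plane.from_vector(v, d)
        H, _ = reflection_about(p)
        np.testing.assert_allclose(H @ H, np.eye(3), atol=1e-9)
        assert np.linalg.det(H) == pytest.approx(-1.0, abs=1e-9)


class TestIcpRegister:
    def test_identical_clouds_give_identity(self, random_cloud):
        res = icp_register(random_cloud, random_cloud)
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(res.transform.translation, 0.0, atol=1e-6)
        assert res.residual_rms < 1e-6

    def test_pure_translation_recovered(self, random_cloud):
        target = PointCloud(random_cloud.points + np.array([3.0, 2.0, 2.0]))
        res = icp_register(random_cloud, target)
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-3)
        np.testing.assert_allclose(res.transform.translation, [3, 2, 2], atol=1e-3)

    @pytest.mark.parametrize("angle", [4.0, 10.0, 15.0])
    def test_rotation_about_centroid_recovered(self, random_cloud, angle):
        ctr = random_cloud.centroid
        R = rotation_xyz((0, 0, angle))
        target = PointCloud((random_cloud.points - ctr) @ R.T + ctr)
        res = icp_register(random_cloud, target)
        rec = np.degrees(np.arccos(np.clip((np.trace(res.transform.rotation) - 1) / 2, -1, 1)))
        assert rec == pytest.approx(angle, abs=0.1)

    def test_general_rigid_transforms_recovered(self, rng):
        pts = rng.uniform(0, 30, size=(300, 3))
        for _ in range(10):
            angles = rng.uniform(-15, 15, size=3)
            t_true = rng.uniform(-5, 5, size=3)
            R = rotation_xyz(angles)
            target = PointCloud(pts @ R.T + t_true)
            res = icp_register(PointCloud(pts), target)
            np.testing.assert_allclose(res.transform.rotation, R, atol=2e-3)
            np.testing.assert_allclose(res.transform.translation, t_true, atol=0.05)

    def test_rms_history_is_monotone_nonincreasing(self, rng):
        pts = rng.uniform(0, 20, size=(500, 3))
        R = rotation_xyz((5, -8, 12))
        target = PointCloud(pts @ R.T + np.array([1.0, -2.0, 0.5]))
        res = icp_register(PointCloud(pts), target, tol=0.0, max_iter=30)
        diffs = np.diff(res.rms_history)
        assert np.all(diffs <= 1e-9)

    def test_coincident_points_raise_rank_error(self):
        coincident = PointCloud(np.ones((20, 3)))
        with pytest.raises(RankError):
            icp_register(coincident, coincident)

    def test_subsampling_is_deterministic_under_seed(self, rng):
        pts = rng.uniform(0, 50, size=(9000, 3))
        target = PointCloud(pts + np.array([1.0, 0.0, 0.0]))
        r1 = icp_register(PointCloud(pts), target, max_points=2000, seed=5)
        r2 = icp_register(PointCloud(pts), target, max_points=2000, seed=5)
        np.testing.assert_array_equal(r1.transform.rotation, r2.transform.rotation)


def mirrored_cloud(rng, n=600, normal=(1.0, 0.0, 0.0), offset=0.0, spread=20.0):
    """Random half-cloud unioned with its mirror image: exactly symmetric."""
    pts = rng.uniform(-spread, spread, size=(n, 3)) + np.array([25.0, 25.0, 25.0])
    p = Plane.from_vector(normal, offset)
    mirrored = reflect_points(PointCloud(pts), p)
    return PointCloud(np.vstack([pts, mirrored.points]))


class TestBestSymmetryPlane:
    def test_recovers_plane_of_constructed_symmetric_cloud(self, rng):
        cloud = mirrored_cloud(rng, normal=(1.0, 0.0, 0.0), offset=10.0)
        sp = best_symmetry_plane(cloud, seed=0)
        assert angle_deg(sp.plane.n, [1, 0, 0]) < 1.0
        assert abs(abs(sp.plane.offset) - 10.0) < 0.5

    def test_composite_eigenstructure_of_symmetric_cloud(self, rng):
        cloud = mirrored_cloud(rng, normal=(0.0, 1.0, 0.0), offset=25.0)
        sp = best_symmetry_plane(cloud, seed=1)
        # residual near zero and the frame orthonormal
        assert sp.residual_rms < 0.2
        G = np.stack([sp.plane.n, sp.axis_u, sp.axis_v])
        np.testing.assert_allclose(G @ G.T, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(np.cross(sp.axis_u, sp.axis_v), sp.plane.n, atol=1e-6)

    def test_equivariance_under_known_rigid_motion(self, rng):
        cloud = mirrored_cloud(rng, normal=(1.0, 0.0, 0.0), offset=25.0)
        sp0 = best_symmetry_plane(cloud, seed=2)
        R = rotation_xyz((8.0, -12.0, 5.0))
        t = np.array([4.0, -3.0, 2.0])
        moved = PointCloud(cloud.points @ R.T + t)
        sp1 = best_symmetry_plane(moved, seed=2)
        assert angle_deg(R @ sp0.plane.n, sp1.plane.n) < 2.0

    def test_asymmetric_cloud_still_returns_a_plane(self, rng):
        cloud = PointCloud(rng.uniform(0, 30, size=(500, 3)))
        sp = best_symmetry_plane(cloud, seed=3)
        assert np.isfinite(sp.residual_rms)
        assert sp.residual_rms > 0

    def test_too_few_or_coplanar_points_rejected(self, rng):
        with pytest.raises(SymmetryEstimationError):
            best_symmetry_plane(PointCloud(np.eye(3)))
        flat = rng.uniform(0, 10, size=(100, 3))
        flat[:, 2] = 1.0
        with pytest.raises(SymmetryEstimationError):
            best_symmetry_plane(PointCloud(flat))

    def test_serialization_roundtrip(self, rng, tmp_path):
        from symslice.symmetry import SymmetryPlane

        sp = best_symmetry_plane(mirrored_cloud(rng), seed=4)
        path = tmp_path / "plane.json"
        sp.to_json(path)
        back = SymmetryPlane.from_json(path)
        np.testing.assert_allclose(back.plane.n, sp.plane.n)
        np.testing.assert_allclose(back.axis_u, sp.axis_u)
        assert back.residual_rms == sp.residual_rms


class TestRigidTransform:
    def test_rejects_improper_rotation(self):
        H = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(Exception):
            RigidTransform(H, np.zeros(3))
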