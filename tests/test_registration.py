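import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from sealerdelta.errors import CorrespondenceError, DegenerateConfigurationError, \
    ValidationError
from sealerdelta.geometry import SurfaceLocator, sample_surface
from sealerdelta.phantom import make_baseline
from sealerdelta.registration import ICPConfig, apply_transform, icp_refine, \
    kabsch, landmark_align
from sealerdelta.transforms import LandmarkSet, RigidTransform, \
    random_small_transform
from sealerdelta.volumetry import mesh_volume

from conftest import random_rotation


def scipy_rigid_fit(src, tgt):
    """Independent SVD-based rigid least-squares fit via scipy Rotation."""
    cs, ct = src.mean(axis=0), tgt.mean(axis=0)
    rot, _ = Rotation.align_vectors(tgt - ct, src - cs)
    R = rot.as_matrix()
    return R, ct - R @ cs


class TestLandmarkAlign:
    def test_identity_for_identical_sets(self):
        lm = LandmarkSet(np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]))
        T = landmark_align(lm, lm)
        assert np.allclose(T.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(T.translation, 0.0, atol=1e-12)

    def test_exact_rigid_case_recovered(self):
        """A 90-degree rotation about z plus a (1,0,0) shift is recovered
        exactly with zero residual."""
        src = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        Rz = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
        t = np.array([1.0, 0, 0])
        tgt = src @ Rz.T + t
        T = landmark_align(LandmarkSet(src), LandmarkSet(tgt))
        assert np.abs(T.rotation - Rz).max() < 1e-12
        assert np.abs(T.translation - t).max() < 1e-12
        assert np.abs(T.apply(src) - tgt).max() < 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_noisy_fit_matches_independent_svd_oracle(self, seed):
        rng = np.random.default_rng(seed)
        src = rng.normal(size=(8, 3))
        R = random_rotation(rng)
        tgt = src @ R.T + rng.normal(size=3) + rng.normal(0, 0.05, size=(8, 3))
        T = kabsch(src, tgt)
        R2, t2 = scipy_rigid_fit(src, tgt)
        assert np.abs(T.rotation - R2).max() < 1e-9
        assert np.abs(T.translation - t2).max() < 1e-9

    def test_degenerate_and_mismatched_inputs(self):
        line = LandmarkSet(np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]]))
        with pytest.raises(DegenerateConfigurationError):
            landmark_align(line, line)
        a = LandmarkSet(np.eye(3), labels=("a", "b", "c"))
        b = LandmarkSet(np.eye(3), labels=("a", "b", "x"))
        with pytest.raises(CorrespondenceError):
            landmark_align(a, b)


class TestClosestPoint:
    def test_matches_brute_force_on_random_mesh(self, coarse_baseline):
        """Locator distances equal an exhaustive, independently coded
        all-triangle search to 1e-9."""
        mesh = coarse_baseline.sealer_mesh
        rng = np.random.default_rng(0)
        pts = rng.normal(scale=2.0, size=(60, 3)) + mesh.vertices.mean(axis=0)
        loc = SurfaceLocator(mesh)
        _, d, _ = loc.closest(pts)
        tri = np.asarray(mesh.triangles)
        for p, dist in zip(pts, d):
            assert abs(_brute_force_distance(p, tri) - dist) < 1e-9

    def test_point_on_surface_distance_zero(self, coarse_baseline):
        mesh = coarse_baseline.root_mesh
        rng = np.random.default_rng(1)
        pts, _ = sample_surface(mesh, 50, rng)
        _, d, _ = SurfaceLocator(mesh).closest(pts)
        assert d.max() < 1e-12


def _brute_force_distance(p, triangles):
    """Plane-projection + edge-clamp point-triangle distance (test oracle)."""
    best = np.inf
    for a, b, c in triangles:
        n = np.cross(b - a, c - a)
        nn = n / np.linalg.norm(n)
        proj = p - np.dot(p - a, nn) * nn
        # inside test via barycentric areas
        area = np.linalg.norm(n)
        w0 = np.dot(np.cross(b - proj, c - proj), nn)
        w1 = np.dot(np.cross(c - proj, a - proj), nn)
        w2 = np.dot(np.cross(a - proj, b - proj), nn)
        if w0 >= -1e-12 * area and w1 >= -1e-12 * area and w2 >= -1e-12 * area:
            cand = np.linalg.norm(p - proj)
        else:
            cand = min(_seg_dist(p, a, b), _seg_dist(p, b, c), _seg_dist(p, c, a))
        best = min(best, cand)
    return best


def _seg_dist(p, a, b):
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
    return np.linalg.norm(p - (a + t * ab))


class TestICP:
    def test_identical_meshes_converge_immediately(self, identity_baseline):
        mesh = identity_baseline.mesh
        T, report = icp_refine(mesh, mesh, cfg=ICPConfig(seed=0))
        assert report.converged
        assert report.iterations <= 2
        assert report.final_residual < 1e-9
        assert T.rotation_angle_deg() < 1e-6
        assert T.translation_norm() < 1e-8

    def test_recovers_known_small_motion_noise_free(self, identity_baseline):
        """A 2-degree / 0.2-mm perturbation of a noise-free phantom is
        recovered within 0.1 degree and 0.01 mm from an identity start."""
        rng = np.random.default_rng(5)
        Tp = random_small_transform(rng, 2.0, 0.2)
        moved = apply_transform(identity_baseline.mesh, Tp)
        T, report = icp_refine(
            moved, identity_baseline.mesh,
            cfg=ICPConfig(seed=0, convergence_tol=1e-6, max_iterations=250))
        err = T.compose(Tp)
        assert err.rotation_angle_deg() < 0.1
        assert err.translation_norm() < 0.01

    def test_single_iteration_reports_nonconvergence(self, identity_baseline):
        rng = np.random.default_rng(2)
        Tp = random_small_transform(rng, 5.0, 1.0)
        moved = apply_transform(identity_baseline.mesh, Tp)
        _, report = icp_refine(moved, identity_baseline.mesh,
                               cfg=ICPConfig(seed=0, max_iterations=1))
        assert report.iterations == 1
        assert not report.converged

    def test_trimmed_residual_monotone_nonincreasing(self, identity_baseline):
        rng = np.random.default_rng(9)
        Tp = random_small_transform(rng, 4.0, 0.5)
        moved = apply_transform(identity_baseline.mesh, Tp)
        _, report = icp_refine(moved, identity_baseline.mesh,
                               cfg=ICPConfig(seed=3))
        res = np.asarray(report.residuals)
        assert np.all(np.diff(res) <= 1e-15)

    def test_empty_mesh_rejected(self, identity_baseline):
        import trimesh
        empty = trimesh.Trimesh(vertices=np.zeros((0, 3)),
                                faces=np.zeros((0, 3), dtype=int), process=False)
        with pytest.raises(ValidationError):
            icp_refine(empty, identity_baseline.mesh)


class TestApplyTransform:
    def test_identity_returns_equal_mesh(self, identity_baseline):
        out = apply_transform(identity_baseline.mesh, RigidTransform.identity())
        assert np.array_equal(out.vertices, identity_baseline.mesh.vertices)
        assert np.array_equal(out.faces, identity_baseline.mesh.faces)

    def test_roundtrip_and_volume_invariance(self, identity_baseline):
        """Rigid motion preserves closed-mesh volume to 1e-9 relative and
        T followed by its inverse restores vertices to 1e-9 mm."""
        rng = np.random.default_rng(4)
        T = RigidTransform(random_rotation(rng), rng.normal(scale=5.0, size=3))
        blob = identity_baseline.sealer_mesh
        moved = apply_transform(blob, T)
        back = apply_transform(moved, T.inverse())
        assert np.abs(back.vertices - blob.vertices).max() < 1e-9
        v0, v1 = mesh_volume(blob), mesh_volume(moved)
        assert abs(v1 - v0) / v0 < 1e-9
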