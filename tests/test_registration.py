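import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from bisym import (CpdConfig, ParameterError, Plane, RigidTransform,
                   apply_transform, cpd_rigid, mirror_across_plane,
                   random_rigid, subsample_points)


class TestSubsamplePoints:
    def test_deterministic_for_fixed_seed(self, tibia_small):
        a = subsample_points(tibia_small, 200, seed=42)
        b = subsample_points(tibia_small, 200, seed=42)
        assert np.array_equal(a, b)

    def test_area_weighted_sampling_law(self):
        """Two triangles with 9:1 areas receive counts in that ratio (3σ)."""
        from bisym import TriangleMesh
        v = np.array([[0.0, 0, 0], [3, 0, 0], [0, 6, 0],     # area 9
                      [10, 0, 0], [11, 0, 0], [10, 2, 0]])   # area 1
        m = TriangleMesh(v, np.array([[0, 1, 2], [3, 4, 5]]))
        n = 4000
        pts = subsample_points(m, n, seed=0)
        frac = (pts[:, 0] >= 10).mean()          # points on the small triangle
        p = 0.1
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_samples_lie_on_surface(self, tetrahedron):
        pts = subsample_points(tetrahedron, 4, seed=1)
        # every sampled point satisfies one of the 4 face-plane equations
        tri = tetrahedron.vertices[tetrahedron.faces]
        normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        off = np.einsum("fi,fi->f", normals, tri[:, 0])
        dist = np.abs(pts @ normals.T - off) / np.linalg.norm(normals, axis=1)
        assert (dist.min(axis=1) < 1e-9).all()

    def test_too_few_points_rejected(self, tetrahedron):
        with pytest.raises(ParameterError):
            subsample_points(tetrahedron, 3, seed=0)


class TestApplyTransform:
    def test_identity_is_noop(self, tetrahedron):
        out = apply_transform(tetrahedron, RigidTransform.identity())
        assert np.array_equal(out.vertices, tetrahedron.vertices)

    def test_translation_moves_origin(self):
        T = RigidTransform(np.eye(3), [1.0, 1, 1])
        assert np.allclose(apply_transform(np.zeros((1, 3)), T), [[1, 1, 1]])


class TestCpdRigid:
    def test_identity_on_identical_clouds(self, tibia_small):
        pts = subsample_points(tibia_small, 300, seed=0)
        res = cpd_rigid(pts, pts, CpdConfig())
        assert np.abs(res.transform.rotation - np.eye(3)).max() < 1e-6
        assert np.abs(res.transform.translation).max() < 1e-6

    def test_recovers_known_transform(self, tibia_small):
        """10° about z + (5,0,0) mm on 500 clean points → exact recovery."""
        pts = subsample_points(tibia_small, 500, seed=3)
        R0 = Rotation.from_euler("z", 10, degrees=True).as_matrix()
        t0 = np.array([5.0, 0, 0])
        res = cpd_rigid(pts, pts @ R0.T + t0, CpdConfig())
        rot_err = Rotation.from_matrix(res.transform.rotation @ R0.T).magnitude()
        assert rot_err < 1e-3
        assert np.abs(res.transform.translation - t0).max() < 1e-3

    def test_robust_to_uniform_outliers(self, tibia_small):
        """20% appended outliers with w=0.2 stay within 0.5° / 0.2 mm."""
        rng = np.random.default_rng(11)
        pts = subsample_points(tibia_small, 500, seed=11)
        R0 = Rotation.from_euler("z", 10, degrees=True).as_matrix()
        t0 = np.array([5.0, 0, 0])
        tgt = pts @ R0.T + t0
        outliers = rng.uniform(tgt.min(0), tgt.max(0), (100, 3))
        res = cpd_rigid(pts, np.vstack([tgt, outliers]), CpdConfig(w=0.2))
        rot_err = Rotation.from_matrix(res.transform.rotation @ R0.T).magnitude()
        assert np.degrees(rot_err) < 0.5
        assert np.linalg.norm(res.transform.translation - t0) < 0.2

    def test_rotation_always_proper(self, tibia_small):
        res = cpd_rigid(subsample_points(tibia_small, 200, seed=0),
                        subsample_points(tibia_small, 200, seed=1), CpdConfig())
        assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0)

    def test_chirality_never_absorbed(self, tibia_small):
        """Registering onto an un-repaired mirror image leaves a large residual:
        a proper rotation cannot supply the reflection."""
        pts = subsample_points(tibia_small, 400, seed=5)
        mirrored = mirror_across_plane(tibia_small,
                                       Plane([0, 0, 0], [1, 0, 0]),
                                       repair_winding=False)
        tgt = subsample_points(mirrored, 400, seed=5)
        res = cpd_rigid(pts, tgt, CpdConfig())
        aligned = apply_transform(pts, res.transform)
        residual = cKDTree(tgt).query(aligned)[0].mean()
        # symmetric (achiral-path) registration residual is ~0; chirality is not
        assert residual > 0.5

    def test_scale_fixed_at_one_without_scaling(self, tibia_small):
        pts = subsample_points(tibia_small, 200, seed=2)
        res = cpd_rigid(pts, 1.05 * pts, CpdConfig(allow_scaling=False))
        assert res.scale == 1.0

    def test_scaling_recovered_when_allowed(self, tibia_small):
        pts = subsample_points(tibia_small, 300, seed=2)
        res = cpd_rigid(pts, 1.05 * pts, CpdConfig(allow_scaling=True))
        assert res.scale == pytest.approx(1.05, abs=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ParameterError):
            cpd_rigid(np.zeros((3, 3)), np.ones((10, 3)), CpdConfig())

    def test_invalid_outlier_weight_rejected(self):
        with pytest.raises(ParameterError):
            CpdConfig(w=1.0)


def test_cpd_beats_exhaustive_grid_search(tibia_small):
    """On a 10-point instance the CPD fit is at least as good (mean nearest
    neighbour after alignment) as the best transform on a coarse grid of
    rotations (5° steps per axis) × translations (1 mm grid)."""
    pts = subsample_points(tibia_small, 10, seed=9)
    R0 = Rotation.from_euler("xyz", [4, -7, 6], degrees=True).as_matrix()
    t0 = np.array([1.5, -0.5, 1.0])
    tgt = pts @ R0.T + t0

    deg = np.arange(-10, 11, 5.0)
    shifts = np.arange(-2, 3, 1.0)
    t_grid = np.array(np.meshgrid(shifts, shifts, shifts)).T.reshape(-1, 3)
    tree = cKDTree(tgt)
    best = np.inf
    for ax in deg:
        for ay in deg:
            for az in deg:
                R = Rotation.from_euler("xyz", [ax, ay, az],
                                        degrees=True).as_matrix()
                moved = (pts @ R.T)[None, :, :] + t_grid[:, None, :]
                d = tree.query(moved.reshape(-1, 3))[0].reshape(len(t_grid), -1)
                best = min(best, d.mean(axis=1).min())
    res = cpd_rigid(pts, tgt, CpdConfig())
    cpd_score = tree.query(apply_transform(pts, res.transform))[0].mean()
    assert cpd_score <= best + 1e-6


def test_objective_trace_non_increasing_with_noise(tibia_small):
    """EM monotonicity holds in the noisy regime as well."""
    rng = np.random.default_rng(21)
    pts = subsample_points(tibia_small, 400, seed=21)
    T = random_rigid(rng, 25, 15)
    tgt = T.apply(pts) + rng.normal(0, 0.3, pts.shape)
    res = cpd_rigid(pts, tgt, CpdConfig())
    tr = np.asarray(res.objective_trace)
    assert (np.diff(tr) <= 1e-9 * np.maximum(1.0, np.abs(tr[:-1]))).all()
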