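import numpy as np
import pytest
from scipy.spatial.distance import cdist

from bisym import (CorrespondenceSet, ParameterError, TriangleMesh,
                   heatmap_field, mask_cut_edge, mask_sphere,
                   nearest_correspondence, read_mesh, subject_summary,
                   write_mesh)
from bisym.cropping import AxisEstimate


def _cs_with_distances(distances):
    """Correspondence set whose pair separations are exactly `distances`."""
    d = np.asarray(distances, dtype=float)
    src = np.column_stack([d, np.zeros_like(d), np.zeros_like(d)])
    tgt = np.zeros((len(d), 3))
    return CorrespondenceSet(src, np.arange(len(d)), tgt, d)


class TestNearestCorrespondence:
    def test_single_point_distance(self):
        m = TriangleMesh(np.array([[0.0, 0, 2], [1, 0, 2], [0, 1, 2]]),
                         np.array([[0, 1, 2]]))
        cs = nearest_correspondence(np.array([[0.0, 0, 0]]), m, mode="vertex")
        assert cs.distances[0] == pytest.approx(2.0)

    def test_identity_gives_zero_distances(self, tibia_small):
        cs = nearest_correspondence(tibia_small.vertices, tibia_small,
                                    mode="vertex")
        assert cs.distances.max() == 0.0

    def test_vertex_mode_matches_exhaustive_scan(self, tibia_small):
        """KD-tree distances equal the O(N²) all-pairs oracle exactly."""
        rng = np.random.default_rng(4)
        pts = rng.uniform(-40, 90, (200, 3))
        tgt = tibia_small.vertices[:200]
        m = TriangleMesh(tgt, np.array([[0, 1, 2]]))
        cs = nearest_correspondence(pts, m, mode="vertex")
        brute = cdist(pts, tgt).min(axis=1)
        assert np.array_equal(cs.distances, brute)

    def test_surface_mode_at_most_vertex_mode(self, tibia_small):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-40, 90, (100, 3))
        dv = nearest_correspondence(pts, tibia_small, mode="vertex").distances
        ds = nearest_correspondence(pts, tibia_small, mode="surface").distances
        assert (ds <= dv + 1e-12).all()

    def test_surface_mode_matches_brute_force_triangles(self, tibia_small):
        """Pruned point-to-triangle search equals the scan over all faces."""
        from bisym._geometry import closest_point_on_triangles
        rng = np.random.default_rng(6)
        pts = rng.uniform(-40, 90, (50, 3))
        ds = nearest_correspondence(pts, tibia_small, mode="surface").distances
        tri = tibia_small.vertices[tibia_small.faces]
        for i, p in enumerate(pts):
            P = np.repeat(p[None], len(tri), axis=0)
            cc = closest_point_on_triangles(P, tri[:, 0], tri[:, 1], tri[:, 2])
            brute = np.linalg.norm(cc - p, axis=1).min()
            assert ds[i] == pytest.approx(brute, abs=1e-9)

    def test_empty_target_rejected(self):
        m = TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(ParameterError):
            nearest_correspondence(np.zeros((1, 3)), m)

    def test_directed_means_bounded_by_hausdorff(self, tibia_small):
        """Both directed mean distances are ≤ the symmetric Hausdorff
        distance (max of the two directed maxima)."""
        rng = np.random.default_rng(9)
        a = TriangleMesh(tibia_small.vertices + rng.normal(0, 0.5, tibia_small.vertices.shape),
                         tibia_small.faces)
        ab = nearest_correspondence(a.vertices, tibia_small, mode="vertex")
        ba = nearest_correspondence(tibia_small.vertices, a, mode="vertex")
        hausdorff = max(ab.distances.max(), ba.distances.max())
        assert ab.distances.mean() <= hausdorff
        assert ba.distances.mean() <= hausdorff


class TestMasking:
    def _axis(self):
        return AxisEstimate([0, 0, 1.0], plateau_level=0.0)

    def test_band_zero_leaves_mask(self):
        cs = _cs_with_distances([1.0, 2.0])
        out = mask_cut_edge(cs, self._axis(), cut_level=-15.0, band=0.0)
        assert out.mask.all()

    def test_all_masked_summary_is_error(self):
        cs = _cs_with_distances([1.0, 2.0])
        cs.mask[:] = False
        with pytest.raises(ParameterError):
            subject_summary(cs, use_mask=True)

    def test_edge_spike_reduced_by_masking(self):
        """A spike confined to the cut edge inflates only the raw mean."""
        z = np.linspace(-15.0, 0.0, 50)
        src = np.column_stack([np.zeros(50), np.zeros(50), z])
        d = np.where(z < -13.5, 3.0, 0.1)      # artifact at the cut
        cs = CorrespondenceSet(src, np.arange(50), src.copy(), d)
        masked = mask_cut_edge(cs, self._axis(), cut_level=-15.0, band=2.0)
        raw = subject_summary(masked, use_mask=False)
        msk = subject_summary(masked, use_mask=True)
        assert msk["mean_mm"] < raw["mean_mm"]

    def test_sphere_exclusion(self):
        cs = _cs_with_distances([1.0, 5.0])
        out = mask_sphere(cs, center=[5.0, 0, 0], radius=1.0)
        assert out.mask.tolist() == [True, False]


class TestSubjectSummary:
    def test_hand_arithmetic(self):
        s = subject_summary(_cs_with_distances([3.0, 4.0]))
        assert s["mean_mm"] == pytest.approx(3.5)
        assert s["rms_mm"] == pytest.approx(np.sqrt(12.5))
        assert s["max_mm"] == pytest.approx(4.0)

    def test_all_zero(self):
        s = subject_summary(_cs_with_distances([0.0, 0.0, 0.0]))
        assert s["mean_mm"] == s["rms_mm"] == s["max_mm"] == 0.0

    def test_half_normal_rms(self):
        """1000 draws of |N(0, 0.3)| have RMS ≈ σ within 3σ sampling error."""
        rng = np.random.default_rng(12)
        d = np.abs(rng.normal(0, 0.3, 1000))
        s = subject_summary(_cs_with_distances(d))
        assert 0.27 < s["rms_mm"] < 0.33

    def test_mean_rms_max_ordering(self):
        rng = np.random.default_rng(13)
        s = subject_summary(_cs_with_distances(rng.gamma(2.0, 0.3, 500)))
        assert s["mean_mm"] <= s["rms_mm"] <= s["max_mm"]


class TestHeatmapField:
    def test_symmetric_pair_all_zero(self, tibia_small):
        cs = nearest_correspondence(tibia_small.vertices, tibia_small,
                                    mode="vertex")
        hm = heatmap_field(tibia_small, cs)
        assert hm.scalar_fields["distance_mm"].max() == 0.0

    def test_size_mismatch_rejected(self, tibia_small):
        with pytest.raises(ParameterError):
            heatmap_field(tibia_small, _cs_with_distances([1.0]))

    def test_roundtrip_through_ply(self, tibia_small, tmp_path):
        cs = nearest_correspondence(
            tibia_small.vertices + [0, 0, 0.25], tibia_small, mode="surface")
        hm = heatmap_field(tibia_small, cs)
        write_mesh(hm, tmp_path / "hm.ply")
        back = read_mesh(tmp_path / "hm.ply")
        assert np.abs(back.scalar_fields["distance_mm"]
                      - hm.scalar_fields["distance_mm"]).max() < 1e-6
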