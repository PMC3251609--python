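"""Distance, overlap and cohort-report statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thalatract as tt

finite = st.floats(-100, 100, allow_nan=False)
vec3 = st.tuples(finite, finite, finite).map(np.array)


class TestEuclideanDistance:
    @pytest.mark.parametrize(
        "p,q,expected",
        [
            ((1.0, 2.0, 3.0), (1.0, 2.0, 3.0), 0.0),
            ((1.0, 2.0, 2.0), (0.0, 0.0, 0.0), 3.0),
            ((2.0, 3.0, 6.0), (0.0, 0.0, 0.0), 7.0),
        ],
    )
    def test_worked_examples(self, p, q, expected):
        assert tt.euclidean_distance(p, q) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(p=vec3, q=vec3, r=vec3)
    def test_metric_axioms(self, p, q, r):
        dpq = tt.euclidean_distance(p, q)
        assert dpq >= 0
        assert dpq == pytest.approx(tt.euclidean_distance(q, p))
        assert tt.euclidean_distance(p, p) == 0
        assert dpq <= tt.euclidean_distance(p, r) + tt.euclidean_distance(r, q) + 1e-9


class TestMeanPairwiseDistance:
    def test_two_points(self):
        s = tt.mean_pairwise_distance([[0, 0, 0], [5, 0, 0]])
        assert s["mean"] == s["min"] == s["max"] == pytest.approx(5.0)
        assert s["n_pairs"] == 1

    def test_collinear_triple(self):
        s = tt.mean_pairwise_distance([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        assert s["mean"] == pytest.approx(4.0 / 3.0)
        assert s["n_pairs"] == 3

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            tt.mean_pairwise_distance([[0, 0, 0]])

    def test_gaussian_cloud_matches_closed_form(self):
        """iid 3D Gaussian points: mean pairwise distance -> 4*sigma/sqrt(pi)."""
        rng = np.random.default_rng(3)
        sigma = 2.0
        pts = rng.normal(0.0, sigma, size=(400, 3))
        s = tt.mean_pairwise_distance(pts)
        assert s["mean"] == pytest.approx(4 * sigma / np.sqrt(np.pi), rel=0.08)


class TestDistanceToReference:
    def test_all_points_on_reference(self):
        d = tt.distance_to_reference([[1, 1, 1]] * 3, [1, 1, 1])
        assert d["mean"] == 0.0

    def test_known_distances(self):
        pts = [[3, 0, 0], [0, 4, 0], [0, 0, 5]]
        d = tt.distance_to_reference(pts, [0, 0, 0])
        assert d["mean"] == pytest.approx(4.0)
        assert d["per_subject"] == pytest.approx([3.0, 4.0, 5.0])

    def test_gaussian_cloud_matches_mean_norm(self):
        """Points scattered around the reference: mean -> sigma*2*sqrt(2/pi)."""
        rng = np.random.default_rng(4)
        sigma = 1.5
        pts = rng.normal(0.0, sigma, size=(400, 3)) + np.array([7.0, -3.0, 2.0])
        d = tt.distance_to_reference(pts, [7.0, -3.0, 2.0])
        assert d["mean"] == pytest.approx(sigma * 2 * np.sqrt(2 / np.pi), rel=0.08)


class TestTanimoto:
    @staticmethod
    def grid(data):
        return tt.VoxelGrid(np.asarray(data, dtype=np.uint8), np.eye(4))

    def test_identical_masks_give_one(self):
        a = np.zeros((4, 4, 4))
        a[1:3, 1:3, 1:3] = 1
        assert tt.tanimoto(self.grid(a), self.grid(a)) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((4, 4, 4))
        b = np.zeros((4, 4, 4))
        a[0, 0, 0] = 1
        b[3, 3, 3] = 1
        assert tt.tanimoto(self.grid(a), self.grid(b)) == 0.0

    def test_counting_example(self):
        """|A|=30, |B|=30, |A∩B|=20 -> 20/40 = 0.5."""
        a = np.zeros((5, 5, 5))
        b = np.zeros((5, 5, 5))
        a.reshape(-1)[:30] = 1
        b.reshape(-1)[10:40] = 1
        assert tt.tanimoto(self.grid(a), self.grid(b)) == 0.5

    def test_symmetry_on_random_masks(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = self.grid(rng.integers(0, 2, (5, 5, 5)))
            b = self.grid(rng.integers(0, 2, (5, 5, 5)))
            assert tt.tanimoto(a, b) == tt.tanimoto(b, a)

    def test_monotone_in_growing_intersection(self):
        """With a fixed union, moving voxels into the intersection raises TC."""
        base = np.zeros((4, 4, 4), dtype=np.uint8)
        base.reshape(-1)[:20] = 1
        prev = -1.0
        for k in (5, 10, 15, 20):
            b = np.zeros_like(base)
            b.reshape(-1)[:k] = 1  # B grows inside A
            val = tt.tanimoto(self.grid(base), self.grid(b))
            assert val > prev
            prev = val

    def test_empty_pair_rejected(self):
        empty = self.grid(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError, match="empty"):
            tt.tanimoto(empty, empty)

    def test_geometry_mismatch_rejected(self):
        a = tt.VoxelGrid(np.ones((3, 3, 3), np.uint8), np.eye(4))
        b = tt.VoxelGrid(np.ones((3, 3, 3), np.uint8), np.diag([2.0, 2, 2, 1]))
        with pytest.raises(ValueError, match="geometry"):
            tt.tanimoto(a, b)


class TestStereotacticTarget:
    LM = dict(AC=[0.0, 12.45, 0.0], PC=[0.0, -12.45, 0.0], IH=[0.0, 0.0, 40.0])

    def test_worked_clinical_construction(self):
        """8 mm anterior of PC, 12.7 mm lateral, right side, AC-PC 24.9 mm."""
        lm = tt.LandmarkSet(**self.LM)
        target = tt.stereotactic_target(lm, 8.0, 12.7, side="right")
        assert np.allclose(target, [-12.7, -4.45, 0.0])

    def test_zero_offsets_return_pc(self):
        lm = tt.LandmarkSet(**self.LM)
        assert np.allclose(tt.stereotactic_target(lm, 0.0, 0.0), lm.PC)

    def test_anterior_projection_matches_offset(self):
        lm = tt.LandmarkSet(**self.LM)
        target = tt.stereotactic_target(lm, 8.0, 12.7, side="left")
        ac_pc = (lm.PC - lm.AC) / np.linalg.norm(lm.PC - lm.AC)
        assert (target - lm.PC) @ (-ac_pc) == pytest.approx(8.0)

    def test_sides_mirror_across_midsagittal_plane(self):
        lm = tt.LandmarkSet(**self.LM)
        right = tt.stereotactic_target(lm, 8.0, 12.7, side="right")
        left = tt.stereotactic_target(lm, 8.0, 12.7, side="left")
        assert right[0] == pytest.approx(-left[0])
        assert right[0] < 0  # right is -x in RAS
        assert np.allclose(right[1:], left[1:])

    def test_fractional_mode(self):
        lm = tt.LandmarkSet(**self.LM)
        frac = tt.stereotactic_target(lm, 0.25, 0.0, fractional=True)
        absolute = tt.stereotactic_target(lm, 0.25 * 24.9, 0.0)
        assert np.allclose(frac, absolute)


class TestCohortReport:
    def test_identical_subjects_degenerate_report(self):
        peaks = {"vop": np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])}
        a = np.zeros((4, 4, 4), dtype=np.uint8)
        a[1:3, 1:3, 1:3] = 1
        masks = {"vop": [tt.VoxelGrid(a, np.eye(4))] * 2}
        rep = tt.build_cohort_report(peaks, masks=masks)
        assert rep.pairwise["vop"]["mean"] == 0.0
        assert rep.overlaps["vop"]["mean"] == 1.0

    def test_pair_count_is_n_choose_2(self):
        rng = np.random.default_rng(6)
        peaks = {"vop": rng.normal(size=(9, 3)), "vim": rng.normal(size=(9, 3))}
        rep = tt.build_cohort_report(peaks)
        for t in ("vop", "vim"):
            assert len(rep.pairwise_values[t]) == 36
        rep.validate()

    def test_reference_distances_included(self):
        peaks = {"vop": np.array([[3.0, 0, 0], [0, 4.0, 0]])}
        rep = tt.build_cohort_report(peaks, references={"atlas": [0.0, 0.0, 0.0]})
        assert rep.reference_distances["atlas"]["vop"]["mean"] == pytest.approx(3.5)

    def test_roundtrip_and_table(self, tmp_path):
        rng = np.random.default_rng(7)
        rep = tt.build_cohort_report({"vop": rng.normal(size=(4, 3))})
        rep.save(tmp_path / "report.json")
        table = rep.pairwise_table()
        assert len(table) == 6
        assert set(table.columns) >= {"target", "subject_a", "subject_b", "distance_mm"}

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            tt.build_cohort_report({"vop": np.array([[0.0, 0.0, 0.0]])})
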