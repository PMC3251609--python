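"""Phantom generator: determinism, geometry invariants, cohort statistics."""

import dataclasses

import numpy as np
import pytest
from scipy.spatial.distance import pdist

import thalatract as tt
from thalatract.phantom import BundleSpec, PhantomSpec


def centered_single_bundle_spec(seed=0):
    """One bundle whose thalamic origin sits at the thalamus center.

    Maximizes the clearance between the origin and the thalamus boundary so
    that Gaussian peak displacement is effectively never clamped.
    """
    return PhantomSpec(
        bundles=[
            BundleSpec(
                target_name="motor",
                thalamic_origin_mm=[10.0, 16.0, 14.0],
                cortical_patch_center_mm=[27.0, 16.0, 16.0],
                cortical_patch_radius_mm=3.0,
            )
        ],
        seed=seed,
    )


class TestGenerateSubject:
    def test_target_keys_mirror_spec(self, default_subject):
        assert set(default_subject.target_masks) == {"premotor", "motor"}
        assert set(default_subject.truth_peaks_mm) == {"premotor", "motor"}

    def test_deterministic_given_spec(self):
        spec = tt.default_spec(seed=3)
        a = tt.generate_subject(spec)
        b = tt.generate_subject(spec)
        assert np.array_equal(a.thalamus_mask.data, b.thalamus_mask.data)
        assert np.array_equal(
            a.orientation_field.directions, b.orientation_field.directions
        )
        for k in a.truth_peaks_mm:
            assert np.array_equal(a.truth_peaks_mm[k], b.truth_peaks_mm[k])

    def test_truth_peaks_equal_bundle_origins(self):
        spec = tt.default_spec(seed=0)
        subj = tt.generate_subject(spec)
        for b in spec.bundles:
            assert np.allclose(subj.truth_peaks_mm[b.target_name], b.thalamic_origin_mm)

    def test_masks_nested_and_disjoint(self, default_subject):
        default_subject.validate()  # thalamus/target containment + disjointness
        brain = default_subject.brain_mask.data.astype(bool)
        thal = default_subject.thalamus_mask.data.astype(bool)
        assert np.all(brain[thal])

    def test_orientations_unit_norm(self, default_subject):
        f = default_subject.orientation_field
        sel = f.n_directions > 0
        norms = np.linalg.norm(f.directions[sel, 0, :], axis=-1)
        assert np.allclose(norms, 1.0, atol=1e-9)

    def test_straight_zero_dispersion_bundle_is_axis_parallel(self):
        """A straight bundle's on-tube orientations equal the bundle axis."""
        spec = centered_single_bundle_spec()
        # remove curvature by monkeypatching the control-point fraction
        import thalatract.phantom as ph

        old = ph.CURVATURE_FRACTION
        ph.CURVATURE_FRACTION = 0.0
        try:
            subj = tt.generate_subject(spec)
        finally:
            ph.CURVATURE_FRACTION = old
        b = spec.bundles[0]
        axis = b.cortical_patch_center_mm - b.thalamic_origin_mm
        axis = axis / np.linalg.norm(axis)
        f = subj.orientation_field
        sel = f.n_directions > 0
        dots = f.directions[sel, 0, :] @ axis
        assert np.all(np.abs(np.abs(dots) - 1.0) < 1e-9)

    @pytest.mark.parametrize(
        "mutation",
        [
            {"voxel_size_mm": -1.0},
            {"grid_shape": (8, 32, 32)},
            {"thalamus_radius_mm": -2.0},
        ],
    )
    def test_invalid_spec_rejected(self, mutation):
        with pytest.raises(ValueError):
            dataclasses.replace(tt.default_spec(), **mutation)

    def test_patch_overlapping_thalamus_rejected(self):
        with pytest.raises(ValueError, match="overlaps the thalamus"):
            PhantomSpec(
                bundles=[
                    BundleSpec(
                        target_name="bad",
                        thalamic_origin_mm=[10.0, 16.0, 14.0],
                        cortical_patch_center_mm=[14.0, 16.0, 14.0],
                        cortical_patch_radius_mm=3.0,
                    )
                ]
            )

    def test_spec_yaml_roundtrip(self, tmp_path):
        spec = tt.default_spec(seed=5)
        p = tmp_path / "spec.yaml"
        spec.save(p)
        again = PhantomSpec.load(p)
        assert again.to_dict() == spec.to_dict()


class TestGenerateCohort:
    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            tt.generate_cohort(tt.default_spec(), 1, 1.0, seed=0)

    def test_zero_sd_gives_identical_truth_peaks(self):
        subs = tt.generate_cohort(tt.default_spec(), 4, 0.0, seed=0)
        ref = subs[0].truth_peaks_mm
        for s in subs[1:]:
            for k in ref:
                assert np.allclose(s.truth_peaks_mm[k], ref[k])

    def test_cohort_size_and_validity(self):
        subs = tt.generate_cohort(tt.default_spec(), 5, 2.0, seed=1)
        assert len(subs) == 5
        for s in subs:
            s.validate()

    def test_reproducible_given_seed(self):
        a = tt.generate_cohort(tt.default_spec(), 3, 2.0, seed=9)
        b = tt.generate_cohort(tt.default_spec(), 3, 2.0, seed=9)
        for sa, sb in zip(a, b):
            for k in sa.truth_peaks_mm:
                assert np.array_equal(sa.truth_peaks_mm[k], sb.truth_peaks_mm[k])

    def test_offset_sd_matches_requested(self):
        """Empirical SD of truth-peak offsets tracks peak_sd_mm.

        Offsets are iid per axis, so the three axes are pooled into one SD
        estimate (750 samples) to keep the estimator noise well inside the
        tolerance.
        """
        base = centered_single_bundle_spec()
        subs = tt.generate_cohort(base, 250, 1.0, seed=7)
        pts = np.array([s.truth_peaks_mm["motor"] for s in subs])
        offsets = pts - base.bundles[0].thalamic_origin_mm
        pooled_sd = offsets.ravel().std(ddof=1)
        assert abs(pooled_sd - 1.0) < 0.10

    def test_mean_pairwise_matches_closed_form(self):
        """Truth-peak mean pairwise distance ~ 4*sigma/sqrt(pi) (3D Gaussian)."""
        base = centered_single_bundle_spec()
        subs = tt.generate_cohort(base, 200, 1.0, seed=11)
        pts = np.array([s.truth_peaks_mm["motor"] for s in subs])
        expected = 4 * 1.0 / np.sqrt(np.pi)
        assert abs(pdist(pts).mean() - expected) / expected < 0.10

    def test_landmark_jitter_recorded_and_consistent(self):
        """The recorded world transform maps base geometry onto the subject's."""
        base = tt.default_spec(seed=2)
        subs = tt.generate_cohort(
            base, 3, 0.0, seed=2, landmark_jitter_deg=5.0, landmark_jitter_mm=4.0
        )
        base_lm = tt.LandmarkSet(**base.landmark_positions_mm)
        for s in subs:
            T = s.world_transform
            assert T is not None
            assert np.allclose(T.apply(base_lm.AC), s.landmarks.AC, atol=1e-9)
            for b in base.bundles:
                assert np.allclose(
                    T.apply(b.thalamic_origin_mm),
                    s.truth_peaks_mm[b.target_name],
                    atol=1e-9,
                )

    def test_subject_roundtrip_on_disk(self, tmp_path):
        subs = tt.generate_cohort(tt.default_spec(), 2, 1.0, seed=4,
                                  landmark_jitter_deg=3.0, landmark_jitter_mm=2.0)
        tt.write_subject(subs[0], tmp_path, 0)
        again = tt.read_subject(tmp_path, 0)
        assert np.array_equal(again.thalamus_mask.data, subs[0].thalamus_mask.data)
        assert np.allclose(
            again.orientation_field.directions,
            subs[0].orientation_field.directions,
        )
        for k in subs[0].truth_peaks_mm:
            assert np.allclose(again.truth_peaks_mm[k], subs[0].truth_peaks_mm[k])
        assert np.allclose(
            again.world_transform.to_matrix(), subs[0].world_transform.to_matrix()
        )
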