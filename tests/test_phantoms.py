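"""Phantom generators: analytic ground truth, determinism, parameter errors."""
import numpy as np
import pytest

from airwaykit.errors import ParameterError
from airwaykit.phantoms import (BreathSpec, CohortSpec, MouseAirwayConfig,
                                make_breath_trace, make_morphometry_cohort,
                                make_mouse_airway_phantom, make_tube_phantom,
                                make_venturi_phantom)


class TestTube:
    def test_mask_volume_matches_pi_r2_l(self, tube_005):
        _, mask, truth = tube_005
        assert mask.volume_mm3 == pytest.approx(truth.volume_true_mm3, rel=0.02)
        assert truth.volume_true_mm3 == pytest.approx(np.pi * 0.25 * 10.0, rel=1e-6)

    def test_axial_slice_area(self, tube_fine):
        _, mask, _ = tube_fine
        k = mask.shape[2] // 2
        area = mask.voxels[:, :, k].sum() * mask.spacing_mm[0] * mask.spacing_mm[1]
        assert area == pytest.approx(np.pi * 0.25, rel=0.02)

    def test_intensity_levels(self, tube_005):
        vol, mask, _ = tube_005
        assert vol.voxels[mask.voxels].max() == -1000
        assert vol.voxels.max() == 1000  # bone shell present

    def test_coarse_grid_warns(self):
        with pytest.warns(UserWarning, match="diameter"):
            make_tube_phantom(0.5, 2.0, 0.25)

    @pytest.mark.parametrize("bad", [dict(radius_mm=-1), dict(length_mm=0),
                                     dict(spacing_mm=-0.1)])
    def test_nonpositive_dimensions_rejected(self, bad):
        kwargs = dict(radius_mm=0.5, length_mm=2.0, spacing_mm=0.05)
        kwargs.update(bad)
        with pytest.raises(ParameterError):
            make_tube_phantom(**kwargs)


class TestVenturi:
    def test_throat_minimum_area(self, venturi_004):
        _, _, truth = venturi_004
        prof = truth.area_profile_true
        assert prof[:, 1].min() == pytest.approx(np.pi * 0.4**2, rel=1e-6)
        # minimum attained inside the throat section
        s_min = prof[np.argmin(prof[:, 1]), 0]
        assert 3.0 + 1.5 <= s_min <= 3.0 + 1.5 + 2.0

    def test_profile_monotone_through_tapers(self, venturi_004):
        _, _, truth = venturi_004
        s, a = truth.area_profile_true.T
        inlet_taper = (s >= 3.0) & (s <= 4.5)
        outlet_taper = (s >= 6.5) & (s <= 8.0)
        assert np.all(np.diff(a[inlet_taper]) <= 1e-12)
        assert np.all(np.diff(a[outlet_taper]) >= -1e-12)

    def test_throat_wider_than_inlet_rejected(self):
        with pytest.raises(ParameterError):
            make_venturi_phantom(0.4, 0.5)


class TestMouseAirway:
    def test_landmarks_inside_mask(self, mouse_005):
        _, mask, lms, _ = mouse_005
        for name in ("nostril_left", "nostril_right", "meatus_merge",
                     "hard_palate_edge", "epiglottis", "arytenoid"):
            idx = mask.world_to_index(lms.get(name))
            assert mask.voxels[tuple(idx)], name

    def test_uniform_scale_squares_areas(self, mouse_005, mouse_scaled_005):
        _, _, _, truth = mouse_005
        _, _, _, truth_s = mouse_scaled_005
        ratio = truth_s.area_profile_true[:, 1] / truth.area_profile_true[:, 1]
        assert ratio == pytest.approx(np.full_like(ratio, 0.64), rel=1e-6)

    def test_ground_truth_self_consistent(self, mouse_005):
        _, _, _, truth = mouse_005
        assert truth.integrated_volume_mm3() == pytest.approx(
            truth.volume_true_mm3, rel=0.01
        )

    def test_nasal_split_variant_generates(self):
        cfg = MouseAirwayConfig(spacing_mm=0.08, nasal_split=True)
        _, mask, lms, truth = make_mouse_airway_phantom(cfg)
        # the two nostrils land in distinct lateral passages
        li = mask.world_to_index(lms.get("nostril_left"))
        ri = mask.world_to_index(lms.get("nostril_right"))
        assert mask.voxels[tuple(li)] and mask.voxels[tuple(ri)]
        mid = (li + ri) // 2
        assert not mask.voxels[tuple(mid)]  # septum between the passages

    def test_bad_landmark_order_rejected(self):
        with pytest.raises(ParameterError):
            MouseAirwayConfig(s_meatus_merge_mm=9.0, s_hard_palate_mm=4.0).validate()


class TestBreathTrace:
    def test_tidal_volume_is_volume_excursion(self):
        spec = BreathSpec(tidal_volume_ml=0.15, rate_bpm=150, ti_fraction=0.5,
                          duration_s=10.0)
        tr = make_breath_trace(spec)
        excursion = tr.volume_ml.max() - tr.volume_ml.min()
        assert excursion == pytest.approx(0.15, rel=0.01)

    def test_peak_inspiratory_flow_analytic(self):
        # Ti = 0.2 s half-sine integrating to 0.15 ml peaks at pi TV / (2 Ti)
        spec = BreathSpec(tidal_volume_ml=0.15, rate_bpm=150, ti_fraction=0.5,
                          duration_s=5.0)
        tr = make_breath_trace(spec)
        assert tr.flow_ml_s.max() == pytest.approx(np.pi * 0.15 / (2 * 0.2), rel=0.01)

    def test_seeded_traces_bit_identical(self):
        spec = BreathSpec(noise_sd=0.2, seed=7, duration_s=5.0)
        a = make_breath_trace(spec)
        b = make_breath_trace(spec)
        assert np.array_equal(a.flow_ml_s, b.flow_ml_s)
        assert np.array_equal(a.volume_ml, b.volume_ml)

    def test_undersampled_spec_rejected(self):
        with pytest.raises(ParameterError):
            make_breath_trace(BreathSpec(rate_bpm=600), sampling_hz=100.0)


class TestCohort:
    def test_sample_means_converge(self):
        spec = CohortSpec(measures={"b": (7.93, 0.17, 7.33, 0.20)},
                          n_g1=10_000, n_g2=10_000, seed=3)
        g1, g2 = make_morphometry_cohort(spec)
        m1 = np.mean([t.values["b"] for t in g1])
        m2 = np.mean([t.values["b"] for t in g2])
        assert abs(m1 - 7.93) < 0.01
        assert abs(m2 - 7.33) < 0.01

    def test_reproducible_under_seed(self):
        spec = CohortSpec(measures={"a": (7.0, 0.2, 6.8, 0.2)}, seed=11)
        a1, _ = make_morphometry_cohort(spec)
        a2, _ = make_morphometry_cohort(spec)
        assert [t.values for t in a1] == [t.values for t in a2]

    def test_type_one_error_calibrated(self):
        """Identical moments in both groups: Welch rejects ~5% of cohorts."""
        from airwaykit.stats import welch_from_summary_arrays

        rng = np.random.default_rng(123)
        reps = 1000
        x = rng.normal(7.0, 0.2, (reps, 8))
        y = rng.normal(7.0, 0.2, (reps, 7))
        _, _, p = welch_from_summary_arrays(
            x.mean(1), x.std(1, ddof=1), 8, y.mean(1), y.std(1, ddof=1), 7
        )
        assert abs(float((p < 0.05).mean()) - 0.05) <= 0.02
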