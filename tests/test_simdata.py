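"""Synthetic RF ensembles and cohorts: power control, determinism, truth."""

import numpy as np
import pytest

from pdus import (
    CohortSpec,
    GroundTruthSpec,
    casorati,
    default_rois,
    ischemic_truth_curve,
    pdus_power,
    simulate_cohort,
    simulate_control_profile,
    simulate_ensemble,
    simulate_mouse_profile,
)


def _spec(**kw):
    base = dict(respiration_amplitude_mm=0.0, axial_drift_mm_per_s=0.0)
    base.update(kw)
    return GroundTruthSpec(**base)


class TestEnsembleSimulation:
    def test_static_noiseless_field_is_rank_one(self, small_geom):
        spec = _spec(blood_power_db=-np.inf, noise_power_db=-np.inf, seed=1)
        ens = simulate_ensemble(spec, small_geom)
        for f in range(1, 16):
            np.testing.assert_array_equal(ens.frames[f], ens.frames[0])
        s = np.linalg.svd(casorati(ens), compute_uv=False)
        assert s[0] ** 2 / np.sum(s**2) == pytest.approx(1.0, abs=1e-12)

    def test_blood_only_power_matches_target(self, small_geom):
        # sample-mean oracle over repeated seeds, clutter and noise disabled
        target_db = 3.0
        roi = default_rois(small_geom)[0]
        powers = []
        for seed in range(20):
            spec = _spec(
                clutter_power_db=-np.inf,
                blood_power_db=target_db,
                noise_power_db=-np.inf,
                seed=seed,
            )
            ens = simulate_ensemble(spec, small_geom)
            powers.append(pdus_power(casorati(ens, roi)))
        mean_db = 10 * np.log10(np.mean(powers))
        assert mean_db == pytest.approx(target_db, abs=0.5)

    def test_power_additivity(self, small_geom):
        # total power equals the sum of component target powers
        spec = _spec(clutter_power_db=20.0, blood_power_db=0.0,
                     noise_power_db=10.0, seed=3)
        ens = simulate_ensemble(spec, small_geom)
        expected = 10**2.0 + 1.0 + 10**1.0
        assert np.mean(ens.frames**2) == pytest.approx(expected, rel=0.05)

    def test_echo_snr_is_controlled(self, small_geom):
        # measured (clutter+blood)/noise over seeds within +/- 0.5 dB
        snrs = []
        for seed in range(20):
            spec = GroundTruthSpec(seed=seed)
            sig = simulate_ensemble(
                _spec(noise_power_db=-np.inf, seed=seed), small_geom
            )
            noise = simulate_ensemble(
                _spec(clutter_power_db=-np.inf, blood_power_db=-np.inf,
                      noise_power_db=spec.noise_power_db, seed=seed),
                small_geom,
            )
            snrs.append(
                10 * np.log10(np.mean(sig.frames**2) / np.mean(noise.frames**2))
            )
        assert np.mean(snrs) == pytest.approx(
            GroundTruthSpec().echo_snr_db, abs=0.5
        )
        assert GroundTruthSpec().echo_snr_db == pytest.approx(15.0, abs=0.1)

    def test_identical_seeds_are_bit_identical(self, small_geom):
        a = simulate_ensemble(GroundTruthSpec(seed=7), small_geom)
        b = simulate_ensemble(GroundTruthSpec(seed=7), small_geom)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_non_physical_parameters_rejected(self):
        with pytest.raises(ValueError):
            GroundTruthSpec(scatterer_density_per_mm2=-1.0)
        with pytest.raises(ValueError):
            GroundTruthSpec(respiration_amplitude_mm=-0.01)
        with pytest.raises(ValueError):
            GroundTruthSpec(blood_speed_mm_per_s=-1.0)
        with pytest.raises(ValueError):
            GroundTruthSpec(clutter_power_db=np.nan)

    def test_perfusion_curve_must_be_zero_at_baseline(self):
        with pytest.raises(ValueError, match="pre"):
            GroundTruthSpec(perfusion_curve={"pre": -3.0})

    def test_unknown_schedule_time_rejected(self, small_geom):
        with pytest.raises(ValueError):
            simulate_ensemble(GroundTruthSpec(), small_geom, t="5 d")


class TestProfileSimulation:
    def test_truth_curve_hits_its_defining_points(self):
        curve = ischemic_truth_curve(3.0, -6.0, 9.0)
        assert curve["pre"] == 0.0
        assert curve["1 d"] == pytest.approx(-6.0)
        # 20-min point sits P_max above the acute trend through 10/30/60 min
        import math
        s = 0.6 * -6.0 / math.log10(60.0) ** 2
        assert curve["20 m"] - s * math.log10(20.0) ** 2 == pytest.approx(3.0)

    def test_profile_baseline_is_zero_and_noise_seeded(self):
        a = simulate_mouse_profile(3, -6, 9, noise_sd_db=0.5, seed=3)
        b = simulate_mouse_profile(3, -6, 9, noise_sd_db=0.5, seed=3)
        assert a.value("pre") == 0.0
        np.testing.assert_array_equal(a.values_db, b.values_db)

    def test_invalid_truth_rejected(self):
        with pytest.raises(ValueError):
            ischemic_truth_curve(3.0, 1.0, 9.0)  # positive minimum
        with pytest.raises(ValueError):
            ischemic_truth_curve(3.0, -6.0, 40.0)  # T beyond the study

    def test_control_profile_is_flat_truth(self):
        p = simulate_control_profile(noise_sd_db=0.0, seed=0)
        assert np.all(p.values_db == 0.0)
        assert p.limb == "control"


class TestCohortSimulation:
    def test_zero_spread_makes_identical_mice(self):
        cs = CohortSpec(
            groups=[("HS", "M")], n_per_group=3,
            param_sds=(0.0, 0.0, 0.0), noise_sd_db=0.0, seed=1,
        )
        cohort = simulate_cohort(cs)
        v = [p.values_db for p in cohort.profiles]
        np.testing.assert_array_equal(v[0], v[1])
        np.testing.assert_array_equal(v[0], v[2])

    def test_empty_group_list_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(groups=[])

    def test_records_align_with_profiles(self):
        cohort = simulate_cohort(CohortSpec(n_per_group=2, seed=2))
        assert len(cohort.records) == len(cohort.profiles)
        assert set(cohort.records.mouse_id) == {
            p.mouse_id for p in cohort.profiles
        }
        tidy = cohort.to_tidy()
        assert {"mouse_id", "group", "time_label", "pdus_db"} <= set(tidy.columns)

    def test_cohort_reproducible_given_seed(self):
        a = simulate_cohort(CohortSpec(n_per_group=2, seed=9))
        b = simulate_cohort(CohortSpec(n_per_group=2, seed=9))
        for pa, pb in zip(a.profiles, b.profiles):
            np.testing.assert_array_equal(pa.values_db, pb.values_db)
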