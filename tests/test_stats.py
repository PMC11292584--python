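"""Box-Cox, rank tests vs enumeration oracles, ANCOVA, diabetic rule."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from pdus import (
    GlucoseAssay,
    MouseRecord,
    ancova_adjusted_comparison,
    box_cox,
    classify_diabetic,
    compare_at_timepoint,
    compare_profiles,
    offset_to_positive,
)
from pdus.stats import box_cox_inverse, box_cox_transform


class TestBoxCox:
    def test_lambda_one_is_location_shift(self):
        x = np.array([1.0, 2.0, 5.0])
        np.testing.assert_allclose(box_cox_transform(x, 1.0), x - 1.0)

    def test_transform_inverse_identity(self, rng):
        x = rng.uniform(0.5, 8.0, size=40)
        for lam in (0.1, 0.5, 1.0, 1.1):
            np.testing.assert_allclose(
                box_cox_inverse(box_cox_transform(x, lam), lam), x, atol=1e-12
            )

    def test_lambda_selected_within_range(self, rng):
        x = rng.lognormal(0.0, 0.8, size=60)
        _, lam = box_cox(x)
        assert 0.1 <= lam <= 1.1

    def test_non_positive_inputs_guide_to_offset(self):
        with pytest.raises(ValueError, match="offset"):
            box_cox(np.array([-1.0, 2.0, 3.0]))
        shifted, offset = offset_to_positive(np.array([-1.0, 2.0, 3.0]))
        assert shifted.min() == 1.0
        assert offset == 2.0

    def test_lognormal_normality_improves(self):
        # over repeated draws the transformed sample passes a normality
        # check more often than the raw sample
        raw_pass = trans_pass = 0
        for seed in range(200):
            x = np.random.default_rng(seed).lognormal(0.0, 1.0, size=40)
            raw_pass += sps.shapiro(x).pvalue > 0.05
            trans_pass += sps.shapiro(box_cox(x)[0]).pvalue > 0.05
        assert trans_pass > raw_pass


def _exact_ranksum_p(x, y):
    """Exhaustive enumeration oracle for the two-sided rank-sum test."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    w_obs = ranks[: len(x)].sum()
    ws = [sum(ranks[list(c)]) for c in combinations(range(n), len(x))]
    ws = np.array(ws)
    mu = ws.mean()
    p = np.mean(np.abs(ws - mu) >= abs(w_obs - mu) - 1e-12)
    return float(p)


def _exact_kruskal_p(x, y):
    """Exhaustive permutation oracle for the two-group H statistic."""
    pooled = np.concatenate([x, y])
    n, na = len(pooled), len(x)

    def h_stat(mask):
        ranks = sps.rankdata(pooled)
        ra, rb = ranks[mask], ranks[~mask]
        h = 12.0 / (n * (n + 1)) * (
            ra.sum() ** 2 / len(ra) + rb.sum() ** 2 / len(rb)
        ) - 3 * (n + 1)
        return h

    obs_mask = np.zeros(n, dtype=bool)
    obs_mask[:na] = True
    h_obs = h_stat(obs_mask)
    hs = []
    for c in combinations(range(n), na):
        m = np.zeros(n, dtype=bool)
        m[list(c)] = True
        hs.append(h_stat(m))
    return float(np.mean(np.array(hs) >= h_obs - 1e-12))


class TestRankTests:
    def test_complete_separation_exact_p(self):
        # n = 3 vs 3, complete separation: 2 of 20 assignments are as
        # extreme -> p = 0.1 two-sided
        p = compare_at_timepoint([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_curves_give_p_one(self):
        vals = np.array([0.0, -1.0, 2.0, -3.0, -5.0, -4.0, -2.0, 0.5])
        for method in ("kruskal_wallis", "wilcoxon"):
            assert compare_profiles(vals, vals.copy(), method=method) == \
                pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_ranksum_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(3, 6, size=2)
        x = rng.normal(0, 1, na)
        y = rng.normal(0.8, 1, nb)
        assert compare_at_timepoint(x, y) == pytest.approx(
            _exact_ranksum_p(x, y), abs=1e-10
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_kruskal_matches_enumeration_oracle(self, seed):
        from pdus.stats import _kruskal_p

        rng = np.random.default_rng(100 + seed)
        na, nb = rng.integers(3, 6, size=2)
        x = rng.normal(0, 1, na)
        y = rng.normal(0.8, 1, nb)
        assert _kruskal_p(x, y) == pytest.approx(
            _exact_kruskal_p(x, y), abs=1e-10
        )

    def test_mismatched_schedules_fail(self):
        with pytest.raises(ValueError, match="schedule"):
            compare_profiles([1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="schedules"):
            compare_profiles([1.0, 2.0], [1.0, 2.0],
                             labels_a=["pre", "1 d"], labels_b=["pre", "2 d"])

    def test_registration_comparison_scenario_retains_null(self):
        # two pipelines differing only by sub-resolution-cell motion handling
        # produce statistically indistinguishable profiles
        from pdus import simulate_mouse_profile

        a = simulate_mouse_profile(3.0, -6.0, 9.0, noise_sd_db=0.3, seed=1)
        b = simulate_mouse_profile(3.0, -6.0, 9.0, noise_sd_db=0.3, seed=2)
        for method in ("t", "kruskal_wallis", "wilcoxon"):
            assert compare_profiles(a.values_db, b.values_db,
                                    method=method) > 0.05


class TestAncova:
    def test_reproducible_given_seed(self, rng):
        ya, yb = rng.normal(0, 1, 8), rng.normal(0, 1, 8)
        ca, cb = rng.normal(10, 2, (8, 2)), rng.normal(12, 2, (8, 2))
        p1 = ancova_adjusted_comparison(ya, yb, ca, cb, n_perm=499, seed=42)
        p2 = ancova_adjusted_comparison(ya, yb, ca, cb, n_perm=499, seed=42)
        assert p1 == p2

    def test_permutation_p_converges_with_n_perm(self, rng):
        ya, yb = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
        ca, cb = rng.normal(10, 2, (10, 1)), rng.normal(10, 2, (10, 1))
        ps = [
            ancova_adjusted_comparison(ya, yb, ca, cb, n_perm=999, seed=s)
            for s in range(8)
        ]
        p_bar = np.mean(ps)
        assert np.std(ps) < 4 * np.sqrt(p_bar * (1 - p_bar) / 999) + 1e-3

    def test_constant_covariate_dropped_with_warning(self, rng):
        ya, yb = rng.normal(0, 1, 6), rng.normal(0, 1, 6)
        ca = np.column_stack([np.full(6, 3.0), rng.normal(0, 1, 6)])
        cb = np.column_stack([np.full(6, 3.0), rng.normal(0, 1, 6)])
        with pytest.warns(UserWarning, match="constant"):
            p = ancova_adjusted_comparison(ya, yb, ca, cb, n_perm=199, seed=0)
        assert 0.0 < p <= 1.0

    def test_confounded_effect_is_adjusted_away(self):
        # group difference driven purely by a weight->response slope:
        # the covariate-adjusted test retains the null in most replicates
        retained = 0
        n_sims = 100
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            wa = rng.normal(35.0, 3.0, 10)
            wb = rng.normal(55.0, 3.0, 10)  # heavier group
            slope = 0.1
            ya = slope * wa + rng.normal(0, 0.5, 10)
            yb = slope * wb + rng.normal(0, 0.5, 10)
            p = ancova_adjusted_comparison(ya, yb, wa[:, None], wb[:, None],
                                           n_perm=199, seed=seed)
            retained += p > 0.05
        assert retained >= 0.80 * n_sims

    def test_equal_mean_subcohorts_can_be_pooled(self, rng):
        # two sub-cohorts measured months apart with different age/weight but
        # the same perfusion mean: the adjusted test accepts equality
        ya, yb = rng.normal(-6.0, 0.6, 9), rng.normal(-6.0, 0.6, 9)
        ca = np.column_stack([rng.normal(10, 1, 9), rng.normal(35, 3, 9)])
        cb = np.column_stack([rng.normal(24, 1, 9), rng.normal(55, 3, 9)])
        p = ancova_adjusted_comparison(ya, yb, ca, cb, n_perm=999, seed=7)
        assert p > 0.05

    def test_small_groups_fail(self):
        with pytest.raises(ValueError):
            ancova_adjusted_comparison([1.0, 2.0], [1.0, 2.0, 3.0],
                                       [[1], [2]], [[1], [2], [3]])


def _assay(baseline, excursion, rng=None):
    """Glucose assay rising to baseline+excursion at 30 min, then decaying."""
    noise = rng.normal(0, 5, 5) if rng is not None else np.zeros(5)
    vals = np.array([
        baseline,
        baseline + 10,
        baseline + excursion,
        baseline + 0.6 * excursion,
        baseline + 0.25 * excursion,
    ]) + noise
    return GlucoseAssay(glucose_mg_dl=tuple(float(v) for v in vals))


class TestDiabeticRule:
    def _references(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        return [_assay(rng.uniform(110, 160), rng.uniform(80, 140), rng)
                for _ in range(n)]

    def test_trapezoid_auc_hand_integration(self):
        a = GlucoseAssay(glucose_mg_dl=(150.0, 300.0, 300.0, 300.0, 300.0))
        assert a.auc(0, 30) == pytest.approx(9000.0)
        assert a.auc(30, 90) == pytest.approx(18000.0)

    def test_low_baseline_gates_negative(self):
        refs = self._references()
        hot = _assay(150.0, 400.0)  # huge excursion but normal fasting level
        out = classify_diabetic(hot, refs)
        assert not out["positive"]
        assert not out["baseline_above_threshold"]

    def test_simulated_diabetic_cohort_is_positive(self):
        refs = self._references()
        positives = 0
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            assay = _assay(rng.uniform(230, 280), rng.uniform(280, 380), rng)
            positives += classify_diabetic(assay, refs)["positive"]
        assert positives >= 38  # >= 95%

    def test_small_reference_cohort_warns(self):
        refs = self._references(n=5)
        with pytest.warns(UserWarning, match="reference"):
            classify_diabetic(_assay(250.0, 300.0), refs)

    def test_incomplete_assay_fails(self):
        with pytest.raises(ValueError):
            GlucoseAssay(glucose_mg_dl=(100.0, 120.0, 200.0))


class TestRecords:
    def test_mouse_record_validation(self):
        MouseRecord("m1", "HS", "M", age_months=10.0, weight_g=34.0)
        with pytest.raises(ValueError):
            MouseRecord("m2", "DS", "F", age_months=-1.0, weight_g=50.0)
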