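"""Agreement statistics against hand computations and independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lithovol.agreement import (
    MeasurementTable,
    agreement_report,
    bland_altman,
    coefficient_of_variation,
    kendall_w,
    lin_ccc,
    mann_whitney_u,
    paired_t_test,
)


class TestLinCCC:
    def test_perfect_agreement(self, rng):
        x = rng.normal(1000, 300, size=30)
        res = lin_ccc(x, x)
        assert res["ccc"] == pytest.approx(1.0)

    def test_shift_penalizes_below_pearson(self):
        # x=[1,2,3], y=x+1: r=1 but ccc = 2*(2/3)/(2/3+2/3+1) = 4/7
        res = lin_ccc([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res["ccc"] == pytest.approx(4.0 / 7.0)

    def test_ccc_is_pearson_times_accuracy_factor(self, rng):
        for _ in range(10):
            x = rng.normal(0, 1, 25)
            y = 0.5 * x + rng.normal(0.3, 0.8, 25)
            ccc = lin_ccc(x, y)["ccc"]
            r = stats.pearsonr(x, y)[0]
            cb = ccc / r
            assert 0 < cb <= 1 + 1e-12
            assert abs(ccc) <= abs(r) + 1e-12

    def test_symmetric_in_arguments(self, rng):
        x, y = rng.normal(10, 3, 20), rng.normal(12, 2, 20)
        assert lin_ccc(x, y)["ccc"] == pytest.approx(lin_ccc(y, x)["ccc"])

    def test_invariant_under_common_rescaling_only(self, rng):
        x = rng.normal(100, 30, 25)
        y = x + rng.normal(0, 10, 25)
        base = lin_ccc(x, y)["ccc"]
        assert lin_ccc(3 * x, 3 * y)["ccc"] == pytest.approx(base)
        # rescaling one series breaks agreement
        assert lin_ccc(3 * x, y)["ccc"] < base

    def test_ci_brackets_point_estimate_and_shrinks_with_n(self, rng):
        x = rng.normal(100, 30, 200)
        y = x + rng.normal(0, 15, 200)
        small = lin_ccc(x[:20], y[:20])
        large = lin_ccc(x, y)
        for res in (small, large):
            assert res["ci_low"] <= res["ccc"] <= res["ci_high"]
        assert (large["ci_high"] - large["ci_low"]) < (small["ci_high"] - small["ci_low"])

    def test_ci_coverage_monte_carlo(self, rng):
        """~95% of Fisher-z CIs should cover the population CCC."""
        n, reps = 50, 300
        # population: y = x + noise; population ccc derivable in closed form
        sx2, se2, bias = 1.0, 0.25, 0.5
        pop_ccc = 2 * sx2 / (sx2 + sx2 + se2 + bias**2)
        hits = 0
        for _ in range(reps):
            x = rng.normal(0, 1, n)
            y = x + bias + rng.normal(0, math.sqrt(se2), n)
            res = lin_ccc(x, y)
            hits += res["ci_low"] <= pop_ccc <= res["ci_high"]
        assert 0.88 <= hits / reps <= 0.99

    def test_constant_series(self):
        assert lin_ccc([5.0] * 4, [5.0] * 4)["ccc"] == 1.0
        with pytest.warns(UserWarning):
            res = lin_ccc([5.0] * 4, [7.0] * 4)
        assert res["ccc"] == 0.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            lin_ccc([1.0, 2.0], [1.0, 2.0])


class TestKendallW:
    def test_identical_rankings_give_one(self):
        ratings = np.column_stack([[10, 20, 30, 40]] * 3)
        assert kendall_w(ratings)["w"] == pytest.approx(1.0)

    def test_spearman_identity_without_ties(self, rng):
        """For tie-free data, W = ((m-1)*mean_spearman + 1) / m."""
        for _ in range(5):
            ratings = rng.normal(size=(8, 3))
            res = kendall_w(ratings)
            rhos = [
                stats.spearmanr(ratings[:, a], ratings[:, b])[0]
                for a, b in itertools.combinations(range(3), 2)
            ]
            m = 3
            expected = ((m - 1) * np.mean(rhos) + 1) / m
            assert res["w"] == pytest.approx(expected)

    def test_tie_correction_against_definition(self):
        # one rater ties all cases: mid-ranks + correction, hand-checked
        ratings = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        res = kendall_w(ratings)
        # ranks: rater1 = 1,2,3; rater2 = 2,2,2; R = 3,4,5; S = 2
        # T = (3^3-3) = 24 for rater2; denom = 4*(27-3) - 2*24 = 48
        assert res["w"] == pytest.approx(12 * 2 / 48)

    def test_chi2_p_value(self):
        ratings = np.column_stack([[1, 2, 3, 4, 5]] * 3)
        res = kendall_w(ratings)
        assert res["chi2"] == pytest.approx(3 * 4 * 1.0)
        assert res["p"] == pytest.approx(float(stats.chi2.sf(12, 4)))

    def test_in_unit_interval_and_permutation_invariant(self, rng):
        ratings = rng.normal(size=(10, 4))
        res = kendall_w(ratings)
        assert 0 <= res["w"] <= 1
        perm = rng.permutation(10)
        assert kendall_w(ratings[perm])["w"] == pytest.approx(res["w"])

    def test_degenerate_all_tied(self):
        with pytest.warns(UserWarning):
            res = kendall_w(np.ones((4, 3)))
        assert res["w"] == 1.0


class TestCV:
    def test_constant_replicates(self):
        assert coefficient_of_variation([5.0] * 5) == 0.0

    def test_hand_computed(self):
        # sample SD of [90,100,110] is 10, mean 100 -> 10%
        assert coefficient_of_variation([90.0, 100.0, 110.0]) == pytest.approx(10.0)

    def test_scale_invariance(self, rng):
        reps = rng.uniform(100, 200, size=5)
        assert coefficient_of_variation(3 * reps) == pytest.approx(
            coefficient_of_variation(reps)
        )

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([5.0])
        assert math.isnan(coefficient_of_variation([0.0, 0.0]))


class TestBlandAltman:
    def test_identical_series(self, rng):
        x = rng.normal(1000, 200, 20)
        res = bland_altman(x, x)
        assert res["bias"] == 0.0 and res["sd_diff"] == 0.0 and res["rc"] == 0.0

    def test_rc_is_1p96_times_sd(self, rng):
        x = rng.normal(1000, 300, 40)
        y = x + rng.normal(50, 400, 40)
        res = bland_altman(x, y)
        assert res["rc"] == pytest.approx(1.96 * res["sd_diff"])
        assert res["loa_low"] == pytest.approx(res["bias"] - res["rc"])
        assert res["loa_high"] == pytest.approx(res["bias"] + res["rc"])

    def test_sd_422_gives_rc_827(self):
        """A difference SD of 422 mm^3 yields a repeatability coefficient
        of 827.1 mm^3 (1.96 x 422)."""
        d = np.array([-1.0, 0.0, 1.0]) * 422.0  # sample SD exactly 422
        y = np.zeros(3)
        res = bland_altman(d, y)
        assert res["sd_diff"] == pytest.approx(422.0)
        assert res["rc"] == pytest.approx(827.12)
        assert res["rc"] == pytest.approx(827.11, abs=0.05)

    def test_loa_covers_95_percent_of_normal_differences(self, rng):
        d = rng.normal(0, 37.0, 10_000)
        res = bland_altman(d, np.zeros_like(d))
        inside = np.mean((d >= res["loa_low"]) & (d <= res["loa_high"]))
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestPairedT:
    def test_matches_scipy(self, rng):
        x = rng.normal(100, 20, 15)
        y = x + rng.normal(5, 10, 15)
        res = paired_t_test(x, y)
        t_ref, p_ref = stats.ttest_rel(x, y)
        assert res["t"] == pytest.approx(float(t_ref))
        assert res["p"] == pytest.approx(float(p_ref))

    def test_hand_computed_small_vectors(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([0.0, 0.0, 0.0, 0.0])
        # d mean 2.5, sample sd sqrt(5/3), t = 2.5/(sd/2)
        sd = math.sqrt(5.0 / 3.0)
        res = paired_t_test(x, y)
        assert res["t"] == pytest.approx(2.5 / (sd / 2.0))

    def test_swap_flips_sign_same_p(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.5, 1, 12)
        a, b = paired_t_test(x, y), paired_t_test(y, x)
        assert a["t"] == pytest.approx(-b["t"])
        assert a["p"] == pytest.approx(b["p"])

    def test_zero_variance_differences_rejected(self):
        x = np.arange(5.0)
        with pytest.raises(ValueError):
            paired_t_test(x, x + 3.0)


class TestMannWhitney:
    def test_identical_singletons_midrank_u(self):
        res = mann_whitney_u([5.0], [5.0])
        assert res["u"] == 0.5

    def test_exact_p_matches_scipy_enumeration(self, rng):
        """The exact path must agree with scipy's exact distribution for
        every tie-free small-sample input tried."""
        for _ in range(10):
            a = rng.normal(0, 1, int(rng.integers(2, 8)))
            b = rng.normal(0.5, 1, int(rng.integers(2, 8)))
            res = mann_whitney_u(a, b)
            assert res["method"] == "exact"
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert res["p"] == pytest.approx(ref.pvalue)

    def test_exact_enumeration_count_for_4v4(self, rng):
        a = rng.normal(0, 1, 4)
        b = rng.normal(1, 1, 4)
        res = mann_whitney_u(a, b)
        # 70 arrangements of ranks; p must be a multiple of 1/70
        assert (res["p"] * 70) == pytest.approx(round(res["p"] * 70))

    def test_asymptotic_with_ties_matches_scipy(self, rng):
        a = rng.integers(0, 5, 30).astype(float)
        b = rng.integers(1, 6, 25).astype(float)
        res = mann_whitney_u(a, b)
        assert res["method"] == "asymptotic"
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res["p"] == pytest.approx(ref.pvalue, rel=1e-6)

    def test_extreme_separation_minimal_p(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [100.0, 101.0, 102.0, 103.0, 104.0]
        res = mann_whitney_u(a, b)
        # most extreme arrangement: p = 2 / C(10,5)
        assert res["p"] == pytest.approx(2.0 / 252.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


def _perfect_table(n_cases=6, n_obs=3, n_reps=4, rng=None):
    rows = []
    base = (rng or np.random.default_rng(0)).uniform(100, 5000, n_cases)
    for c in range(n_cases):
        for o in range(n_obs):
            for r in range(n_reps):
                rows.append(
                    {
                        "case_id": c + 1,
                        "observer_id": f"obs{o+1}",
                        "replicate": r + 1,
                        "volume_mm3": base[c],
                        "is_complex": c % 2 == 0,
                        "is_homogeneous": True,
                        "is_multiple": False,
                    }
                )
    return MeasurementTable(pd.DataFrame(rows))


class TestAgreementReport:
    def test_perfectly_repeating_observers(self, rng):
        report = agreement_report(_perfect_table(rng=rng))
        for entry in report.pairwise.values():
            assert entry["lin_ccc"]["ccc"] == pytest.approx(1.0)
        assert report.overall_kendall["w"] == pytest.approx(1.0)
        for obs in report.per_observer.values():
            assert obs["cv_percent_mean"] == pytest.approx(0.0)

    def test_injected_extra_variance_raises_subgroup_cv(self, rng):
        table = _perfect_table(n_cases=10, rng=rng).df.copy()
        noisy = table["is_complex"].to_numpy()
        jitter = rng.normal(1.0, 0.15, len(table))
        table.loc[noisy, "volume_mm3"] *= jitter[noisy]
        report = agreement_report(MeasurementTable(table))
        sub = report.subgroup["is_complex"]
        assert sub["complex"]["median_cv"] > sub["non_complex"]["median_cv"]
        assert sub["mann_whitney"]["p"] < 0.05

    def test_missing_metadata_skips_subgroups_with_warning(self, rng):
        df = _perfect_table(rng=rng).df.drop(columns=["is_complex", "is_homogeneous", "is_multiple"])
        report = agreement_report(MeasurementTable(df))
        assert report.subgroup == {} or "is_complex" not in report.subgroup
        assert any("metadata" in w for w in report.warnings)
        assert report.overall_kendall["w"] == pytest.approx(1.0)  # rest still runs

    def test_duplicate_keys_rejected(self):
        df = pd.DataFrame(
            {
                "case_id": [1, 1],
                "observer_id": ["a", "a"],
                "replicate": [1, 1],
                "volume_mm3": [1.0, 2.0],
            }
        )
        with pytest.raises(ValueError):
            MeasurementTable(df)

    def test_single_observer_rejected(self):
        df = pd.DataFrame(
            {
                "case_id": [1, 2, 3],
                "observer_id": ["a"] * 3,
                "replicate": [1, 1, 1],
                "volume_mm3": [1.0, 2.0, 3.0],
            }
        )
        with pytest.raises(ValueError):
            agreement_report(MeasurementTable(df))
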