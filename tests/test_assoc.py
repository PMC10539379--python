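"""Association battery: t-test, logistic OR, R2 conversions, trend, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from trdprs.assoc import (
    CollinearityError,
    SeparationError,
    bh_fdr,
    fit_logistic,
    liability_r2,
    mean_difference_test,
    nagelkerke_r2,
    quartile_trend,
    run_battery,
)


class TestMeanDifference:
    def test_identical_groups(self):
        x = np.array([0.1, 0.5, -0.2, 0.3])
        res = mean_difference_test(x, x)
        assert res.estimate == 0.0
        assert res.p == pytest.approx(1.0)

    def test_frozen_welch_oracle(self):
        # closed-form Welch on these values: t = 12.2474487139, df = 4,
        # p = 2.552167494e-04 (computed independently from the formula)
        res = mean_difference_test([1.0, 1.1, 0.9], [0.0, -0.1, 0.1])
        assert res.estimate == pytest.approx(1.0)
        assert res.t == pytest.approx(12.2474487139, abs=1e-8)
        assert res.df == pytest.approx(4.0, abs=1e-9)
        assert res.p == pytest.approx(2.552167494419e-04, rel=1e-9)
        assert res.ci_low < res.estimate < res.ci_high

    def test_student_variant(self):
        res = mean_difference_test([1.0, 1.1, 0.9], [0.0, -0.1, 0.1], kind="student")
        assert res.df == 4

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            mean_difference_test([1.0, 1.0], [1.0, 1.0])

    def test_tiny_group_raises(self):
        with pytest.raises(ValueError):
            mean_difference_test([1.0], [0.0, 0.1])


class TestLogistic:
    def test_two_by_two_equals_cross_product_ratio(self):
        # exposed cases 30, exposed controls 10, unexposed cases 10,
        # unexposed controls 30: OR = (30*30)/(10*10) = 9
        y = np.r_[np.ones(40), np.zeros(40)]
        x = np.r_[np.ones(30), np.zeros(10), np.ones(10), np.zeros(30)]
        res = fit_logistic(y, x)
        assert res.odds_ratio == pytest.approx(9.0, abs=1e-8)

    def test_null_model_or_near_one(self, rng):
        n = 10_000
        z = rng.standard_normal(n)
        y = rng.integers(0, 2, size=n).astype(float)
        res = fit_logistic(y, z)
        assert res.odds_ratio == pytest.approx(1.0, abs=0.07)
        assert res.ci_low < res.odds_ratio < res.ci_high

    def test_independent_covariates_leave_or_unchanged_on_average(self, rng):
        deltas = []
        for _ in range(50):
            n = 600
            z = rng.standard_normal(n)
            y = (rng.random(n) < expit(0.3 * z)).astype(float)
            pcs = pd.DataFrame(rng.standard_normal((n, 4)),
                               columns=["PC1", "PC2", "PC3", "PC4"])
            plain = fit_logistic(y, z)
            adjusted = fit_logistic(y, z, covariates=pcs)
            deltas.append(adjusted.beta - plain.beta)
        assert abs(np.mean(deltas)) < 0.01

    def test_perfect_separation_raises_with_direction(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        x = np.r_[np.ones(20) + np.arange(20) * 0.01, -np.arange(20) * 0.01 - 1]
        with pytest.raises(SeparationError, match="above"):
            fit_logistic(y, x)

    def test_collinear_covariates_named(self, rng):
        n = 100
        z = rng.standard_normal(n)
        y = rng.integers(0, 2, size=n).astype(float)
        cov = pd.DataFrame({"PC1": rng.standard_normal(n)})
        cov["PC2"] = 2 * cov["PC1"]
        with pytest.raises(CollinearityError, match="PC2"):
            fit_logistic(y, z, covariates=cov)

    def test_non_binary_status_raises(self):
        with pytest.raises(ValueError, match="binary"):
            fit_logistic([0, 1, 2], [0.0, 1.0, 2.0])

    def test_profile_ci_close_to_wald_at_large_n(self, rng):
        n = 4000
        z = rng.standard_normal(n)
        y = (rng.random(n) < expit(0.2 * z)).astype(float)
        wald = fit_logistic(y, z, ci_method="wald")
        prof = fit_logistic(y, z, ci_method="profile")
        assert prof.ci_low == pytest.approx(wald.ci_low, rel=0.02)
        assert prof.ci_high == pytest.approx(wald.ci_high, rel=0.02)


class TestVarianceExplained:
    def test_null_improvement_is_zero(self):
        assert nagelkerke_r2(-100.0, -100.0, 500) == 0.0

    def test_frozen_formula_value(self):
        # direct two-line evaluation: CS = 1 - exp(2(llb - llf)/n),
        # max = 1 - exp(2 llb / n); ratio = 0.226627320048
        assert nagelkerke_r2(-600.0, -693.147, 1000) == pytest.approx(
            0.226627320048, abs=1e-9
        )

    def test_perfect_prediction_limit(self):
        assert nagelkerke_r2(-1e-9, -693.147, 1000) == pytest.approx(1.0, abs=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            nagelkerke_r2(-10.0, -5.0, 100)
        with pytest.raises(ValueError):
            nagelkerke_r2(-5.0, -10.0, 0)

    def test_liability_zero_at_zero(self):
        assert liability_r2(0.0, K=0.1, P=0.5) == 0.0

    def test_liability_multiplier_at_half(self):
        # K = P = 0.5: multiplier K(1-K)/phi(0)^2 = 0.25/phi(0)^2
        # phi(0) = 1/sqrt(2 pi) -> multiplier = pi/2
        assert liability_r2(1.0, K=0.5, P=0.5) == pytest.approx(np.pi / 2, abs=1e-10)

    def test_liability_linear_in_r2(self):
        vals = [liability_r2(r, K=0.1, P=0.4) for r in (0.0, 0.25, 0.5, 1.0)]
        assert vals[1] == pytest.approx(vals[3] / 4)
        assert vals[2] == pytest.approx(vals[3] / 2)
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_liability_continuous_in_k(self):
        ks = np.linspace(0.02, 0.98, 97)
        vals = np.array([liability_r2(0.05, K=k, P=0.3) for k in ks])
        assert np.all(np.abs(np.diff(vals)) < 0.05)

    def test_liability_invalid_k(self):
        with pytest.raises(ValueError):
            liability_r2(0.1, K=0.0)


class TestQuartileTrend:
    def test_flat_proportions_null(self, rng):
        scores = rng.standard_normal(4000)
        status = rng.integers(0, 2, size=4000)
        res = quartile_trend(scores, status)
        assert res.p > 0.01

    def test_frozen_cochran_armitage_oracle(self):
        # (cases, controls) per quartile: (10,20),(15,15),(20,10),(25,5)
        # textbook statistic = 17.1428571429, p = 3.4671e-05
        scores = np.concatenate([np.full(30, q) for q in (1.0, 2.0, 3.0, 4.0)])
        status = np.concatenate(
            [np.r_[np.ones(c), np.zeros(30 - c)] for c in (10, 15, 20, 25)]
        )
        res = quartile_trend(scores, status)
        assert res.statistic == pytest.approx(17.1428571429, abs=1e-8)
        assert res.p == pytest.approx(3.4671076873e-05, rel=1e-8)
        assert res.case_proportion == pytest.approx((1 / 3, 1 / 2, 2 / 3, 5 / 6))

    def test_increasing_risk_detected(self, rng):
        n = 3000
        z = rng.standard_normal(n)
        y = (rng.random(n) < expit(-1 + 0.3 * z)).astype(float)
        assert quartile_trend(z, y).p < 0.05

    def test_small_n_raises(self):
        with pytest.raises(ValueError):
            quartile_trend([1, 2, 3], [0, 1, 0])


def stepup_oracle(p):
    """Independent BH step-up: adjusted(i) = min_{j >= rank_i} m p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.minimum.accumulate((m / np.arange(m, 0, -1)) * p[order][::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


class TestBhFdr:
    def test_six_test_battery_values(self):
        p = [0.631, 0.794, 0.742, 0.003, 0.004, 0.009]
        adj = bh_fdr(p)
        assert np.round(adj, 3).tolist() == [0.794, 0.794, 0.794, 0.012, 0.012, 0.018]

    def test_ties_all_equal(self):
        assert bh_fdr([0.04] * 5) == pytest.approx([0.04] * 5)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_matches_stepup_oracle_and_order_invariance(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(1, 30))
            adj = bh_fdr(p)
            assert adj == pytest.approx(stepup_oracle(p), abs=1e-12)
            perm = rng.permutation(len(p))
            assert bh_fdr(p[perm]) == pytest.approx(adj[perm], abs=1e-12)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.random(10)
        assert np.all(bh_fdr(p) >= p - 1e-15)

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


def null_dataset(rng, n_cases=150, n_controls=150, effect_lithium=0.0):
    n = n_cases + n_controls
    z_li = rng.standard_normal(n)
    z_ad = rng.standard_normal(n)
    if effect_lithium:
        eta = effect_lithium * z_li
        status = (rng.random(n) < expit(eta)).astype(int)
    else:
        status = np.r_[np.ones(n_cases), np.zeros(n_controls)].astype(int)
    return pd.DataFrame(
        {"status": status, "score_lithium": z_li, "score_antidep": z_ad,
         "lithium_user": rng.random(n) < 0.2}
    )


class TestRunBattery:
    def test_lithium_signal_antidep_null(self, rng):
        datasets = {
            d: null_dataset(rng, 1500, 1500, effect_lithium=np.log(1.5))
            for d in ("broad", "narrow_1", "narrow_2")
        }
        res = run_battery(datasets, lithium_sensitivity=True)
        primary = res[(res["covariate_set"] == "base") & (~res["lithium_excluded"])]
        li = primary[primary["trait"] == "lithium"]
        ad = primary[primary["trait"] == "antidep"]
        assert (li["p_logistic_fdr"] < 0.05).all()
        assert (ad["p_logistic_fdr"] > 0.05).all()
        assert len(primary) == 6
        # lithium-exclusion sensitivity rows exist and keep the signal
        sens = res[res["lithium_excluded"]]
        assert len(sens) == 6
        assert (sens[sens["trait"] == "lithium"]["odds_ratio"] > 1.2).all()

    def test_covariate_sets_present_when_scores_available(self, rng):
        datasets = {}
        for d in ("broad", "narrow_1", "narrow_2"):
            df = null_dataset(rng, 200, 200)
            df["score_mdd"] = rng.standard_normal(len(df))
            df["score_bip"] = rng.standard_normal(len(df))
            datasets[d] = df
        res = run_battery(datasets)
        assert set(res["covariate_set"]) == {"base", "mdd_adj", "bip_adj", "bip_mdd_adj"}
        # independent covariate scores barely move the estimate
        base = res[(res["covariate_set"] == "base") & (~res["lithium_excluded"])]
        adj = res[res["covariate_set"] == "bip_mdd_adj"]
        merged = base.merge(adj, on=["definition", "trait"], suffixes=("_b", "_a"))
        assert np.allclose(
            np.log(merged["odds_ratio_b"]), np.log(merged["odds_ratio_a"]), atol=0.1
        )

    def test_fdr_applied_to_exactly_six_primary_tests(self, rng):
        datasets = {d: null_dataset(rng) for d in ("broad", "narrow_1", "narrow_2")}
        res = run_battery(datasets)
        assert res["p_ttest_fdr"].notna().sum() == 6
        assert res["p_logistic_fdr"].notna().sum() == 6

    def test_missing_scores_raise_with_context(self, rng):
        datasets = {d: null_dataset(rng) for d in ("broad", "narrow_1", "narrow_2")}
        datasets["narrow_1"].loc[0, "score_lithium"] = np.nan
        with pytest.raises(ValueError, match="narrow_1"):
            run_battery(datasets)
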