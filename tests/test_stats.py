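import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats as sps
from scipy.special import expit

from transprs.stats import (anova_from_summaries, code_groups, fit_linear,
                            fit_logistic, group_trend, interaction_test,
                            km_logrank, late_initiation_rates, nagelkerke_r2,
                            pearson_chi2, scan_thresholds)
from transprs.prs import PrsProfile


class TestFitLinear:
    def test_perfect_fit(self):
        x = np.arange(10, dtype=float)
        res = fit_linear(3.0 + 2.0 * x, pd.DataFrame({"prs": x}))
        assert res.variance_explained == pytest.approx(1.0)
        assert res.coefficient == pytest.approx(2.0)
        assert res.p_value < 1e-12

    def test_eight_point_normal_equations_oracle(self):
        """Coefficients must equal the closed-form (X'X)^-1 X'y solution."""
        rng = np.random.default_rng(12)
        x1 = np.array([1, 2, 3, 4, 5, 6, 7, 8], dtype=float)
        x2 = np.array([2, 1, 4, 3, 6, 5, 8, 7], dtype=float)
        y = np.array([1.2, 2.1, 2.9, 4.2, 4.8, 6.1, 6.9, 8.3])
        res = fit_linear(y, pd.DataFrame({"prs": x1, "cov": x2}))
        X = np.column_stack([np.ones(8), x1, x2])
        beta_hat = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.coefficient == pytest.approx(beta_hat[1], rel=1e-10)
        # adjusted R2 from the same closed form
        resid = y - X @ beta_hat
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert res.variance_explained == pytest.approx(
            1 - (1 - r2) * 7 / (8 - 2 - 1), rel=1e-10)

    def test_type_one_error_calibrated(self):
        """PRS coefficient p < 0.05 in about 5% of pure-noise replicates."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_reps = 500
        for _ in range(n_reps):
            x = rng.normal(size=40)
            y = rng.normal(size=40)
            if fit_linear(y, pd.DataFrame({"prs": x})).p_value < 0.05:
                rejections += 1
        # binomial 95% band around 0.05 at 500 replicates
        assert 13 <= rejections <= 38

    def test_collinear_columns_named(self):
        x = np.arange(10, dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            fit_linear(x, pd.DataFrame({"prs": x, "copy": 2 * x}))


class TestFitLogistic:
    def test_constant_predictor_collapses_to_null(self):
        y = np.array([0, 1] * 10)
        res = fit_logistic(y, pd.DataFrame({"prs": np.zeros(20)}))
        assert res.variance_explained == 0.0

    def test_saturated_binary_predictor_equals_table_log_or(self):
        # 2x2 table: exposed 30/10, unexposed 10/30 -> OR = 9
        x = np.array([1] * 40 + [0] * 40, dtype=float)
        y = np.array([1] * 30 + [0] * 10 + [1] * 10 + [0] * 30, dtype=float)
        res = fit_logistic(y, pd.DataFrame({"prs": x}))
        assert res.coefficient == pytest.approx(np.log(9.0), rel=1e-6)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="class"):
            fit_logistic(np.ones(10), pd.DataFrame({"prs": np.arange(10.0)}))

    def test_twelve_observation_likelihood_surface_oracle(self):
        """Log-likelihood and Nagelkerke R² must match a direct numerical
        maximization of the Bernoulli likelihood."""
        x = np.array([0.2, -1.3, 0.8, 1.7, -0.4, 0.0,
                      2.1, -2.2, 0.9, -0.6, 1.1, 0.4])
        y = np.array([0, 0, 1, 1, 0, 1, 1, 0, 1, 0, 1, 0], dtype=float)

        def negll(params, design):
            eta = design @ params
            return -np.sum(y * eta - np.log1p(np.exp(eta)))

        X = np.column_stack([np.ones(12), x])
        full = optimize.minimize(negll, np.zeros(2), args=(X,),
                                 method="Nelder-Mead",
                                 options={"xatol": 1e-10, "fatol": 1e-12,
                                          "maxiter": 5000})
        null = optimize.minimize(negll, np.zeros(1),
                                 args=(np.ones((12, 1)),),
                                 method="Nelder-Mead",
                                 options={"xatol": 1e-10, "fatol": 1e-12})
        res = fit_logistic(y, pd.DataFrame({"prs": x}))
        assert res.extra["llf"] == pytest.approx(-full.fun, abs=1e-6)
        assert res.extra["llnull"] == pytest.approx(-null.fun, abs=1e-6)
        expected_r2 = nagelkerke_r2(-full.fun, -null.fun, 12)
        assert res.variance_explained == pytest.approx(expected_r2, abs=1e-6)

    def test_nagelkerke_invariant_to_predictor_rescaling(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=80)
        y = (rng.random(80) < expit(x)).astype(float)
        r1 = fit_logistic(y, pd.DataFrame({"prs": x})).variance_explained
        r2 = fit_logistic(y, pd.DataFrame({"prs": 1e3 * x + 5})).variance_explained
        assert r1 == pytest.approx(r2, rel=1e-6)


def make_profile(scores, cutoffs=(0.5,)):
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    return PrsProfile([f"s{i}" for i in range(scores.shape[0])],
                      tuple(cutoffs), scores,
                      np.arange(1, scores.shape[1] + 1))


class TestScan:
    def test_single_cutoff_scan_equals_single_fit(self):
        rng = np.random.default_rng(31)
        x = rng.normal(size=60)
        y = x + rng.normal(size=60)
        profile = make_profile(x)
        results, best = scan_thresholds(profile, y, model="linear")
        direct = fit_linear(y, pd.DataFrame({"prs": x}))
        assert len(results) == 1
        assert best.variance_explained == pytest.approx(
            direct.variance_explained)
        assert best.p_value == pytest.approx(direct.p_value)

    def test_misaligned_outcome_rejected(self):
        profile = make_profile(np.zeros(5))
        with pytest.raises(ValueError, match="aligned"):
            scan_thresholds(profile, np.zeros(4))

    def test_best_is_max_variance_explained(self):
        rng = np.random.default_rng(32)
        x = rng.normal(size=100)
        y = x + rng.normal(size=100)
        scores = np.column_stack([rng.normal(size=100), x,
                                  x + rng.normal(size=100)])
        profile = make_profile(scores, cutoffs=(0.01, 0.5, 1.0))
        results, best = scan_thresholds(profile, y, model="linear")
        assert best.threshold == 0.5
        assert best.variance_explained == max(r.variance_explained
                                              for r in results)


class TestGroupTrend:
    def test_identical_scores_give_zero_trend(self):
        res, summary = group_trend(np.ones(30),
                                   ["HC"] * 10 + ["FR"] * 10 + ["SCZ"] * 10)
        assert res.coefficient == 0.0
        assert set(summary["group"]) == {"HC", "FR", "SCZ"}

    def test_two_group_subset_equals_logistic_fit(self):
        rng = np.random.default_rng(41)
        prs = np.r_[rng.normal(0.5, 1, 40), rng.normal(0, 1, 40)]
        groups = ["SCZ"] * 40 + ["HC"] * 40
        y = (np.array(groups) == "SCZ").astype(float)
        direct = fit_logistic(y, pd.DataFrame({"prs": prs}))
        assert direct.variance_explained > 0
        # consistency: the trend on the 2-group subset ranks the same way
        res, _ = group_trend(prs, groups)
        assert np.sign(res.coefficient) == np.sign(direct.coefficient)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown group"):
            group_trend(np.arange(4.0), ["HC", "FR", "SCZ", "XX"])


class TestInteraction:
    def test_null_interaction_type_one_error(self):
        rng = np.random.default_rng(51)
        rejections = 0
        n_reps = 200
        for _ in range(n_reps):
            n = 200
            prs = rng.normal(size=n)
            status = (rng.random(n) < 0.4).astype(float)
            # equal PRS effect in both strata -> no interaction
            y = (rng.random(n) < expit(0.5 * prs)).astype(float)
            if interaction_test(prs, status, y) < 0.05:
                rejections += 1
        assert 3 <= rejections <= 18  # binomial 95% band at alpha 0.05

    def test_equal_stratum_effects_large_n(self):
        rng = np.random.default_rng(52)
        n = 20_000
        prs = rng.normal(size=n)
        status = (rng.random(n) < 0.5).astype(float)
        y = (rng.random(n) < expit(0.8 * prs)).astype(float)
        assert interaction_test(prs, status, y) > 0.05

    def test_constant_prs_is_rank_deficient(self):
        status = np.array([0.0, 1.0] * 20)
        y = np.array([0.0, 0.0, 1.0, 1.0] * 10)
        with pytest.raises(ValueError, match="collinear"):
            interaction_test(np.ones(40), status, y)


class TestChi2:
    def test_proportional_rows_give_zero(self):
        stat, df, p = pearson_chi2([[10, 20], [30, 60]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert (df, p) == (1, pytest.approx(1.0))

    def test_textbook_formula_oracle_on_random_tables(self):
        rng = np.random.default_rng(61)
        for _ in range(20):
            t = rng.integers(1, 40, size=(3, 2)).astype(float)
            stat, df, p = pearson_chi2(t)
            # independent textbook computation
            e = np.outer(t.sum(1), t.sum(0)) / t.sum()
            expected = ((t - e) ** 2 / e).sum()
            assert stat == pytest.approx(expected, rel=1e-12)
            assert p == pytest.approx(sps.chi2.sf(expected, 2), rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            pearson_chi2([[0, 0], [1, 2]])


class TestAnovaFromSummaries:
    def test_textbook_oracle_on_random_summaries(self):
        rng = np.random.default_rng(71)
        for _ in range(20):
            data = [rng.normal(rng.uniform(-1, 1), 1, size=rng.integers(5, 30))
                    for _ in range(3)]
            triples = [(len(d), d.mean(), d.std(ddof=1)) for d in data]
            f, dfb, dfw, p = anova_from_summaries(triples)
            f_ref, p_ref = sps.f_oneway(*data)
            assert f == pytest.approx(f_ref, rel=1e-10)
            assert p == pytest.approx(p_ref, rel=1e-8)

    def test_equal_means_give_zero(self):
        f, *_ = anova_from_summaries([(10, 5.0, 1.0), (12, 5.0, 2.0)])
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            anova_from_summaries([(10, 5.0, -1.0), (12, 5.0, 2.0)])


def logrank_hand_oracle(time, event, group):
    """Step-by-step two-group log-rank computation over the risk-set table."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    group = np.asarray(group)
    labels = np.unique(group)
    assert len(labels) == 2
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(time[event])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == labels[0])).sum()
        d = (event & (time == t)).sum()
        d1 = (event & (time == t) & (group == labels[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


class TestSurvival:
    def test_identical_groups_give_zero_statistic(self):
        time = np.array([2, 3, 5, 7.0] * 2)
        event = np.array([True, True, False, True] * 2)
        group = ["a"] * 4 + ["b"] * 4
        res = km_logrank(time, event, group)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 1

    def test_km_equals_one_minus_ecdf_without_censoring(self):
        rng = np.random.default_rng(81)
        t1 = rng.integers(1, 20, size=30).astype(float)
        t2 = rng.integers(1, 20, size=25).astype(float)
        res = km_logrank(np.r_[t1, t2], np.ones(55, bool),
                         ["a"] * 30 + ["b"] * 25)
        curve = res.curves["a"]
        for _, row in curve.iterrows():
            if row["time"] > 0:
                assert row["survival"] == pytest.approx(
                    (t1 > row["time"]).mean(), abs=1e-12)

    def test_eight_subject_hand_table(self):
        """Mixed events and censoring, verified against an independent
        risk-set-by-risk-set computation."""
        time = np.array([1, 2, 3, 4, 4, 5, 6, 8], dtype=float)
        event = np.array([1, 1, 0, 1, 1, 0, 1, 0], dtype=bool)
        group = np.array(["a", "b", "a", "b", "a", "b", "a", "b"])
        res = km_logrank(time, event, group)
        assert res.statistic == pytest.approx(
            logrank_hand_oracle(time, event, group), rel=1e-9)

    def test_all_censored_flags_test_error(self):
        res = km_logrank([3.0, 4.0, 5.0, 6.0], [False] * 4,
                         ["a", "a", "b", "b"])
        assert res.statistic is None
        assert "censored" in res.test_error
        assert set(res.curves) == {"a", "b"}

    def test_km_curves_non_increasing_from_one(self):
        rng = np.random.default_rng(82)
        time = rng.uniform(1, 30, size=50)
        event = rng.random(50) < 0.7
        res = km_logrank(time, event, ["a"] * 25 + ["b"] * 25)
        for c in res.curves.values():
            s = c["survival"].to_numpy()
            assert s[0] <= 1.0 + 1e-12
            assert np.all(np.diff(s) <= 1e-12)


class TestLateInitiation:
    def make_pheno(self):
        from transprs.datasets import build_demo_phenotypes
        return build_demo_phenotypes()

    def test_demo_rates_match_published_fractions(self):
        rates, p, note = late_initiation_rates(self.make_pheno())
        by = rates.set_index("group")
        assert by.loc["HC", "n_late"] == 5 and by.loc["HC", "n_ever"] == 36
        assert by.loc["HC", "proportion"] == pytest.approx(5 / 36)
        assert by.loc["FR", "proportion"] == pytest.approx(5 / 12)
        assert by.loc["SCZ", "proportion"] == pytest.approx(12 / 33)
        assert p is not None and 0 < p < 1

    def test_all_early_initiation_is_degenerate(self):
        pheno = self.make_pheno()
        pheno.loc[pheno["ever_smoker"] == 1, "age_initiation"] = 18.0
        rates, p, note = late_initiation_rates(pheno)
        assert (rates["proportion"].dropna() == 0).all()
        assert p is None and "degenerate" in note
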