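import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats.contingency import odds_ratio as scipy_odds_ratio

import crcrisk as cr
from crcrisk.evaluate import (
    DegenerateStratumError,
    FACTOR_MODEL_TERMS,
    TwoByTwo,
    likelihood_ratios,
)


def brute_force_auroc(scores, labels):
    """All-pairs concordance count with ties worth 1/2."""
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    wins = 0.0
    for c in cases:
        wins += (c > controls).sum() + 0.5 * (c == controls).sum()
    return wins / (len(cases) * len(controls))


class TestCrudeOr:
    def test_agrees_with_independent_sample_odds_ratio(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(1, 400, 4)
            got = cr.crude_or(TwoByTwo(a, b, c, d))
            ref = scipy_odds_ratio([[a, b], [c, d]], kind="sample")
            assert got["or_"] == pytest.approx(ref.statistic)

    def test_symmetric_table_is_null(self):
        res = cr.crude_or(TwoByTwo(50, 50, 50, 50))
        assert res["or_"] == pytest.approx(1.0)

    def test_zero_cell_rejected(self):
        with pytest.raises(ValueError, match="zero cell"):
            cr.crude_or(TwoByTwo(0, 10, 10, 10))


class TestPlainAuroc:
    def test_matches_brute_force_with_ties(self, rng):
        n = 400
        scores = rng.integers(0, 12, n).astype(float)  # many ties
        labels = rng.integers(0, 2, n)
        assert cr.plain_auroc(scores, labels) == pytest.approx(
            brute_force_auroc(scores, labels), abs=1e-12
        )

    def test_perfect_ranking(self):
        labels = np.array([0] * 10 + [1] * 10)
        assert cr.plain_auroc(labels.astype(float), labels) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cr.plain_auroc([1.0, 2.0], [1, 1])


class TestStratifiedAuroc:
    def test_one_stratum_reduces_to_pooled(self, rng):
        n = 300
        scores = rng.normal(size=n)
        labels = rng.integers(0, 2, n)
        ps = rng.normal(size=n)
        pooled = cr.plain_auroc(scores, labels)
        est = cr.ps_stratified_auroc(scores, labels, ps, n_strata=1)
        assert est.estimate == pytest.approx(pooled, abs=1e-12)

    def test_equal_case_counts_give_unweighted_mean(self, rng):
        # two strata, same number of cases in each
        scores = rng.normal(size=400)
        labels = np.tile([0, 0, 0, 1], 100)
        ps = np.repeat([0.0, 1.0], 200)
        est = cr.ps_stratified_auroc(scores, labels, ps, n_strata=2)
        a0 = cr.plain_auroc(scores[:200], labels[:200])
        a1 = cr.plain_auroc(scores[200:], labels[200:])
        assert est.estimate == pytest.approx((a0 + a1) / 2)

    def test_null_scores_near_half(self, rng):
        n = 20_000
        labels = rng.integers(0, 2, n)
        est = cr.ps_stratified_auroc(rng.normal(size=n), labels,
                                     rng.normal(size=n))
        n1 = labels.sum()
        n0 = n - n1
        se = np.sqrt((n + 1) / (12 * n1 * n0)) * np.sqrt(5)  # per-stratum pooling
        assert abs(est.estimate - 0.5) < 3 * se

    def test_caseless_stratum_gets_zero_weight(self, rng):
        scores = rng.normal(size=200)
        labels = np.concatenate([np.zeros(100, int),
                                 rng.integers(0, 2, 100)])
        ps = np.repeat([0.0, 1.0], 100)
        est = cr.ps_stratified_auroc(scores, labels, ps, n_strata=2)
        expected = cr.plain_auroc(scores[100:], labels[100:])
        assert est.estimate == pytest.approx(expected)

    def test_stratum_without_controls_errors(self):
        labels = np.concatenate([np.zeros(50, int), np.ones(50, int)])
        ps = np.repeat([0.0, 1.0], 50)
        with pytest.raises(DegenerateStratumError):
            cr.ps_stratified_auroc(np.arange(100.0), labels, ps, n_strata=2)


def null_model_cohort(n, rng):
    """Scores and propensity unrelated to outcome."""
    return pd.DataFrame({
        "ers": rng.integers(0, 7, n).astype(float),
        "family_history": rng.integers(0, 2, n).astype(float),
        "grs": rng.normal(18, 3, n),
        "ps": rng.normal(0, 0.3, n),
        "case_status": rng.integers(0, 2, n),
    })


class TestRiskModelFit:
    def test_null_data_recovers_unit_ors(self, rng):
        fit = cr.fit_risk_model(null_model_cohort(5000, rng))
        t = fit.table.loc[["ers", "family_history", "grs"]]
        assert np.all(np.abs(t["beta"]) < 3 * t["se"])

    def test_wald_interval_brackets_estimate(self, small_cohort):
        fit = cr.fit_risk_model(small_cohort)
        t = fit.table
        assert (t["ci_low"] <= t["or_"]).all() and (t["or_"] <= t["ci_high"]).all()

    def test_score_model_matches_common_factor_effect(self, default_cohort):
        """Data generated with one shared per-factor effect: the ERS-count
        coefficient should recover it."""
        fit = cr.fit_risk_model(default_cohort)
        lo, hi = fit.table.loc["ers", ["ci_low", "ci_high"]]
        assert lo < 1.36 < hi

    def test_factor_and_score_models_agree_on_grs(self, default_cohort):
        f = cr.fit_risk_model(default_cohort, FACTOR_MODEL_TERMS)
        s = cr.fit_risk_model(default_cohort)
        assert f.table.loc["grs", "or_"] == pytest.approx(
            s.table.loc["grs", "or_"], abs=0.01
        )

    def test_separation_raises_model_fit_error(self, rng):
        cohort = null_model_cohort(200, rng)
        cohort["case_status"] = (cohort["grs"] > 18).astype(int)
        with pytest.raises(cr.evaluate.ModelFitError):
            cr.fit_risk_model(cohort)


class TestCvAuroc:
    def test_null_model_near_half(self, rng):
        cohort = null_model_cohort(4000, rng)
        est = cr.cv_auroc(cohort, n_boot=0, seed=rng)
        assert abs(est.estimate - 0.5) < 0.03

    def test_reproducible_for_fixed_seed(self, small_cohort):
        a = cr.cv_auroc(small_cohort, n_boot=0, seed=7)
        b = cr.cv_auroc(small_cohort, n_boot=0, seed=7)
        assert a.estimate == b.estimate

    def test_bootstrap_ci_brackets_point_estimate(self, small_cohort):
        est = cr.cv_auroc(small_cohort, n_boot=30, seed=5)
        assert est.ci_low is not None
        assert est.ci_low <= est.estimate <= est.ci_high

    def test_cv_estimate_shows_optimism_correction(self, small_config):
        """Across replicates, cross-validated AUROC is on average below the
        resubstitution estimate of the same model."""
        diffs = []
        cfg = dataclasses.replace(small_config, n_cases=150, n_controls=300)
        for rep in range(12):
            cohort = cr.generate_cohort(cfg, seed=3000 + rep)
            cohort = cr.attach_propensity(cohort, cr.fit_propensity(cohort))
            cv = cr.cv_auroc(cohort, n_boot=0, seed=rep).estimate
            apparent = cr.apparent_auroc(cohort).estimate
            diffs.append(apparent - cv)
        assert np.mean(diffs) > 0

    def test_too_few_cases_rejected(self, rng):
        cohort = null_model_cohort(20, rng)
        cohort["case_status"] = [1, 0, 0, 1] + [0] * 16
        with pytest.raises(ValueError, match="folds|cases"):
            cr.cv_auroc(cohort, k=5, n_boot=0)


class TestCumulativeCurve:
    def test_single_variable_cumulative_equals_individual(self, small_cohort):
        curve = cr.cumulative_auroc_curve(small_cohort, ["grs"], seed=1)
        assert len(curve) == 1
        assert curve.loc[0, "cumulative_auroc"] == pytest.approx(
            curve.loc[0, "individual_auroc"]
        )

    def test_sorted_ascending_and_ends_at_full_model(self, small_cohort):
        variables = ["ers", "family_history", "grs"]
        curve = cr.cumulative_auroc_curve(
            small_cohort, variables, seed=2, cross_validated=False
        )
        assert list(curve["individual_auroc"]) == sorted(curve["individual_auroc"])
        full = cr.apparent_auroc(small_cohort, list(curve["variable"])).estimate
        assert curve["cumulative_auroc"].iloc[-1] == pytest.approx(full)

    def test_noise_variable_adds_nothing_on_average(self, small_config, rng):
        gains = []
        cfg = dataclasses.replace(small_config, n_cases=150, n_controls=300)
        for rep in range(8):
            cohort = cr.generate_cohort(cfg, seed=4000 + rep)
            cohort = cr.attach_propensity(cohort, cr.fit_propensity(cohort))
            cohort["noise"] = rng.normal(size=len(cohort))
            base = cr.cv_auroc(cohort, ["ers", "family_history", "grs"],
                               n_boot=0, seed=rep).estimate
            plus = cr.cv_auroc(cohort, ["ers", "family_history", "grs", "noise"],
                               n_boot=0, seed=rep).estimate
            gains.append(plus - base)
        assert np.mean(gains) < 0.01


class TestScreeningPerformance:
    def test_cutoff_below_minimum(self, rng):
        rs = rng.uniform(0.5, 5.0, 200)
        labels = rng.integers(0, 2, 200)
        row = cr.screening_performance(rs, labels, [0.0]).iloc[0]
        assert row["sensitivity"] == 100.0 and row["specificity"] == 0.0
        assert row["nlr_undefined"]

    def test_monotone_in_cutoff(self, rng):
        rs = rng.lognormal(0, 0.8, 1000)
        labels = rng.integers(0, 2, 1000)
        table = cr.screening_performance(rs, labels, np.linspace(0.1, 5, 25))
        assert (table["sensitivity"].diff().dropna() <= 1e-12).all()
        assert (table["specificity"].diff().dropna() >= -1e-12).all()

    def test_likelihood_ratio_identities(self, rng):
        rs = rng.lognormal(0, 0.8, 500)
        labels = rng.integers(0, 2, 500)
        t = cr.screening_performance(rs, labels, [0.5, 1, 2])
        finite = t[~t["plr_undefined"] & ~t["nlr_undefined"]]
        assert np.allclose(
            finite["positive_lr"],
            finite["sensitivity"] / (100 - finite["specificity"]),
        )

    def test_likelihood_ratios_helper_degenerate(self):
        plr, nlr = likelihood_ratios(50.0, 100.0)
        assert np.isinf(plr) and nlr == pytest.approx(0.5)
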