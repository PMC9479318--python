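"""Tests of the logistic estimators: per-issue fits, crossed-random-
intercept pooled models, change rates and weighting semantics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from moralargs.estimation import (
    ChangeRateModel,
    IssueLogit,
    PooledOpinionModel,
    fit_change_rate,
    fit_issue_logistic,
    fit_pooled_m1,
    fit_pooled_m2,
    normalize_weights,
)
from moralargs.exceptions import (
    DegenerateInputError,
    InsufficientDataError,
    ValidationError,
)
from moralargs.glmm import CrossedLogisticGLMM
from moralargs.synthetic import SurveyDGP, gen_survey


def _two_by_two(n11, n10, n01, n00):
    """Binary y/x data realizing a 2x2 table."""
    y = np.r_[np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)]
    x = np.r_[np.ones(n11 + n10), np.zeros(n01 + n00)]
    X = np.column_stack([np.ones_like(x), x])
    return y, X


class TestClosedFormOracle:
    def test_logistic_mle_equals_log_odds_ratio(self):
        """On a collapsed 2x2 table the slope is the log odds ratio."""
        n11, n10, n01, n00 = 40, 25, 20, 55
        y, X = _two_by_two(n11, n10, n01, n00)
        fit = IssueLogit(y, X, ["const", "x"]).fit()
        lor = np.log(n11 * n00 / (n10 * n01))
        assert fit["x"].estimate == pytest.approx(lor, abs=1e-8)

    def test_odds_factor_is_exp_of_coefficient(self):
        y, X = _two_by_two(30, 20, 20, 30)
        fit = IssueLogit(y, X, ["const", "x"]).fit()
        assert fit["x"].odds_factor == pytest.approx(
            np.exp(fit["x"].estimate), rel=1e-12
        )


class TestWeights:
    def _data(self, seed=0, n=300):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-0.5 * x))).astype(float)
        X = np.column_stack([np.ones(n), x])
        return y, X

    def test_unit_weights_match_unweighted(self):
        y, X = self._data()
        a = IssueLogit(y, X, ["const", "x"]).fit()
        b = IssueLogit(y, X, ["const", "x"], weights=np.ones(len(y))).fit()
        for nm in ("const", "x"):
            assert a[nm].estimate == pytest.approx(b[nm].estimate, abs=1e-10)

    def test_weight_two_equals_duplication(self):
        y, X = self._data(1)
        w = np.ones(len(y))
        w[:50] = 2.0
        weighted = IssueLogit(y, X, ["const", "x"], weights=w).fit()
        y2 = np.r_[y, y[:50]]
        X2 = np.vstack([X, X[:50]])
        dup = IssueLogit(y2, X2, ["const", "x"]).fit()
        for nm in ("const", "x"):
            assert weighted[nm].estimate == pytest.approx(
                dup[nm].estimate, abs=1e-8
            )

    def test_zero_weight_equals_deletion(self):
        y, X = self._data(2)
        w = np.ones(len(y))
        w[:40] = 0.0
        zw = IssueLogit(y, X, ["const", "x"], weights=w).fit()
        cut = IssueLogit(y[40:], X[40:], ["const", "x"]).fit()
        for nm in ("const", "x"):
            assert zw[nm].estimate == pytest.approx(cut[nm].estimate, abs=1e-8)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValidationError):
            normalize_weights(np.array([1.0, -0.5]))

    def test_glmm_weight_duplication_equivalence(self):
        """Integer GLMM weights reproduce duplicated rows (point
        estimates)."""
        rng = np.random.default_rng(3)
        n = 400
        g = rng.integers(0, 40, n)
        x = rng.normal(size=n)
        u = rng.normal(0, 0.5, 40)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 * x + u[g])))).astype(float)
        X = np.column_stack([np.ones(n), x])
        w = np.ones(n)
        w[:100] = 2.0
        fit_w = CrossedLogisticGLMM(y, X, {"g": g}, weights=w,
                                    exog_names=["const", "x"]).fit()
        idx = np.r_[np.arange(n), np.arange(100)]
        fit_d = CrossedLogisticGLMM(y[idx], X[idx], {"g": g[idx]},
                                    exog_names=["const", "x"]).fit()
        assert fit_w.params["x"] == pytest.approx(fit_d.params["x"], abs=1e-4)
        assert fit_w.re_sd["g"] == pytest.approx(fit_d.re_sd["g"], abs=1e-3)


class TestSeparation:
    def test_constant_outcome_flagged(self):
        y = np.ones(50)
        X = np.column_stack([np.ones(50), np.arange(50.0)])
        fit = IssueLogit(y, X, ["const", "x"]).fit()
        assert fit.separated and not fit.converged

    def test_monotone_trend_separates(self):
        df = pd.DataFrame(
            {
                "item_id": "a",
                "wave_year": np.repeat([1990, 2000, 2010], 30),
                "opinion_adv": np.repeat([0, 0, 1], 30),
            }
        )
        cr = fit_change_rate(df, "a")
        assert cr.separated

    def test_single_wave_rejected(self):
        df = pd.DataFrame(
            {"item_id": "a", "wave_year": [2000] * 10,
             "opinion_adv": [0, 1] * 5}
        )
        with pytest.raises(InsufficientDataError):
            fit_change_rate(df, "a")


class TestChangeRate:
    def test_flat_prevalence_zero_slope(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "item_id": "a",
                "wave_year": np.repeat([1985, 1995, 2005, 2015], 800),
                "opinion_adv": rng.integers(0, 2, 3200),
            }
        )
        cr = fit_change_rate(df, "a")
        assert abs(cr.slope) <= 2 * cr.se

    def test_recovers_synthetic_trend(self):
        """logit(p) = -0.5 + 0.3 * decades recovered within 2 SE."""
        rng = np.random.default_rng(5)
        years = np.repeat([1984, 1994, 2004, 2014], 3000)
        dec = (years - 1984) / 10.0
        p = 1 / (1 + np.exp(-(-0.5 + 0.3 * dec)))
        df = pd.DataFrame(
            {
                "item_id": "a",
                "wave_year": years,
                "opinion_adv": (rng.random(len(years)) < p).astype(int),
            }
        )
        cr = fit_change_rate(df, "a", reference_year=1984)
        assert abs(cr.slope - 0.3) <= 2 * cr.se


class TestPooledModels:
    def test_degeneracy_oracle_matches_plain_logit(self, flat_survey):
        """With all generating RE variances at zero the GLMM collapses to
        the plain logistic MLE."""
        table, _ = flat_survey
        glmm_fit = fit_pooled_m1(table, group=None)
        mdl = PooledOpinionModel.from_dataframe(table, group=None, spec="m1")
        glm = sm.GLM(mdl.y, mdl.X, family=sm.families.Binomial()).fit()
        for nm, b in zip(mdl.names, glm.params):
            assert abs(glmm_fit[nm].estimate - b) < 0.01

    def test_m1_recovers_liberal_df_effect(self, effect_survey):
        table, truth = effect_survey
        fit = fit_pooled_m1(table, group="liberal")
        c = fit["df_std"]
        assert abs(c.estimate - truth["beta1_by_group"]["liberal"]) <= 2 * c.se
        assert fit.converged
        assert set(fit.re_sd) == {"individual", "issue_wave", "issue"}

    def test_m1_row_order_invariant(self, effect_survey):
        table, _ = effect_survey
        a = fit_pooled_m1(table, group="liberal")
        shuffled = table.sample(frac=1.0, random_state=9)
        b = fit_pooled_m1(shuffled, group="liberal")
        assert a["df_std"].estimate == pytest.approx(
            b["df_std"].estimate, abs=1e-6
        )

    def test_single_issue_drops_degenerate_levels(self):
        dgp = SurveyDGP(n_respondents=400, n_issues=1, waves=(2000,), seed=13)
        table, _ = gen_survey(dgp)
        with pytest.warns(UserWarning, match="single group"):
            fit = fit_pooled_m1(table, group=None)
        assert "issue" not in fit.re_sd and "issue_wave" not in fit.re_sd

    def test_m2_recovers_interaction(self):
        """DF x advantage interaction of 0.10 per 0.1 advantage is
        recovered within 2 SE."""
        dgp = SurveyDGP(
            n_respondents=3000,
            n_issues=12,
            beta1_by_group={"liberal": 0.12, "moderate": 0.06,
                            "conservative": 0.0},
            beta3=0.10,
            re_sd_individual=0.5,
            re_sd_issue=0.3,
            re_sd_issuewave=0.2,
            seed=14,
        )
        table, truth = gen_survey(dgp)
        fit = fit_pooled_m2(table, group="liberal")
        c = fit["df_std:adv10"]
        assert abs(c.estimate - 0.10) <= 2 * c.se

    def test_m2_constant_advantage_inestimable(self, flat_survey):
        table, _ = flat_survey
        table = table.copy()
        table["advantage"] = 0.2
        with pytest.raises(DegenerateInputError, match="inestimable"):
            fit_pooled_m2(table, group=None)

    def test_m1_coverage_when_effect_absent(self):
        """beta1_true = 0: the Wald CI covers zero at roughly nominal
        rate across seeds."""
        hits = 0
        n_rep = 25
        for seed in range(n_rep):
            dgp = SurveyDGP(n_respondents=700, n_issues=5,
                            beta1_by_group={}, re_sd_individual=0.4,
                            seed=500 + seed)
            table, _ = gen_survey(dgp)
            fit = fit_pooled_m1(table, group=None)
            lo, hi = fit["df_std"].ci95
            hits += lo <= 0 <= hi
        assert hits >= int(0.8 * n_rep)

    def test_fallback_pooled_logit_labeled(self, flat_survey):
        table, _ = flat_survey
        mdl = PooledOpinionModel.from_dataframe(table, group=None, spec="m1")
        fit = mdl.fit_pooled_logit()
        assert "cluster-robust" in fit.method
        assert "df_std" in fit.coefficients


def test_issue_logit_summary_prints_coefficients(effect_survey):
    table, _ = effect_survey
    fit = fit_issue_logistic(table, item_id=0, group="liberal")
    text = fit.summary()
    assert "df_std" in text and "per_issue" in text
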