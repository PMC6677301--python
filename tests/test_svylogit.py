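"""Survey-weighted logistic regression: pseudo-ML equivalence with the
classical MLE under a uniform design, weight semantics, linearized
variance, odds-ratio algebra, pseudo-AIC ranking and the linearity check."""

import numpy as np
import pandas as pd
import pytest

import cadencerisk as cr
from cadencerisk.svylogit import (ConvergenceError, LogitModelSpec,
                                  SurveyDesign, SurveyLogit,
                                  logit_linearity_check, model_aic_compare)


def logistic_data(rng, n=400, beta=(0.3, 0.8, -0.5)):
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
    from scipy.special import expit
    y = (rng.random(n) < expit(X @ np.asarray(beta))).astype(float)
    return X, y


def uniform_design(n):
    # one stratum, each pair of observations its own PSU (>=2 PSUs/stratum)
    return SurveyDesign(np.ones(n), np.zeros(n, dtype=int), np.arange(n) // 2)


class TestFit:
    def test_uniform_design_matches_classical_mle(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(0)
        X, y = logistic_data(rng)
        ours = SurveyLogit(y, X, uniform_design(len(y))).fit()
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.abs(ours.params - ref.params).max() < 1e-8

    def test_duplicate_record_equals_double_weight(self):
        rng = np.random.default_rng(1)
        X, y = logistic_data(rng, n=200)
        w = np.ones(200)
        w[0] = 2.0
        des_w = SurveyDesign(w, np.zeros(200, dtype=int), np.arange(200) // 2)
        dup_X = np.vstack([X, X[:1]])
        dup_y = np.concatenate([y, y[:1]])
        des_d = SurveyDesign(np.ones(201), np.zeros(201, dtype=int),
                             np.concatenate([np.arange(200) // 2, [0]]))
        a = SurveyLogit(y, X, des_w).fit().params
        b = SurveyLogit(dup_y, dup_X, des_d).fit().params
        assert np.abs(a - b).max() < 1e-8

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(2)
        X, y = logistic_data(rng, n=300)
        w = rng.lognormal(size=300)
        d1 = SurveyDesign(w, np.zeros(300, dtype=int), np.arange(300) // 3)
        d2 = SurveyDesign(17.3 * w, np.zeros(300, dtype=int), np.arange(300) // 3)
        r1, r2 = SurveyLogit(y, X, d1).fit(), SurveyLogit(y, X, d2).fit()
        assert np.abs(r1.params - r2.params).max() < 1e-10
        assert np.abs(r1.bse - r2.bse).max() < 1e-8

    def test_degenerate_outcome_errors(self):
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.raises(ValueError, match="degenerate"):
            SurveyLogit(np.ones(20), X, uniform_design(20))

    def test_perfect_separation_raises(self):
        n = 40
        x = np.arange(n, dtype=float)
        X = np.column_stack([np.ones(n), x])
        y = (x >= 20).astype(float)
        with pytest.raises(ConvergenceError):
            SurveyLogit(y, X, uniform_design(n)).fit()

    def test_recovers_generator_truth_within_3se(self):
        rng = np.random.default_rng(3)
        from scipy.special import expit
        n = 5000
        x1 = rng.normal(68, 21, n)
        x2 = rng.integers(18, 86, n).astype(float)
        beta = np.array([1.2, -0.03, 0.02])
        X = np.column_stack([np.ones(n), x1, x2])
        y = (rng.random(n) < expit(X @ beta)).astype(float)
        des = SurveyDesign(np.ones(n), np.arange(n) % 10, np.arange(n) // 10)
        res = SurveyLogit(y, X, des).fit()
        assert np.all(np.abs(res.params - beta) < 3 * res.bse)


class TestLinearizedCov:
    def test_uniform_design_near_classical_se(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(4)
        X, y = logistic_data(rng, n=2000)
        ours = SurveyLogit(y, X, uniform_design(len(y))).fit()
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.all(np.abs(ours.bse / ref.bse - 1.0) < 0.20)

    def test_two_identical_psus_wellposed(self):
        rng = np.random.default_rng(5)
        X, y = logistic_data(rng, n=100)
        X2, y2 = np.vstack([X, X]), np.concatenate([y, y])
        psu = np.concatenate([np.zeros(100, dtype=int), np.ones(100, dtype=int)])
        res = SurveyLogit(y2, X2, SurveyDesign(np.ones(200), np.zeros(200, dtype=int), psu)).fit()
        assert np.all(np.isfinite(res.bse)) and np.all(res.bse >= 0)
        ev = np.linalg.eigvalsh(res.cov_params)
        assert ev.min() > -1e-10  # PSD

    def test_single_psu_stratum_rejected(self):
        rng = np.random.default_rng(6)
        X, y = logistic_data(rng, n=50)
        des = SurveyDesign(np.ones(50), np.arange(50), np.zeros(50, dtype=int))
        with pytest.raises(ValueError, match="PSU"):
            SurveyLogit(y, X, des).fit()


class TestOddsRatio:
    def _fit(self):
        rng = np.random.default_rng(7)
        X, y = logistic_data(rng)
        return SurveyLogit(y, X, uniform_design(len(y)),
                           exog_names=["const", "peak30", "age"]).fit()

    def test_closed_form_value(self):
        res = self._fit()
        res.params[1] = 0.0235
        orr = res.odds_ratio("peak30", 20.0)
        assert orr.odds_ratio == pytest.approx(np.exp(0.47), rel=1e-12)

    def test_null_beta_gives_unit_or(self):
        res = self._fit()
        res.params[1] = 0.0
        orr = res.odds_ratio("peak30", 20.0)
        assert orr.odds_ratio == 1.0
        assert orr.ci_low < 1.0 < orr.ci_high

    def test_ci_endpoints_are_formula(self):
        from scipy.stats import norm
        res = self._fit()
        orr = res.odds_ratio("peak30", 20.0)
        b, se = res.params[1], res.bse[1]
        z = norm.ppf(0.975)
        assert orr.ci_low == pytest.approx(np.exp(20 * b - z * 20 * se), rel=1e-12)
        assert orr.ci_high == pytest.approx(np.exp(20 * b + z * 20 * se), rel=1e-12)

    def test_round_trip_recovers_beta(self):
        res = self._fit()
        orr = res.odds_ratio("peak30", 20.0)
        assert np.log(orr.odds_ratio) / 20.0 == pytest.approx(res.params[1], rel=1e-12)


def analysis_frame(rng, n=600, beta_age=0.03):
    from scipy.special import expit
    df = pd.DataFrame({
        "peak30": rng.normal(68, 20, n),
        "age": rng.integers(18, 86, n).astype(float),
        "smoking": (rng.random(n) < 0.25).astype(float),
        "weight": rng.lognormal(0, 0.3, n),
        "stratum": np.arange(n) % 8,
        "psu": (np.arange(n) // 8) % 2,
    })
    eta = 1.0 - 0.03 * df["peak30"] + beta_age * df["age"]
    df["y"] = (rng.random(n) < expit(eta)).astype(float)
    return df


def design_of(df):
    return SurveyDesign(df["weight"].to_numpy(), df["stratum"].to_numpy(),
                        df["psu"].to_numpy())


class TestAICAndLinearity:
    def test_identical_spec_identical_aic(self):
        rng = np.random.default_rng(8)
        df = analysis_frame(rng)
        spec = LogitModelSpec("y", "peak30", ("age",))
        fits = model_aic_compare(df, design_of(df), [spec, spec])
        assert fits[0][1].aic == fits[1][1].aic

    def test_age_effect_prefers_adjusted_model(self):
        rng = np.random.default_rng(9)
        wins = 0
        for _ in range(30):
            df = analysis_frame(rng, beta_age=0.05)
            fits = model_aic_compare(df, design_of(df), [
                LogitModelSpec("y", "peak30"),
                LogitModelSpec("y", "peak30", ("age",)),
            ])
            wins += fits[0][0].adjusters == ("age",)
        assert wins >= 27  # >= 90%

    def test_noise_covariate_median_aic_increase_positive(self):
        rng = np.random.default_rng(10)
        deltas = []
        for _ in range(60):
            df = analysis_frame(rng, beta_age=0.0)
            df["noise"] = rng.normal(size=len(df))
            base = cr.fit_weighted_logit(df, design_of(df), LogitModelSpec("y", "peak30"))
            noisy = cr.fit_weighted_logit(df, design_of(df),
                                          LogitModelSpec("y", "peak30", ("noise",)))
            deltas.append(noisy.aic - base.aic)
        assert np.median(deltas) > 0

    def test_differing_row_sets_rejected(self):
        rng = np.random.default_rng(11)
        df = analysis_frame(rng)
        df.loc[0, "age"] = np.nan
        with pytest.raises(ValueError, match="row"):
            model_aic_compare(df, design_of(df), [
                LogitModelSpec("y", "peak30"),
                LogitModelSpec("y", "peak30", ("age",)),
            ])

    def test_strong_quadratic_flagged(self):
        from scipy.special import expit
        rng = np.random.default_rng(12)
        flags = 0
        for _ in range(20):
            df = analysis_frame(rng)
            x = df["peak30"] - df["peak30"].mean()
            df["y"] = (rng.random(len(df)) < expit(-1.0 + 0.004 * x ** 2)).astype(float)
            rep = logit_linearity_check(df, design_of(df), LogitModelSpec("y", "peak30"))
            flags += rep.flagged
        assert flags >= 18

    def test_linear_null_flag_rate_nominal(self):
        rng = np.random.default_rng(13)
        flags = 0
        R = 100
        for _ in range(R):
            df = analysis_frame(rng)
            rep = logit_linearity_check(df, design_of(df), LogitModelSpec("y", "peak30"))
            flags += rep.flagged
        assert 0.02 <= flags / R <= 0.10

    def test_constant_outcome_errors(self):
        rng = np.random.default_rng(14)
        df = analysis_frame(rng)
        df["y"] = 1.0
        with pytest.raises(ValueError):
            logit_linearity_check(df, design_of(df), LogitModelSpec("y", "peak30"))
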