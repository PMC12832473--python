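import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from _oracles import auc_all_pairs
from hhineq.survey_core import OUTCOME, WEIGHT
from hhineq.wreg import (
    Design,
    FitResult,
    average_marginal_effects,
    build_design,
    drop_perfect_predictors,
    fit_weighted_logit,
    fit_weighted_lpm,
    hosmer_lemeshow,
    link_test,
    odds_ratio_table,
    roc_auc,
    significance_mark,
    vif,
)


def _sim_logit(n, beta, rng, weights=None):
    x = rng.standard_normal(n)
    p = expit(beta * x)
    y = (rng.random(n) < p).astype(float)
    w = np.ones(n) if weights is None else weights
    return pd.DataFrame({OUTCOME: y, "x": x, WEIGHT: w})


class TestFitWeightedLogit:
    def test_null_slope_within_2se(self):
        rng = np.random.default_rng(42)
        df = _sim_logit(2000, 0.0, rng)
        fit = fit_weighted_logit(df, f"{OUTCOME} ~ x")
        assert abs(fit.coefficients["x"]) < 2 * fit.se["x"]

    def test_slope_recovery_monte_carlo(self):
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            df = _sim_logit(5000, np.log(2), rng)
            fit = fit_weighted_logit(df, f"{OUTCOME} ~ x")
            if abs(fit.coefficients["x"] - np.log(2)) <= 2 * fit.se["x"]:
                hits += 1
        assert hits >= 93

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(3)
        df = _sim_logit(500, 0.7, rng, weights=rng.gamma(3, 1, 500))
        f1 = fit_weighted_logit(df, f"{OUTCOME} ~ x")
        df2 = df.assign(weight=df[WEIGHT] * 10)
        f2 = fit_weighted_logit(df2, f"{OUTCOME} ~ x")
        np.testing.assert_allclose(
            f1.coefficients, f2.coefficients, atol=1e-10, rtol=0
        )

    def test_equal_weights_match_statsmodels_mle(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(8)
        df = _sim_logit(800, 0.9, rng)
        fit = fit_weighted_logit(df, f"{OUTCOME} ~ x")
        X = np.column_stack([np.ones(len(df)), df["x"]])
        oracle = sm.Logit(df[OUTCOME], X).fit(disp=0)
        np.testing.assert_allclose(
            fit.coefficients.to_numpy(), oracle.params, atol=1e-8
        )

    def test_vcov_symmetric_psd(self, wave1_table):
        fit = fit_weighted_logit(
            wave1_table, f"{OUTCOME} ~ C(ses_quintile) + sex + household_size"
        )
        V = fit.vcov.to_numpy()
        np.testing.assert_allclose(V, V.T, atol=1e-14)
        assert np.all(np.linalg.eigvalsh(V) > -1e-12)

    def test_rank_deficiency_error_without_screen(self):
        rng = np.random.default_rng(5)
        df = _sim_logit(100, 0.5, rng)
        df["x2"] = df["x"]
        with pytest.raises(ValueError, match="aliased"):
            fit_weighted_logit(df, f"{OUTCOME} ~ x + x2", screen=False)


class TestDropPerfectPredictors:
    def test_all_one_level_dropped(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                OUTCOME: (rng.random(60) < 0.5).astype(float),
                "g": ["a"] * 30 + ["b"] * 30,
                WEIGHT: 1.0,
            }
        )
        df.loc[df["g"] == "b", OUTCOME] = 1.0
        design, report = drop_perfect_predictors(df, f"{OUTCOME} ~ g")
        assert ("g[b]", "perfect prediction") in report.dropped
        assert "g[b]" not in design.columns

    def test_duplicate_column_dropped_for_collinearity(self):
        rng = np.random.default_rng(1)
        df = _sim_logit(100, 0.5, rng)
        df["x2"] = df["x"]
        _, report = drop_perfect_predictors(df, f"{OUTCOME} ~ x + x2")
        assert report.dropped == [("x2", "collinearity")]

    def test_well_conditioned_empty_report(self):
        rng = np.random.default_rng(2)
        df = _sim_logit(100, 0.5, rng)
        df["z"] = rng.standard_normal(100)
        _, report = drop_perfect_predictors(df, f"{OUTCOME} ~ x + z")
        assert not report


class TestOddsRatioTable:
    def _fit_with(self, beta, se):
        cols = ["Intercept", "x"]
        design = Design(
            y=np.array([0.0, 1.0]), X=np.eye(2), w=np.ones(2), columns=cols,
            term_of_column=cols, kind_of_column=["intercept", "continuous"],
            index=pd.RangeIndex(2), formula="y ~ x",
        )
        V = np.diag([0.0, se**2])
        return FitResult(
            coefficients=pd.Series([0.0, beta], index=cols),
            vcov=pd.DataFrame(V, index=cols, columns=cols), link="logit",
            n_used=2, dropped_terms=[], converged=True,
            fitted_probabilities=np.array([0.5, 0.5]), design=design,
        )

    def test_point_or_with_zero_se(self):
        tab = odds_ratio_table(self._fit_with(np.log(2), 0.0))
        row = tab.loc["x"]
        assert row["aOR"] == pytest.approx(2.0)
        assert row["ci_low"] == pytest.approx(2.0)
        assert row["ci_high"] == pytest.approx(2.0)

    def test_null_beta_centered(self):
        row = odds_ratio_table(self._fit_with(0.0, 0.5)).loc["x"]
        assert row["aOR"] == 1.0
        assert row["ci_low"] * row["ci_high"] == pytest.approx(1.0)

    def test_significance_marks(self):
        assert significance_mark(0.005) == "a"
        assert significance_mark(0.03) == "b"
        assert significance_mark(0.07) == "c"
        assert significance_mark(0.5) == ""

    def test_identity_link_rejected(self):
        df = pd.DataFrame({OUTCOME: [0, 1, 0, 1.0], "x": [0, 1, 1, 0.0], WEIGHT: 1.0})
        lpm = fit_weighted_lpm(df, f"{OUTCOME} ~ x")
        with pytest.raises(ValueError, match="logit"):
            odds_ratio_table(lpm)

    def test_agrees_with_direct_exponentiation(self, wave1_table):
        fit = fit_weighted_logit(wave1_table, f"{OUTCOME} ~ C(ses_quintile)")
        tab = odds_ratio_table(fit)
        np.testing.assert_array_equal(
            tab["aOR"].to_numpy(), np.exp(fit.coefficients.to_numpy())
        )


class TestFitWeightedLpm:
    def test_perfect_fit(self):
        df = pd.DataFrame(
            {OUTCOME: [0, 1, 0, 1.0], "x": [0, 1, 0, 1.0], WEIGHT: 1.0}
        )
        fit = fit_weighted_lpm(df, f"{OUTCOME} ~ x")
        assert fit.coefficients["Intercept"] == pytest.approx(0.0, abs=1e-12)
        assert fit.coefficients["x"] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(
            fit.fitted_probabilities, df[OUTCOME], atol=1e-12
        )

    def test_orthogonal_predictor_zero_slope(self):
        df = pd.DataFrame(
            {
                OUTCOME: [0, 0, 1, 1.0],
                "x": [-1, 1, -1, 1.0],  # orthogonal to outcome
                WEIGHT: 1.0,
            }
        )
        fit = fit_weighted_lpm(df, f"{OUTCOME} ~ x")
        assert abs(fit.coefficients["x"]) < 1e-10

    def test_normal_equations_oracle_6_rows(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {
                OUTCOME: [0, 1, 1, 0, 1, 0.0],
                "x": rng.standard_normal(6),
                "z": rng.standard_normal(6),
                WEIGHT: rng.gamma(2, 1, 6),
            }
        )
        fit = fit_weighted_lpm(df, f"{OUTCOME} ~ x + z")
        X = np.column_stack([np.ones(6), df["x"], df["z"]])
        w = df[WEIGHT].to_numpy()
        oracle = np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (w * df[OUTCOME]))
        np.testing.assert_allclose(fit.coefficients.to_numpy(), oracle, atol=1e-10)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(9)
        df = _sim_logit(300, 0.4, rng, weights=rng.gamma(3, 1, 300))
        f1 = fit_weighted_lpm(df, f"{OUTCOME} ~ x")
        f2 = fit_weighted_lpm(df.assign(weight=df[WEIGHT] * 7), f"{OUTCOME} ~ x")
        np.testing.assert_allclose(f1.coefficients, f2.coefficients, atol=1e-10)


class TestMarginalEffects:
    def test_identity_link_equals_coefficients(self):
        rng = np.random.default_rng(4)
        df = _sim_logit(200, 0.5, rng)
        fit = fit_weighted_lpm(df, f"{OUTCOME} ~ x")
        me = average_marginal_effects(fit)
        np.testing.assert_array_equal(
            me.ame.to_numpy(), fit.coefficients.iloc[1:].to_numpy()
        )

    def test_logit_half_probability_quarter_beta(self):
        # constant x = 0 forces p = 0.5 everywhere regardless of slope
        cols = ["Intercept", "x"]
        n = 10
        design = Design(
            y=np.repeat([0.0, 1.0], 5),
            X=np.column_stack([np.ones(n), np.zeros(n)]), w=np.ones(n),
            columns=cols, term_of_column=cols,
            kind_of_column=["intercept", "continuous"],
            index=pd.RangeIndex(n), formula="y ~ x",
        )
        fit = FitResult(
            coefficients=pd.Series([0.0, 2.0], index=cols),
            vcov=pd.DataFrame(np.eye(2) * 0.01, index=cols, columns=cols),
            link="logit", n_used=n, dropped_terms=[], converged=True,
            fitted_probabilities=np.full(n, 0.5), design=design,
        )
        me = average_marginal_effects(fit)
        assert me.ame["x"] == pytest.approx(0.25 * 2.0)

    def test_continuous_ame_matches_finite_difference(self):
        df = pd.DataFrame(
            {
                OUTCOME: [0, 1, 0, 0, 1.0],
                "x": [-1.2, 0.3, 1.5, -0.4, 0.9],
                WEIGHT: [1.0, 2.0, 1.0, 1.5, 0.5],
            }
        )
        fit = fit_weighted_logit(df, f"{OUTCOME} ~ x")
        me = average_marginal_effects(fit)
        beta = fit.coefficients.to_numpy()
        w = df[WEIGHT].to_numpy()
        eps = 1e-6

        def mean_pred(shift):
            X = np.column_stack([np.ones(5), df["x"] + shift])
            return np.sum(w * expit(X @ beta)) / w.sum()

        fd = (mean_pred(eps) - mean_pred(-eps)) / (2 * eps)
        assert me.ame["x"] == pytest.approx(fd, abs=1e-6)

    def test_dummy_ame_is_discrete_difference(self, wave1_table):
        fit = fit_weighted_logit(wave1_table, f"{OUTCOME} ~ sex")
        me = average_marginal_effects(fit)
        beta = fit.coefficients.to_numpy()
        w = fit.design.w
        diff = expit(beta[0] + beta[1]) - expit(beta[0])
        assert me.ame["sex[female]"] == pytest.approx(diff, abs=1e-12)


class TestHosmerLemeshow:
    def test_perfect_calibration_zero_statistic(self):
        # 10 deciles of 10 rows; fitted p equals observed frequency per decile
        p = np.repeat(np.arange(1, 11) / 10.0, 10)
        y = np.concatenate(
            [np.r_[np.ones(k), np.zeros(10 - k)] for k in range(1, 11)]
        ).astype(float)
        cols = ["Intercept"]
        design = Design(
            y=y, X=np.ones((100, 1)), w=np.ones(100), columns=cols,
            term_of_column=cols, kind_of_column=["intercept"],
            index=pd.RangeIndex(100), formula="y ~ ",
        )
        fit = FitResult(
            coefficients=pd.Series([0.0], index=cols),
            vcov=pd.DataFrame([[0.0]], index=cols, columns=cols),
            link="logit", n_used=100, dropped_terms=[], converged=True,
            fitted_probabilities=p, design=design,
        )
        stat, pval = hosmer_lemeshow(fit)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert pval == pytest.approx(1.0)

    def test_null_rejection_rate(self):
        rejections = 0
        n_rep = 120
        for s in range(n_rep):
            rng = np.random.default_rng(2000 + s)
            df = _sim_logit(1500, 0.8, rng)
            fit = fit_weighted_logit(df, f"{OUTCOME} ~ x")
            _, pval = hosmer_lemeshow(fit)
            rejections += pval < 0.05
        assert 0.01 <= rejections / n_rep <= 0.12

    def test_misspecification_power(self):
        rejections = 0
        n_rep = 40
        for s in range(n_rep):
            rng = np.random.default_rng(3000 + s)
            x = rng.standard_normal(2000)
            p = expit(1.0 - 1.5 * x**2)  # quadratic truth
            y = (rng.random(2000) < p).astype(float)
            df = pd.DataFrame({OUTCOME: y, "x": x, WEIGHT: 1.0})
            fit = fit_weighted_logit(df, f"{OUTCOME} ~ x")
            _, pval = hosmer_lemeshow(fit)
            rejections += pval < 0.05
        assert rejections > n_rep / 2

    def test_few_distinct_probabilities_reduces_groups(self, wave1_table):
        fit = fit_weighted_logit(wave1_table, f"{OUTCOME} ~ sex")
        with pytest.warns(UserWarning, match="distinct"):
            stat, pval = hosmer_lemeshow(fit, groups=10)
        assert np.isfinite(stat)


class TestRocAuc:
    def test_perfect_separation(self):
        s = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0.0, 0, 1, 1])
        assert roc_auc((s, y, np.ones(4))) == 1.0

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(10)
        n = 20000
        s = rng.random(n)
        y = (rng.random(n) < 0.5).astype(float)
        assert abs(roc_auc((s, y, np.ones(n))) - 0.5) < 0.02

    def test_tie_fixture_matches_all_pairs_oracle(self):
        s = np.array([0.3, 0.5, 0.5, 0.7])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        w = np.array([1.0, 2.0, 1.5, 0.5])
        assert roc_auc((s, y, w)) == pytest.approx(auc_all_pairs(s, y, w))

    def test_random_fixtures_match_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(5, 40)
            s = np.round(rng.random(n), 1)
            y = (rng.random(n) < 0.5).astype(float)
            if y.min() == y.max():
                continue
            w = rng.gamma(2, 1, n)
            assert roc_auc((s, y, w)) == pytest.approx(
                auc_all_pairs(s, y, w), abs=1e-12
            )

    def test_single_class_error(self):
        with pytest.raises(ValueError, match="classes"):
            roc_auc((np.array([0.1, 0.2]), np.array([1.0, 1.0]), np.ones(2)))


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        n = 8
        x1 = np.tile([-1.0, 1.0], n // 2)
        x2 = np.repeat([-1.0, 1.0], n // 2)
        df = pd.DataFrame(
            {OUTCOME: np.tile([0, 1.0], n // 2), "x1": x1, "x2": x2, WEIGHT: 1.0}
        )
        res = vif(df, f"{OUTCOME} ~ x1 + x2")
        np.testing.assert_allclose(res.per_term.to_numpy(), 1.0, atol=1e-10)

    def test_correlation_08_gives_2_7778(self):
        rng = np.random.default_rng(11)
        n = 400
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        a = (a - a.mean()) / a.std()
        b = b - b.mean()
        b -= (b @ a) / (a @ a) * a  # orthogonalize
        b /= b.std()
        x2 = 0.8 * a + 0.6 * b
        df = pd.DataFrame(
            {OUTCOME: (rng.random(n) < 0.5).astype(float), "x1": a, "x2": x2,
             WEIGHT: 1.0}
        )
        res = vif(df, f"{OUTCOME} ~ x1 + x2")
        np.testing.assert_allclose(res.per_term.to_numpy(), 1 / 0.36, rtol=1e-6)
        assert res.mean == pytest.approx(1 / 0.36, rel=1e-6)

    def test_duplicated_predictor_flagged_infinite(self):
        rng = np.random.default_rng(12)
        df = _sim_logit(50, 0.5, rng)
        df["x2"] = df["x"]
        res = vif(df, f"{OUTCOME} ~ x + x2")
        assert np.isinf(res.per_term["x"]) and np.isinf(res.per_term["x2"])


class TestLinkTest:
    def test_well_specified_rarely_rejects(self):
        rejections = 0
        n_rep = 100
        for s in range(n_rep):
            rng = np.random.default_rng(4000 + s)
            df = _sim_logit(1500, 1.0, rng)
            fit = fit_weighted_logit(df, f"{OUTCOME} ~ x")
            _, _, p_hatsq = link_test(fit)
            rejections += p_hatsq < 0.05
        assert rejections / n_rep <= 0.12

    def test_quadratic_truth_detected(self):
        rejections = 0
        n_rep = 30
        for s in range(n_rep):
            rng = np.random.default_rng(5000 + s)
            x = rng.standard_normal(2500)
            p = expit(0.5 + x - 1.2 * x**2)
            y = (rng.random(2500) < p).astype(float)
            df = pd.DataFrame({OUTCOME: y, "x": x, WEIGHT: 1.0})
            fit = fit_weighted_logit(df, f"{OUTCOME} ~ x")
            _, _, p_hatsq = link_test(fit)
            rejections += p_hatsq < 0.05
        assert rejections > n_rep / 2

    def test_constant_predictor_errors(self):
        df = pd.DataFrame({OUTCOME: [0, 1] * 10, WEIGHT: 1.0})
        fit = fit_weighted_logit(df, f"{OUTCOME} ~ ")
        with pytest.raises(ValueError, match="constant"):
            link_test(fit)


class TestBuildDesign:
    def test_reference_levels_default(self, wave1_table):
        d = build_design(wave1_table, f"{OUTCOME} ~ employment + sex")
        assert "employment[not_economically_active]" not in d.columns
        assert "sex[male]" not in d.columns
        assert "employment[unemployed]" in d.columns

    def test_reference_level_override(self, wave1_table):
        d = build_design(
            wave1_table, f"{OUTCOME} ~ sex", reference_levels={"sex": "female"}
        )
        assert "sex[male]" in d.columns and "sex[female]" not in d.columns

    def test_complete_case(self):
        df = pd.DataFrame(
            {OUTCOME: [0, 1, np.nan, 1.0], "x": [1.0, np.nan, 2.0, 3.0],
             WEIGHT: 1.0}
        )
        d = build_design(df, f"{OUTCOME} ~ x")
        assert len(d.y) == 2
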