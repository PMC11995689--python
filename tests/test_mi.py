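"""Imputation model, imputed draws, Rubin pooling, and the four analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from proximpute.mi import (
    draw_imputed_dataset,
    fit_imputation_model,
    rubin_pool,
    run_analysis,
)
from proximpute.models import fit_poisson
from proximpute.synth import SimConfig, simulate_dataset


def make_frame(x, x_star, y, queried, pop=None):
    return pd.DataFrame(
        {
            "x": np.where(queried, x, np.nan),
            "x_star": x_star,
            "y": y,
            "pop": np.full(len(x), 4000) if pop is None else pop,
            "queried": queried,
        }
    )


class TestFitImputationModel:
    def test_identity_when_x_equals_x_star(self, rng):
        x = rng.gamma(1, 2.5, 200) + 0.1
        y = rng.poisson(400, 200) + 1
        df = make_frame(x, x, y, np.ones(200, bool))
        fit = fit_imputation_model(df)
        assert fit.coefficients["x_star"] == pytest.approx(1.0, abs=1e-8)
        assert fit.coefficients["intercept"] == pytest.approx(0.0, abs=1e-7)
        assert fit.coefficients["log(y)"] == pytest.approx(0.0, abs=1e-8)
        assert fit.sigma == pytest.approx(0.0, abs=1e-8)

    def test_recovers_known_coefficients(self, rng):
        n = 5000
        x_star = rng.gamma(2, 1.5, n)
        y = rng.poisson(300, n) + 1
        alpha = np.array([0.2, 1.3, -0.05])
        sigma = 0.4
        x = alpha[0] + alpha[1] * x_star + alpha[2] * np.log(y) + sigma * rng.standard_normal(n)
        df = make_frame(x, x_star, y, np.ones(n, bool))
        fit = fit_imputation_model(df)
        se = np.sqrt(np.diag(fit.coef_cov))
        for est, truth, s in zip(fit.coefficients, alpha, se):
            assert abs(est - truth) < 3 * s
        assert fit.sigma == pytest.approx(sigma, rel=0.05)
        assert fit.n_fit == n

    def test_too_few_queried_units_rejected(self, rng):
        df = make_frame(np.ones(3), np.ones(3), np.ones(3), np.ones(3, bool))
        with pytest.raises(ValueError):
            fit_imputation_model(df)

    def test_zero_outcome_with_log_transform_points_to_option(self, rng):
        df = make_frame(np.ones(20), np.ones(20), np.zeros(20), np.ones(20, bool))
        with pytest.raises(ValueError, match="log1p"):
            fit_imputation_model(df)


class TestDrawImputed:
    @pytest.fixture
    def fitted(self, rng):
        n = 500
        x_star = rng.gamma(1, 2.5, n)
        y = rng.poisson(400, n) + 1
        x = 0.3 + 1.2 * x_star + 0.3 * rng.standard_normal(n)
        queried = np.zeros(n, bool)
        queried[:200] = True
        df = make_frame(x, x_star, y, queried)
        return df, fit_imputation_model(df)

    def test_queried_units_unchanged_across_draws(self, fitted, rng):
        df, fit = fitted
        q = df["queried"].to_numpy(bool)
        for _ in range(5):
            comp = draw_imputed_dataset(df, fit, rng)
            np.testing.assert_array_equal(comp.loc[q, "x"], df.loc[q, "x"])
            assert not comp["x"].isna().any()

    def test_zero_sigma_draws_equal_conditional_mean(self, fitted, rng):
        df, fit = fitted
        fit.sigma = 0.0
        comp = draw_imputed_dataset(df, fit, rng, proper=False)
        missing = ~df["queried"].to_numpy(bool)
        mu = fit.conditional_mean(df.loc[missing])
        np.testing.assert_allclose(comp.loc[missing, "x"], mu)

    def test_draw_distribution_matches_conditional_normal(self, fitted, rng):
        df, fit = fitted
        missing_idx = np.flatnonzero(~df["queried"].to_numpy(bool))[0]
        mu = fit.conditional_mean(df.iloc[[missing_idx]])[0]
        draws = np.array(
            [
                draw_imputed_dataset(df, fit, rng, proper=False)["x"].iloc[missing_idx]
                for _ in range(10_000)
            ]
        )
        p = stats.kstest(draws, "norm", args=(mu, fit.sigma)).pvalue
        assert p > 0.01

    def test_truncate_at_zero_clips(self, fitted, rng):
        df, fit = fitted
        fit.coefficients["intercept"] -= 10  # force negative conditional means
        comp = draw_imputed_dataset(df, fit, rng, truncate_at_zero=True)
        assert (comp["x"] >= 0).all()


class TestRubinPool:
    def test_hand_computed_two_imputation_example(self):
        pooled = rubin_pool(np.array([[0.1], [0.2]]), np.array([[0.01], [0.01]]))
        assert pooled.estimate.iloc[0] == pytest.approx(0.15)
        assert pooled.within.iloc[0] == pytest.approx(0.01)
        assert pooled.between.iloc[0] == pytest.approx(0.005)
        assert pooled.total.iloc[0] == pytest.approx(0.0175)

    def test_identical_estimates_fall_back_to_normal_quantile(self):
        est = np.full((5, 1), 0.3)
        var = np.full((5, 1), 0.04)
        pooled = rubin_pool(est, var)
        assert pooled.between.iloc[0] == 0.0
        assert pooled.total.iloc[0] == pytest.approx(0.04)
        assert np.isinf(pooled.df.iloc[0])
        half = pooled.ci_upper.iloc[0] - pooled.estimate.iloc[0]
        assert half == pytest.approx(stats.norm.ppf(0.975) * 0.2)

    def test_order_invariance(self, rng):
        est = rng.normal(0.1, 0.02, (20, 2))
        var = rng.uniform(0.001, 0.002, (20, 2))
        a = rubin_pool(est, var)
        perm = rng.permutation(20)
        b = rubin_pool(est[perm], var[perm])
        pd.testing.assert_series_equal(a.estimate, b.estimate)
        pd.testing.assert_series_equal(a.total, b.total)

    def test_total_at_least_within_and_ci_contains_point(self, rng):
        est = rng.normal(0, 1, (10, 3))
        var = rng.uniform(0.1, 0.5, (10, 3))
        pooled = rubin_pool(est, var)
        assert (pooled.total >= pooled.within).all()
        assert (pooled.ci_lower <= pooled.estimate).all()
        assert (pooled.estimate <= pooled.ci_upper).all()
        # CI at least as wide as if between-variance were zeroed
        zq = stats.norm.ppf(0.975)
        assert ((pooled.ci_upper - pooled.ci_lower)
                >= 2 * zq * np.sqrt(pooled.within) - 1e-12).all()

    def test_single_imputation_rejected(self):
        with pytest.raises(ValueError):
            rubin_pool(np.array([[0.1]]), np.array([[0.01]]))


class TestRunAnalysis:
    def test_all_methods_coincide_when_fully_queried(self):
        cfg = SimConfig(n=300, q=1.0, seed=3)
        df = simulate_dataset(cfg)
        rng = np.random.default_rng(0)
        gold = run_analysis(df, "gold")
        cc = run_analysis(df, "complete_case")
        mi = run_analysis(df, "imputation", b=5, rng=rng)
        assert cc.beta1 == pytest.approx(gold.beta1, abs=1e-12)
        assert mi.beta1 == pytest.approx(gold.beta1, abs=1e-12)
        assert mi.pooled.between.loc["x"] == 0.0
        assert mi.beta1_se == pytest.approx(gold.beta1_se, rel=1e-9)

    def test_complete_case_equals_direct_restricted_fit(self, small_dataset):
        res = run_analysis(small_dataset, "complete_case")
        direct = fit_poisson(small_dataset[small_dataset["queried"]], x_col="x")
        assert res.beta1 == pytest.approx(direct.params["x"], abs=1e-12)

    def test_naive_equals_gold_without_error(self):
        cfg = SimConfig(n=300, seed=3)
        df = simulate_dataset(cfg)
        df["x_star"] = df["x"]
        gold = run_analysis(df, "gold")
        naive = run_analysis(df, "naive")
        assert naive.beta1 == pytest.approx(gold.beta1, abs=1e-12)

    def test_gold_without_full_x_rejected(self, small_dataset):
        masked = small_dataset.copy()
        masked.loc[~masked["queried"], "x"] = np.nan
        with pytest.raises(ValueError):
            run_analysis(masked, "gold")

    def test_unknown_method_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            run_analysis(small_dataset, "bayes")

    def test_congeniality_omitting_outcome_attenuates(self):
        # with a strong proximity effect, dropping log(Y) from the
        # imputation model pulls the pooled estimate toward zero
        cfg = SimConfig(n=20_000, beta1=0.05, q=0.1, seed=8)
        df = simulate_dataset(cfg)
        with_y = run_analysis(df, "imputation", b=10, rng=np.random.default_rng(1))
        without_y = run_analysis(
            df, "imputation", b=10, rng=np.random.default_rng(1),
            outcome_transform="drop",
        )
        assert without_y.beta1 < with_y.beta1

    def test_imputation_recovers_truth_where_naive_does_not(self):
        # 200 replicates of the default additive-error scenario: the MI
        # estimator's mean is within Monte Carlo error of beta1 = 0.01,
        # the naive estimator's is not
        cfg = SimConfig(n=387, sigma_u=0.8, q=0.1, seed=12)
        imp, naive = [], []
        for child in np.random.SeedSequence(12).spawn(200):
            rng = np.random.default_rng(child)
            df = simulate_dataset(cfg, rng)
            naive.append(run_analysis(df, "naive").beta1)
            imp.append(run_analysis(df, "imputation", b=20, rng=rng).beta1)
        mc_err = np.std(imp, ddof=1) / np.sqrt(len(imp))
        assert abs(np.mean(imp) - 0.01) < 3 * mc_err
        naive_err = np.std(naive, ddof=1) / np.sqrt(len(naive))
        assert abs(np.mean(naive) - 0.01) > 3 * naive_err
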