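"""GLMM engine: degeneracy to GLM/OLS oracles, exact Gaussian marginals,
parameter recovery, and likelihood cross-checks."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.stats import multivariate_normal

from wrenfit.mixedmodels import FAMILIES, GLMMFit, fit_glmm, loglik_gauss_hermite


@pytest.fixture(scope="module")
def xmat():
    rng = np.random.default_rng(1)
    n = 600
    return rng, np.column_stack([np.ones(n), rng.normal(size=n)])


class TestDegenerateOracles:
    def test_binary_no_grouping_matches_glm(self, xmat):
        rng, X = xmat
        y = rng.binomial(1, 1 / (1 + np.exp(-(0.3 + 0.8 * X[:, 1]))))
        fit = fit_glmm(y, X, ["const", "x"], None, "binary")
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.abs(fit.beta - glm.params).max() < 1e-4
        assert fit.loglik == pytest.approx(glm.llf, abs=1e-6)

    def test_gaussian_no_grouping_matches_ols(self, xmat):
        rng, X = xmat
        y = 1.0 + 0.5 * X[:, 1] + rng.normal(0, 1.3, len(X))
        fit = fit_glmm(y, X, ["const", "x"], None, "gaussian")
        ols = sm.OLS(y, X).fit()
        assert np.abs(fit.beta - ols.params).max() < 1e-6
        assert fit.loglik == pytest.approx(ols.llf, abs=1e-6)

    def test_zip_without_zero_inflation_matches_poisson_glm(self):
        # a sample whose zeros sit at/below the Poisson expectation: the
        # zero-inflation collapses to its boundary and the count part
        # degenerates to plain Poisson regression (pi contributes < 0.005
        # residual log-likelihood at the pinned boundary value)
        rng = np.random.default_rng(4)
        n = 600
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.poisson(np.exp(1.2 + 0.4 * X[:, 1]))
        assert (y == 0).mean() <= np.exp(-np.exp(1.2 + 0.4 * X[:, 1])).mean()
        fit = fit_glmm(y, X, ["const", "x"], None, "zip")
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert np.abs(fit.beta - glm.params).max() < 1e-4
        assert fit.loglik == pytest.approx(glm.llf, abs=5e-3)

    def test_zip_matches_statsmodels_zip_ml(self, xmat):
        # independent full-ML oracle for the mixture itself
        from statsmodels.discrete.count_model import ZeroInflatedPoisson

        rng, X = xmat
        mu = np.exp(0.2 + 0.4 * X[:, 1])
        y = np.where(rng.random(len(X)) < 0.25, 0, rng.poisson(mu))
        fit = fit_glmm(y, X, ["const", "x"], None, "zip")
        ref = ZeroInflatedPoisson(y, X, exog_infl=np.ones((len(X), 1))).fit(disp=0)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-4)
        assert np.abs(fit.beta - ref.params[1:]).max() < 1e-3
        assert fit.extra["logit_pi"] == pytest.approx(ref.params[0], abs=1e-3)

    def test_one_observation_per_group_pins_variance(self, xmat):
        rng, X = xmat
        y = rng.binomial(1, 0.4, len(X))
        groups = [("g", np.arange(len(X)))]
        with pytest.warns(UserWarning, match="one level per observation"):
            fit = fit_glmm(y, X[:, :1], ["const"], groups, "binary")
        glm = sm.GLM(y, X[:, :1], family=sm.families.Binomial()).fit()
        assert abs(fit.beta[0] - glm.params[0]) < 1e-3


class TestGaussianExactness:
    def test_single_factor_matches_mixedlm_ml(self, xmat):
        rng, X = xmat
        groups = np.repeat(np.arange(60), 10)
        u = rng.normal(0, 0.7, 60)
        y = 2.0 + 0.5 * X[:, 1] + u[groups] + rng.normal(0, 1.0, len(X))
        fit = fit_glmm(y, X, ["const", "x"], [("g", groups)], "gaussian")
        mlm = sm.MixedLM(y, X, groups=groups).fit(reml=False)
        assert np.abs(fit.beta - mlm.fe_params).max() < 1e-4
        assert fit.loglik == pytest.approx(mlm.llf, abs=1e-5)

    def test_nested_marginal_equals_mvn_density(self, xmat):
        # for Gaussian responses the Laplace marginal is exact: it must
        # equal the closed-form multivariate normal log-density
        rng, X = xmat
        n = len(X)
        mo = np.repeat(np.arange(30), 20)
        ne = np.repeat(np.arange(120), 5)
        y = (
            1.0 + 0.5 * X[:, 1]
            + rng.normal(0, 0.6, 30)[mo]
            + rng.normal(0, 0.5, 120)[ne]
            + rng.normal(0, 1, n)
        )
        fit = fit_glmm(y, X, ["const", "x"], [("m", mo), ("n", ne)], "gaussian")
        Zm = np.eye(30)[mo]
        Zn = np.eye(120)[ne]
        V = (
            np.exp(2 * fit.extra["log_sigma"]) * np.eye(n)
            + fit.re_sd["m"] ** 2 * Zm @ Zm.T
            + fit.re_sd["n"] ** 2 * Zn @ Zn.T
        )
        oracle = multivariate_normal.logpdf(y, X @ fit.beta, V)
        assert fit.loglik == pytest.approx(oracle, abs=1e-8)

    def test_balanced_one_way_matches_anova_closed_form(self):
        # balanced one-way layout: ML variance components have closed forms
        # sigma_e^2 = SSW/(n-a), tau^2 = SSB/n... via profile likelihood;
        # easiest exact check: compare to MixedLM ML on the same data
        rng = np.random.default_rng(8)
        a, m = 40, 8
        groups = np.repeat(np.arange(a), m)
        y = 1.0 + rng.normal(0, 0.9, a)[groups] + rng.normal(0, 1.2, a * m)
        X = np.ones((a * m, 1))
        fit = fit_glmm(y, X, ["const"], [("g", groups)], "gaussian")
        ybar_g = y.reshape(a, m).mean(axis=1)
        ssw = ((y.reshape(a, m) - ybar_g[:, None]) ** 2).sum()
        ssb = m * ((ybar_g - y.mean()) ** 2).sum()
        sigma2 = ssw / (a * (m - 1))
        tau2 = max(ssb / a / m * (a - 1) / a - sigma2 / m, 0)  # ML one-way components
        assert np.exp(2 * fit.extra["log_sigma"]) == pytest.approx(sigma2, rel=0.02)
        assert fit.re_sd["g"] ** 2 == pytest.approx(tau2, rel=0.06)
        assert fit.beta[0] == pytest.approx(y.mean(), abs=1e-6)


class TestRecovery:
    def test_binary_intercept_only_recovers_probability(self):
        rng = np.random.default_rng(10)
        n = 2000
        y = rng.binomial(1, 0.3, n)
        fit = fit_glmm(y, np.ones((n, 1)), ["const"], None, "binary")
        p_hat = 1 / (1 + np.exp(-fit.beta[0]))
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(p_hat - 0.3) < 3 * se

    def test_gaussian_slope_recovery_with_random_intercepts(self):
        rng = np.random.default_rng(11)
        n, g = 2000, 200
        groups = np.repeat(np.arange(g), n // g)
        x = rng.normal(size=n)
        y = 1.0 + 0.4 * x + rng.normal(0, 0.5, g)[groups] + rng.normal(0, 1, n)
        X = np.column_stack([np.ones(n), x])
        fit = fit_glmm(y, X, ["const", "x"], [("g", groups)], "gaussian")
        assert abs(fit.beta[1] - 0.4) < 3 * (1.0 / np.sqrt(n))

    def test_zip_mixture_recovery(self):
        rng = np.random.default_rng(12)
        n = 2000
        x = rng.normal(size=n)
        mu = np.exp(0.7 + 0.3 * x)
        y = np.where(rng.random(n) < 0.4, 0, rng.poisson(mu))
        X = np.column_stack([np.ones(n), x])
        fit = fit_glmm(y, X, ["const", "x"], None, "zip")
        pi_hat = 1 / (1 + np.exp(-fit.extra["logit_pi"]))
        assert abs(pi_hat - 0.4) < 3 * np.sqrt(0.4 * 0.6 / n) * 2
        assert abs(fit.beta[1] - 0.3) < 0.05


class TestLikelihoodCrossChecks:
    def test_no_re_loglik_is_exact_density_sum(self, xmat):
        # direct evaluation of the stated per-observation densities
        rng, X = xmat
        y = rng.binomial(1, 1 / (1 + np.exp(-(0.2 + 0.5 * X[:, 1]))))
        fit = fit_glmm(y, X, ["const", "x"], None, "binary")
        eta = X @ fit.beta
        direct = float((y * eta - np.log1p(np.exp(eta))).sum())
        assert fit.loglik == pytest.approx(direct, abs=1e-8)

    def test_laplace_close_to_gauss_hermite(self, xmat):
        rng, X = xmat
        groups = np.repeat(np.arange(60), 10)
        u = rng.normal(0, 0.8, 60)
        y = rng.binomial(1, 1 / (1 + np.exp(-(0.2 + 0.6 * X[:, 1] + u[groups]))))
        fit = fit_glmm(y, X, ["const", "x"], [("g", groups)], "binary")
        gh = loglik_gauss_hermite(y, X, fit, groups)
        # Laplace is an approximation; agreement to ~0.1% of |logLik|
        assert abs(fit.loglik - gh) < 0.002 * abs(gh)


class TestValidation:
    def test_constant_binary_response_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_glmm(np.ones(20), np.ones((20, 1)), ["const"], None, "binary")

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(30), np.ones(30)])
        y = np.r_[np.zeros(15), np.ones(15)]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_glmm(y, X, ["const", "dup"], None, "binary")

    def test_all_zero_zip_rejected(self):
        with pytest.raises(ValueError, match="all zeros"):
            fit_glmm(np.zeros(20), np.ones((20, 1)), ["const"], None, "zip")

    def test_non_nested_factors_rejected(self):
        from wrenfit.mixedmodels import RandomStructure

        a = np.array([0, 0, 1, 1])
        b = np.array([0, 1, 1, 0])
        with pytest.raises(ValueError, match="nested"):
            RandomStructure([("a", a), ("b", b)])
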