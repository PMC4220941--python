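"""Nested-Laplace inference: inner approximation, grid mixing, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from whitepox import (
    ColonyRecord,
    CovariateMatrix,
    DesignOptions,
    GridSpec,
    Hyperparameters,
    HyperPriors,
    LatentField,
    build_design,
    hyper_grid_integrate,
    inner_gaussian_approx,
    linear_predictor,
    summarize,
)
from whitepox.covariates import COVARIATE_NAMES
from whitepox.inference import ConvergenceError, GaussianObs, _InnerSolver
from whitepox.field import SpaceTimePrior

from conftest import make_panel


def _design_from_columns(panel, names, columns):
    """Hand-built design matrix (already on the analysis scale)."""
    n, T = panel.presence.shape
    values = np.stack(columns, axis=2)
    return CovariateMatrix(
        names=tuple(names),
        values=values,
        standardization={name: (0.0, 1.0) for name in names},
        transform_log={name: False for name in names},
        options=DesignOptions(standardize=False),
    )


@pytest.fixture
def toy_panel(rng):
    presence = np.array(
        [[1.0, 0.0], [0.0, 0.0], [1.0, 1.0]]
    )
    return make_panel(presence, rng=rng)


@pytest.fixture
def toy_design(toy_panel, rng):
    n, T = 3, 2
    x = rng.normal(size=(n, T))
    return _design_from_columns(
        toy_panel, ["intercept", "x"], [np.ones((n, T)), x]
    )


class TestLinearPredictor:
    def test_null_model_gives_half_probability(self, small_panel):
        design = build_design(small_panel)
        eta = linear_predictor(design, np.zeros(9))
        assert np.allclose(expit(eta), 0.5)

    def test_intercept_only_matches_logistic(self, small_panel):
        design = build_design(small_panel)
        beta = np.zeros(9)
        beta[0] = -3.29
        eta = linear_predictor(design, beta)
        assert np.allclose(expit(eta), expit(-3.29))
        assert expit(-3.29) == pytest.approx(0.0359, abs=2e-4)

    def test_matches_elementwise_bruteforce(self, small_panel, rng):
        design = build_design(small_panel)
        beta = rng.normal(size=9)
        xi = LatentField(rng.normal(size=small_panel.presence.shape))
        eps = rng.normal(size=small_panel.presence.shape)
        eta = linear_predictor(design, beta, xi, eps)
        for i in range(small_panel.n_colonies):
            for t in range(small_panel.n_occasions):
                expected = design.values[i, t] @ beta + xi.xi[i, t] + eps[i, t]
                assert eta[i, t] == pytest.approx(expected)

    def test_shape_mismatch_raises(self, small_panel):
        design = build_design(small_panel)
        with pytest.raises(ValueError):
            linear_predictor(design, np.zeros(3))


class TestInnerGaussianApprox:
    def test_gaussian_likelihood_matches_conjugate_oracle(self, toy_panel, toy_design, rng):
        """With a Gaussian likelihood the Laplace approximation is exact."""
        hyper = Hyperparameters(
            spatial_range=50, sigma_xi=0.8, ar_coef=0.5, sigma_eps=0.4
        )
        sd_obs = 0.7
        y = rng.normal(size=6)  # occasion-major stacked observations
        panel = make_panel(np.zeros((3, 2)), rng=np.random.default_rng(3))
        # exact joint Gaussian posterior for (xi, eps, beta)
        prior = SpaceTimePrior(hyper, panel.distance_matrix(), 2)
        Z = toy_design.flat()
        beta_sd = 2.0
        nt, p = Z.shape
        cov_prior = np.zeros((2 * nt + p, 2 * nt + p))
        cov_prior[:nt, :nt] = prior.covariance_dense()
        cov_prior[nt : 2 * nt, nt : 2 * nt] = hyper.sigma_eps**2 * np.eye(nt)
        cov_prior[2 * nt :, 2 * nt :] = beta_sd**2 * np.eye(p)
        A = np.concatenate([np.eye(nt), np.eye(nt), Z], axis=1)
        q_post = np.linalg.inv(cov_prior) + A.T @ A / sd_obs**2
        mean_post = np.linalg.solve(q_post, A.T @ y / sd_obs**2)

        solver = _InnerSolver(prior, Z, y, GaussianObs(sd_obs), np.eye(p) / beta_sd**2)
        res = solver.solve()
        assert np.abs(res["beta"] - mean_post[2 * nt :]).max() < 1e-8
        assert np.abs(res["xi"] - mean_post[:nt]).max() < 1e-8
        cov_post = np.linalg.inv(q_post)
        assert np.abs(res["beta_cov"] - cov_post[2 * nt :, 2 * nt :]).max() < 1e-8

    def test_gaussian_evidence_matches_closed_form(self, toy_design, rng):
        """Laplace log evidence equals the exact Gaussian marginal likelihood."""
        from scipy.stats import multivariate_normal

        hyper = Hyperparameters(
            spatial_range=50, sigma_xi=0.8, ar_coef=0.5, sigma_eps=0.4
        )
        sd_obs = 0.7
        y = rng.normal(size=6)
        panel = make_panel(np.zeros((3, 2)), rng=np.random.default_rng(3))
        prior = SpaceTimePrior(hyper, panel.distance_matrix(), 2)
        Z = toy_design.flat()
        beta_sd = 2.0
        cov_y = (
            prior.covariance_dense()
            + hyper.sigma_eps**2 * np.eye(6)
            + beta_sd**2 * Z @ Z.T
            + sd_obs**2 * np.eye(6)
        )
        exact = multivariate_normal(mean=np.zeros(6), cov=cov_y).logpdf(y)
        solver = _InnerSolver(
            prior, Z, y, GaussianObs(sd_obs), np.eye(2) / beta_sd**2
        )
        res = solver.solve()
        assert res["log_evidence"] == pytest.approx(exact, abs=1e-6)

    def test_negligible_field_matches_1d_quadrature(self, rng):
        """With the field off, the intercept posterior matches quadrature."""
        presence = (rng.uniform(size=(10, 20)) < 0.25).astype(float)
        panel = make_panel(presence, rng=rng)
        design = _design_from_columns(panel, ["intercept"], [np.ones((10, 20))])
        hyper = Hyperparameters(
            spatial_range=50, sigma_xi=1e-4, ar_coef=0.0, sigma_eps=0.0
        )
        beta_sd = 10.0
        fit = hyper_grid_integrate(
            panel,
            design,
            hyper_fixed=hyper,
            strategy="laplace",
            priors=HyperPriors(log_range_mean=np.log(50), beta_prior_sd=beta_sd),
        )
        summ = summarize(fit)
        # dense quadrature over the single coefficient
        y = presence.ravel()
        grid = np.linspace(-6, 4, 4001)
        loglik = np.array(
            [np.sum(y * b - np.logaddexp(0, b)) for b in grid]
        ) - 0.5 * grid**2 / beta_sd**2
        dens = np.exp(loglik - loglik.max())
        dens /= np.trapezoid(dens, grid)
        mean_exact = np.trapezoid(grid * dens, grid)
        assert summ["mean"].iloc[0] == pytest.approx(mean_exact, abs=1e-3)

    def test_all_zero_presence_gives_negative_intercept(self, rng):
        presence = np.zeros((5, 8))
        panel = make_panel(presence, rng=rng)
        design = _design_from_columns(panel, ["intercept"], [np.ones((5, 8))])
        approx = inner_gaussian_approx(panel, design, Hyperparameters())
        assert approx.beta_mean[0] < 0
        # the gradient resolves to its floating-point floor near the mode
        assert approx.converged and approx.grad_norm < 1e-5

    def test_nonconvergence_raises_with_diagnostics(self, toy_panel, toy_design):
        with pytest.raises(ConvergenceError) as err:
            inner_gaussian_approx(
                toy_panel, toy_design, Hyperparameters(), max_iter=1, grad_tol=1e-12
            )
        assert "iterations" in err.value.diagnostics


class TestHyperGridIntegrate:
    def test_single_point_grid_equals_conditional(self, rng, small_panel):
        design = build_design(small_panel)
        hyper = Hyperparameters()
        fit = hyper_grid_integrate(
            small_panel, design, hyper_fixed=hyper, strategy="gaussian"
        )
        approx = inner_gaussian_approx(small_panel, design, hyper)
        assert np.allclose(fit.marginal_mean(), approx.beta_mean, atol=1e-10)
        assert np.allclose(fit.marginal_sd(), approx.beta_sd, atol=1e-10)
        assert fit.weights.tolist() == [1.0]

    def test_equal_evidence_two_point_mixture(self):
        """A symmetric two-component mixture has the pooled moments."""
        from whitepox.inference import ModelFit

        means = np.array([[1.0], [-1.0]])
        sds = np.array([[0.5], [0.5]])
        grid = np.linspace(-4, 4, 1001)
        from scipy.stats import norm as normal

        dens = 0.5 * normal.pdf(grid, 1.0, 0.5) + 0.5 * normal.pdf(grid, -1.0, 0.5)
        fit = ModelFit(
            names=("x",),
            hyper_points=[Hyperparameters(), Hyperparameters()],
            weights=np.array([0.5, 0.5]),
            log_evidence=np.zeros(2),
            beta_means=means,
            beta_sds=sds,
            beta_marginals=[(grid, dens / np.trapezoid(dens, grid))],
            latent_mode=LatentField(np.zeros((1, 1))),
            eps_mode=np.zeros((1, 1)),
            modal_hyper=Hyperparameters(),
        )
        assert fit.marginal_mean()[0] == pytest.approx(0.0)
        assert fit.marginal_sd()[0] == pytest.approx(np.sqrt(0.25 + 1.0))
        summ = summarize(fit)
        assert summ["mean"].iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert not summ["significant"].iloc[0]

    def test_colony_permutation_invariance(self, rng):
        presence = (rng.uniform(size=(8, 12)) < 0.3).astype(float)
        panel = make_panel(presence, rng=rng)
        perm = rng.permutation(8)
        panel_p = make_panel(
            presence[perm], colonies=[panel.colonies[i] for i in perm]
        )
        hyper = Hyperparameters(spatial_range=60, sigma_xi=0.7, ar_coef=0.5, sigma_eps=0.2)
        d1 = build_design(panel)
        d2 = build_design(panel_p)
        f1 = hyper_grid_integrate(panel, d1, hyper_fixed=hyper, strategy="gaussian")
        f2 = hyper_grid_integrate(panel_p, d2, hyper_fixed=hyper, strategy="gaussian")
        assert np.allclose(f1.marginal_mean(), f2.marginal_mean(), atol=1e-7)
        assert np.allclose(f1.marginal_sd(), f2.marginal_sd(), atol=1e-7)


class TestOracleEquivalence:
    """Small-panel posterior means vs dense tensor-quadrature integration."""

    @staticmethod
    def _quadrature_beta_mean(
        panel, design, hyper, beta_sd, n_field_nodes=6, n_beta=41, beta_max=8.0
    ):
        """Dense tensor integration over (beta, latent field).

        Each coefficient lives on a bounded grid; for every grid point the
        marginal likelihood over the 6-dimensional latent field
        (xi + eps ~ N(0, cov_xi + sigma_eps^2 I)) is computed by full tensor
        Gauss-Hermite quadrature.  Stable under node/grid refinement to
        well below the comparison tolerance.
        """
        from numpy.polynomial.hermite_e import hermegauss

        prior = SpaceTimePrior(hyper, panel.distance_matrix(), panel.n_occasions)
        Z = design.flat()
        nt, p = Z.shape
        cov_field = prior.covariance_dense() + hyper.sigma_eps**2 * np.eye(nt)
        L = np.linalg.cholesky(cov_field)
        nodes, wts = hermegauss(n_field_nodes)
        wts = wts / np.sqrt(2 * np.pi)  # N(0,1) quadrature weights
        U = np.stack(
            [g.ravel() for g in np.meshgrid(*([nodes] * nt), indexing="ij")]
        )
        W = np.prod(
            np.stack(
                [g.ravel() for g in np.meshgrid(*([wts] * nt), indexing="ij")]
            ),
            axis=0,
        )
        field = L @ U  # (nt, M)
        y = panel.presence.T.ravel()
        bg = np.linspace(-beta_max, beta_max, n_beta)
        bpoints = np.column_stack(
            [g.ravel() for g in np.meshgrid(*([bg] * p), indexing="ij")]
        )
        etab = bpoints @ Z.T
        log_py = np.empty(len(bpoints))
        for s in range(0, len(bpoints), 32):
            eta = etab[s : s + 32, :, None] + field[None]
            ll = np.einsum("i,cim->cm", y, eta) - np.logaddexp(0, eta).sum(axis=1)
            m = ll.max(axis=1)
            log_py[s : s + 32] = m + np.log(
                (np.exp(ll - m[:, None]) * W).sum(axis=1)
            )
        log_post = log_py - (bpoints**2).sum(axis=1) / (2 * beta_sd**2)
        pw = np.exp(log_post - log_post.max())
        pw /= pw.sum()
        return bpoints.T @ pw

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_small_panel_means_match_quadrature(self, seed):
        rng = np.random.default_rng(seed)
        presence = (rng.uniform(size=(3, 2)) < 0.5).astype(float)
        panel = make_panel(presence, rng=rng)
        x = rng.normal(size=(3, 2))
        design = _design_from_columns(
            panel, ["intercept", "x"], [np.ones((3, 2)), x]
        )
        hyper = Hyperparameters(
            spatial_range=60, sigma_xi=0.6, ar_coef=0.4, sigma_eps=0.3
        )
        beta_sd = 2.0
        priors = HyperPriors(log_range_mean=np.log(60), beta_prior_sd=beta_sd)
        fit = hyper_grid_integrate(
            panel, design, hyper_fixed=hyper, strategy="laplace", priors=priors
        )
        summ = summarize(fit)
        exact = self._quadrature_beta_mean(panel, design, hyper, beta_sd)
        assert np.abs(summ["mean"].to_numpy() - exact).max() < 0.02


class TestSummarize:
    def test_symmetric_marginal_mean_equals_median_and_mode(self):
        from whitepox.inference import ModelFit
        from scipy.stats import norm as normal

        grid = np.linspace(-4, 6, 2001)
        dens = normal.pdf(grid, 1.0, 0.8)
        fit = ModelFit(
            names=("x",),
            hyper_points=[Hyperparameters()],
            weights=np.array([1.0]),
            log_evidence=np.zeros(1),
            beta_means=np.array([[1.0]]),
            beta_sds=np.array([[0.8]]),
            beta_marginals=[(grid, dens)],
            latent_mode=LatentField(np.zeros((1, 1))),
            eps_mode=np.zeros((1, 1)),
            modal_hyper=Hyperparameters(),
        )
        summ = summarize(fit)
        row = summ.iloc[0]
        assert row["mean"] == pytest.approx(1.0, abs=1e-3)
        assert row["q50"] == pytest.approx(1.0, abs=1e-3)
        assert row["mode"] == pytest.approx(1.0, abs=0.01)

    def test_significance_rule(self):
        from whitepox.inference import ModelFit
        from scipy.stats import norm as normal

        # quantiles (0.12, ...) > 0 -> significant; (-1.32, 1.89) -> not
        cases = [
            (0.30, 0.09, True),
            (0.29, 0.83, False),
        ]
        for mean, sd, expected in cases:
            grid = np.linspace(mean - 6 * sd, mean + 6 * sd, 2001)
            dens = normal.pdf(grid, mean, sd)
            fit = ModelFit(
                names=("x",),
                hyper_points=[Hyperparameters()],
                weights=np.array([1.0]),
                log_evidence=np.zeros(1),
                beta_means=np.array([[mean]]),
                beta_sds=np.array([[sd]]),
                beta_marginals=[(grid, dens)],
                latent_mode=LatentField(np.zeros((1, 1))),
                eps_mode=np.zeros((1, 1)),
                modal_hyper=Hyperparameters(),
            )
            assert summarize(fit)["significant"].iloc[0] == expected

    def test_quantiles_ordered_for_full_fit(self, small_panel):
        design = build_design(small_panel)
        fit = hyper_grid_integrate(
            small_panel, design, hyper_fixed=Hyperparameters(), strategy="gaussian"
        )
        summ = summarize(fit)
        assert (summ["q025"] <= summ["q50"]).all()
        assert (summ["q50"] <= summ["q975"]).all()
        assert list(summ.index[:3]) == ["Intercept", "Northing", "Easting"]


class TestLogisticRegressionLimit:
    def test_matches_statsmodels_glm(self, rng):
        """Field off, weak prior: posterior mode ~ the ML logistic fit."""
        import statsmodels.api as sm

        n, T = 12, 30
        presence = np.empty((n, T))
        x = rng.normal(size=(n, T))
        beta_true = np.array([-1.0, 0.8])
        eta = beta_true[0] + beta_true[1] * x
        presence = (rng.uniform(size=(n, T)) < expit(eta)).astype(float)
        panel = make_panel(presence, rng=rng)
        design = _design_from_columns(panel, ["intercept", "x"], [np.ones((n, T)), x])
        hyper = Hyperparameters(
            spatial_range=50, sigma_xi=1e-4, ar_coef=0.0, sigma_eps=0.0
        )
        priors = HyperPriors(log_range_mean=np.log(50), beta_prior_sd=100.0)
        fit = hyper_grid_integrate(
            panel, design, hyper_fixed=hyper, strategy="gaussian", priors=priors
        )
        glm = sm.GLM(
            presence.T.ravel(),
            design.flat(),
            family=sm.families.Binomial(),
        ).fit()
        assert np.abs(fit.marginal_mean() - glm.params).max() < 5e-3
        assert np.abs(fit.marginal_sd() - glm.bse).max() < 5e-3
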