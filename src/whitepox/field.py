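"""Latent spatio-temporal Gaussian structure.

The unobserved disease-propensity field :math:`\\xi(s_i, t)` is a zero-mean
Gaussian field that is Matérn-correlated in space across the colony sites and
evolves in time under stationary first-order autoregressive (AR(1)) dynamics.
Space and time are separable, so the joint covariance of the stacked field is a
Kronecker product

.. math::

    \\mathrm{Cov}(\\xi) = R_{\\mathrm{AR}}(a) \\otimes \\sigma_\\xi^2
    \\bar{C}_{\\nu}(d / r),

where :math:`R_{\\mathrm{AR}}` is the :math:`T \\times T` AR(1) correlation
matrix, :math:`\\bar{C}_\\nu` the Matérn correlation at the pairwise site
distances, and the stationary marginal variance of every cell is
:math:`\\sigma_\\xi^2` (AR(1) innovation variance :math:`(1-a^2)\\sigma_\\xi^2`).

At a few dozen irregular sites the Matérn covariance is computed exactly and
densely; no mesh or finite-element approximation is involved.  An additional
iid Gaussian term :math:`\\varepsilon(s_i,t) \\sim N(0, \\sigma_\\varepsilon^2)`
acts as an observation-level random effect on the linear predictor, absorbing
unstructured extra-binomial variation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.special import gammaln, kv

__all__ = [
    "Hyperparameters",
    "LatentField",
    "matern_covariance",
    "ar1_structure",
    "joint_prior",
    "SpaceTimePrior",
    "sample_field",
]

#: Relative jitter added to covariance diagonals before factorisation.
JITTER = 1e-8


@dataclass(frozen=True)
class Hyperparameters:
    """Hyperparameters of the latent field and observation noise.

    Attributes
    ----------
    spatial_range:
        Distance (metres) at which the Matérn spatial correlation has decayed
        to roughly 0.1; the usual range convention kappa = sqrt(8 nu) / range.
    sigma_xi:
        Stationary marginal standard deviation of the latent field, on the
        logit scale.
    nu:
        Matérn smoothness; 1 by default (0.5 gives the exponential model).
    ar_coef:
        AR(1) coefficient a in (-1, 1) for month-to-month persistence.
    sigma_eps:
        Standard deviation of the iid observation-level Gaussian effect
        (logit scale); 0 disables the term.
    """

    spatial_range: float = 250.0
    sigma_xi: float = 1.5
    nu: float = 1.0
    ar_coef: float = 0.9
    sigma_eps: float = 0.25

    def __post_init__(self) -> None:
        if not self.spatial_range > 0:
            raise ValueError("spatial_range must be > 0")
        if not self.sigma_xi > 0:
            raise ValueError("sigma_xi must be > 0")
        if not self.nu > 0:
            raise ValueError("nu must be > 0")
        if not abs(self.ar_coef) < 1:
            raise ValueError("ar_coef must lie in (-1, 1)")
        if self.sigma_eps < 0:
            raise ValueError("sigma_eps must be >= 0")

    def replace(self, **kwargs) -> "Hyperparameters":
        return replace(self, **kwargs)


@dataclass
class LatentField:
    """A realisation of the latent field, colonies x occasions, logit scale."""

    xi: np.ndarray

    @property
    def n_colonies(self) -> int:
        return self.xi.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.xi.shape[1]


def matern_covariance(
    distances: np.ndarray,
    spatial_range: float,
    sigma: float,
    nu: float = 1.0,
    jitter: float = JITTER,
) -> np.ndarray:
    """Dense Matérn covariance matrix at the given pairwise distances.

    C(d) = sigma^2 * 2^(1-nu)/Gamma(nu) * (kappa d)^nu K_nu(kappa d), with
    kappa = sqrt(8 nu)/range so that the correlation at d = range is ~0.1.
    ``jitter * sigma^2`` is added to the diagonal so the returned matrix is
    safely positive definite.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.ndim != 2 or distances.shape[0] != distances.shape[1]:
        raise ValueError("distances must be a square matrix")
    if not np.allclose(distances, distances.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(distances < 0) or np.any(np.diag(distances) != 0):
        raise ValueError("distances must be non-negative with zero diagonal")
    if spatial_range <= 0 or sigma <= 0 or nu <= 0:
        raise ValueError("spatial_range, sigma and nu must be positive")

    kappa = np.sqrt(8.0 * nu) / spatial_range
    x = kappa * distances
    corr = np.ones_like(x)
    pos = x > 0
    xp = x[pos]
    # log-space for numerical stability of 2^(1-nu)/Gamma(nu) * x^nu K_nu(x)
    log_c = (1.0 - nu) * np.log(2.0) - gammaln(nu) + nu * np.log(xp)
    corr[pos] = np.exp(log_c) * kv(nu, xp)
    cov = sigma**2 * corr
    cov[np.diag_indices_from(cov)] = sigma**2 * (1.0 + jitter)
    return cov


def ar1_structure(n_occasions: int, ar_coef: float) -> tuple[np.ndarray, np.ndarray]:
    """Stationary AR(1) correlation matrix and its tridiagonal precision.

    Returns ``(corr, prec)`` with corr[t, s] = a^|t-s| and prec the standard
    tridiagonal AR(1) precision; ``prec @ corr`` is the identity.
    """
    if not abs(ar_coef) < 1:
        raise ValueError("ar_coef must lie in (-1, 1)")
    if n_occasions < 1:
        raise ValueError("n_occasions must be >= 1")
    t = np.arange(n_occasions)
    corr = ar_coef ** np.abs(t[:, None] - t[None, :])
    prec = np.zeros((n_occasions, n_occasions))
    if n_occasions == 1:
        prec[0, 0] = 1.0
        return corr, prec
    one_m_a2 = 1.0 - ar_coef**2
    diag = np.full(n_occasions, (1.0 + ar_coef**2) / one_m_a2)
    diag[0] = diag[-1] = 1.0 / one_m_a2
    np.fill_diagonal(prec, diag)
    off = -ar_coef / one_m_a2
    idx = np.arange(n_occasions - 1)
    prec[idx, idx + 1] = off
    prec[idx + 1, idx] = off
    return corr, prec


class SpaceTimePrior:
    """Separable AR(1) (x) Matérn Gaussian prior over the stacked latent field.

    The stacked vector is occasion-major: cell (colony i, occasion t) sits at
    index ``t * n + i``.  Solves, quadratic forms, log-determinants and exact
    sampling all use the Kronecker factorisation; the n*T x n*T matrix is never
    materialised.
    """

    def __init__(self, hyper: Hyperparameters, distances: np.ndarray, n_occasions: int):
        self.hyper = hyper
        self.n = distances.shape[0]
        self.T = int(n_occasions)
        self.cov_s = matern_covariance(
            distances, hyper.spatial_range, hyper.sigma_xi, hyper.nu
        )
        self.corr_t, self.prec_t = ar1_structure(self.T, hyper.ar_coef)
        # dense spatial factors (n is small)
        self._chol_s = cholesky(self.cov_s, lower=True)
        c, low = cho_factor(self.cov_s, lower=True)
        self.prec_s = cho_solve((c, low), np.eye(self.n))
        self.prec_s = 0.5 * (self.prec_s + self.prec_s.T)
        self._logdet_cov_s = 2.0 * np.sum(np.log(np.diag(self._chol_s)))
        # AR(1) correlation has log-determinant (T-1) * log(1 - a^2)
        self._logdet_corr_t = (self.T - 1) * np.log1p(-hyper.ar_coef**2)
        self._chol_t = cholesky(self.corr_t, lower=True) if self.T > 1 else np.ones((1, 1))

    @property
    def dim(self) -> int:
        return self.n * self.T

    @property
    def logdet_cov(self) -> float:
        """log |Cov| of the stacked field."""
        return self.n * self._logdet_corr_t + self.T * self._logdet_cov_s

    @property
    def logdet_prec(self) -> float:
        return -self.logdet_cov

    def _as_matrix(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float).reshape(self.T, self.n)

    def prec_mult(self, x: np.ndarray) -> np.ndarray:
        """Q @ x for the stacked field, via (Q_t (x) Q_s) X."""
        xm = self._as_matrix(x)
        return (self.prec_t @ xm @ self.prec_s.T).ravel()

    def solve(self, x: np.ndarray) -> np.ndarray:
        """Q^{-1} @ x (i.e. Cov @ x)."""
        xm = self._as_matrix(x)
        return (self.corr_t @ xm @ self.cov_s.T).ravel()

    def quad(self, x: np.ndarray) -> float:
        """x' Q x."""
        xm = self._as_matrix(x)
        return float(np.sum(xm * (self.prec_t @ xm @ self.prec_s.T)))

    def covariance_dense(self) -> np.ndarray:
        """Dense covariance (for small problems / cross-checks only)."""
        return np.kron(self.corr_t, self.cov_s)

    def precision_banded_lower(self) -> np.ndarray:
        """Precision in LAPACK lower-banded storage, bandwidth 2n - 1.

        Row k of the returned (2n, nT) array holds the k-th sub-diagonal.
        Occasion-major stacking makes the precision block-tridiagonal with
        dense n x n blocks, so the band is narrow and a banded Cholesky is
        cheap even for thousands of cells.
        """
        n, T = self.n, self.T
        nt = n * T
        bw = 2 * n - 1
        ab = np.zeros((bw + 1, nt))
        diag_t = np.diag(self.prec_t)
        off_t = self.prec_t[np.arange(T - 1), np.arange(1, T)] if T > 1 else None
        for j in range(n):
            # diagonal blocks: rows 0..n-j-1 of every occasion's column j
            ab[0 : n - j, j::n] = self.prec_s[j:, j][:, None] * diag_t[None, :]
            if T > 1:
                # sub-diagonal blocks coupling occasions t and t+1
                ab[n - j : 2 * n - j, j : (T - 1) * n : n] = (
                    self.prec_s[:, j][:, None] * off_t[None, :]
                )
        return ab

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        """Exact draw(s) from the prior, returned as (size,) nT vectors."""
        if size is None:
            z = rng.standard_normal((self.n, self.T))
            xm = self._chol_s @ z @ self._chol_t.T
            return xm.T.ravel()
        return np.stack([self.sample(rng) for _ in range(size)])


def joint_prior(
    hyper: Hyperparameters, distances: np.ndarray, n_occasions: int
) -> SpaceTimePrior:
    """Joint Gaussian prior over the stacked latent field (see SpaceTimePrior)."""
    return SpaceTimePrior(hyper, distances, n_occasions)


def sample_field(
    hyper: Hyperparameters,
    distances: np.ndarray,
    n_occasions: int,
    seed: int | np.random.Generator,
) -> LatentField:
    """Draw one latent field realisation; reproducible given the seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prior = SpaceTimePrior(hyper, distances, n_occasions)
    x = prior.sample(rng)
    return LatentField(xi=x.reshape(prior.T, prior.n).T.copy())
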