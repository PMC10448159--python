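"""Fitting the three-step regression chain and the two mean predictors.

The chain estimator is the paper-of-record's central algebraic device in
this class of methods: regressing predictions on the next covariate set is
identical to composing the coefficient estimates,

    alpha_hat = A*_hat beta_hat,    gamma_hat = Gamma*_hat A*_hat beta_hat,

because the multivariate fits share the design with the univariate
proxy-response fits.  ``fit_chain`` computes the composed form; tests
verify the sequential-regression form agrees to machine precision.

Two population-mean predictors are provided: the model-based predictor
(final-phase covariates known wall-to-wall) evaluates p_bar_U gamma_hat;
the hybrid predictor replaces p_bar_U by its Horvitz-Thompson estimate
from a probability sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .datagen import FixedDesigns, HierarchicalDatasets

__all__ = [
    "OLSFit",
    "FittedChain",
    "DesignSample",
    "fit_ols",
    "gram_inverse",
    "fit_chain",
    "predict_3phmb",
    "draw_srswor",
    "ht_mean",
    "predict_3phhy",
]


@dataclass(frozen=True)
class OLSFit:
    """Coefficients, residual (co)variance and inverse Gram matrix of one fit.

    ``resid_cov`` uses the degrees-of-freedom divisor n - p (a scalar for a
    univariate response, an (m, m) matrix for a multivariate one).
    """

    coef: np.ndarray
    resid_cov: np.ndarray | float
    gram_inv: np.ndarray
    n_obs: int
    n_params: int


def _qr(design: np.ndarray, name: str):
    design = np.asarray(design, dtype=float)
    n, p = design.shape
    if n <= p:
        raise ValueError(f"{name}: need more observations ({n}) than parameters ({p})")
    Q, R = np.linalg.qr(design)
    diag = np.abs(np.diag(R))
    if np.min(diag) <= n * np.finfo(float).eps * np.max(diag):
        raise ValueError(
            f"{name}: design matrix is rank deficient (singular Gram matrix); "
            "check for constant or collinear covariate columns"
        )
    return Q, R, n, p


def gram_inverse(design: np.ndarray, name: str = "design") -> np.ndarray:
    """(D'D)^-1 computed from a QR decomposition of the design."""
    _, R, _, p = _qr(design, name)
    r_inv = scipy.linalg.solve_triangular(R, np.eye(p))
    return r_inv @ r_inv.T


def fit_ols(design: np.ndarray, response: np.ndarray, name: str = "dataset") -> OLSFit:
    """Ordinary least squares via QR, with the bookkeeping the variance formulas need.

    Accepts a univariate (n,) or multivariate (n, m) response.  Rank
    deficiency raises (naming the offending dataset) rather than silently
    pseudo-inverting, since a pseudo-inverse would corrupt the inverse
    Gram matrices entering the variance formulas.
    """
    Q, R, n, p = _qr(design, name)
    response = np.asarray(response, dtype=float)
    univariate = response.ndim == 1
    Y = response[:, None] if univariate else response
    if Y.shape[0] != n:
        raise ValueError(f"{name}: response has {Y.shape[0]} rows, design has {n}")
    coef = scipy.linalg.solve_triangular(R, Q.T @ Y)
    resid = Y - np.asarray(design, dtype=float) @ coef
    resid_cov = resid.T @ resid / (n - p)
    r_inv = scipy.linalg.solve_triangular(R, np.eye(p))
    gram_inv = r_inv @ r_inv.T
    if univariate:
        return OLSFit(coef[:, 0], float(resid_cov[0, 0]), gram_inv, n, p)
    return OLSFit(coef, resid_cov, gram_inv, n, p)


@dataclass(frozen=True)
class FittedChain:
    """Estimated chain parameters with residual (co)variances and Gram inverses."""

    beta_hat: np.ndarray
    omega2_hat: float
    A_star_hat: np.ndarray
    Delta_star_hat: np.ndarray
    alpha_hat: np.ndarray
    Gamma_star_hat: np.ndarray
    Theta_star_hat: np.ndarray
    gamma_hat: np.ndarray
    xtx_inv_I: np.ndarray
    ztz_inv_II: np.ndarray
    ptp_inv_III: np.ndarray
    n_I: int
    n_II: int
    n_III: int

    @property
    def delta2_hat(self) -> float:
        """Plug-in estimate beta_hat' Delta*_hat beta_hat."""
        return float(self.beta_hat @ self.Delta_star_hat @ self.beta_hat)

    @property
    def theta2_hat(self) -> float:
        """Plug-in estimate alpha_hat' Theta*_hat alpha_hat."""
        return float(self.alpha_hat @ self.Theta_star_hat @ self.alpha_hat)


def fit_chain(data: HierarchicalDatasets, designs: FixedDesigns) -> FittedChain:
    """Fit F on S_I, the multivariate G* on S_II and Q* on S_III, then compose.

    alpha_hat and gamma_hat are formed by the composition identities;
    regressing the chained predictions sequentially gives the same values
    (the equivalence is exercised in the test suite as the module's main
    oracle).
    """
    f = fit_ols(designs.X_I, data.y_I, name="S_I (field data)")
    g = fit_ols(designs.Z_II, data.X_II, name="S_II (intermediate RS data)")
    q = fit_ols(designs.P_III, data.Z_III, name="S_III (final-phase RS data)")
    alpha_hat = g.coef @ f.coef
    gamma_hat = q.coef @ alpha_hat
    return FittedChain(
        beta_hat=f.coef,
        omega2_hat=f.resid_cov,
        A_star_hat=g.coef,
        Delta_star_hat=g.resid_cov,
        alpha_hat=alpha_hat,
        Gamma_star_hat=q.coef,
        Theta_star_hat=q.resid_cov,
        gamma_hat=gamma_hat,
        xtx_inv_I=f.gram_inv,
        ztz_inv_II=g.gram_inv,
        ptp_inv_III=q.gram_inv,
        n_I=f.n_obs,
        n_II=g.n_obs,
        n_III=q.n_obs,
    )


def predict_3phmb(chain: FittedChain, p_bar_U: np.ndarray) -> float:
    """Model-based population-mean prediction p_bar_U gamma_hat."""
    p_bar_U = np.asarray(p_bar_U, dtype=float)
    if p_bar_U.shape != chain.gamma_hat.shape:
        raise ValueError("p_bar_U and gamma_hat dimensions do not match")
    if p_bar_U[0] != 1.0:
        raise ValueError("first element of p_bar_U must be 1 (intercept)")
    return float(p_bar_U @ chain.gamma_hat)


@dataclass(frozen=True)
class DesignSample:
    """A probability sample of population indices with inclusion probabilities.

    ``inclusion_prob`` may be a scalar (equal-probability designs such as
    SRSWOR, where it equals n_IV / N) or a per-element array aligned with
    ``indices``; only SRSWOR is exercised end-to-end.
    """

    indices: np.ndarray
    inclusion_prob: float | np.ndarray
    seed: object

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices)
        object.__setattr__(self, "indices", idx)
        if idx.size == 0:
            raise ValueError("empty sample")
        if idx.size != np.unique(idx).size:
            raise ValueError("sample indices must be distinct")
        pi = np.asarray(self.inclusion_prob, dtype=float)
        if np.any(pi <= 0) or np.any(pi > 1):
            raise ValueError("inclusion probabilities must be in (0, 1]")


def draw_srswor(N: int, n_IV: int, seed) -> DesignSample:
    """Simple random sample without replacement of n_IV out of N indices."""
    if n_IV > N:
        raise ValueError(f"sample size n_IV ({n_IV}) exceeds population size N ({N})")
    rng = np.random.default_rng(seed)
    idx = rng.choice(N, size=n_IV, replace=False)
    return DesignSample(indices=idx, inclusion_prob=n_IV / N, seed=seed)


def ht_mean(P_U: np.ndarray, sample: DesignSample) -> np.ndarray:
    """Horvitz-Thompson estimator of the population covariate mean row.

    (1/N) sum_{k in S_IV} p_k / pi_k; under SRSWOR this is the plain
    sample mean of the sampled rows.
    """
    P_U = np.asarray(P_U, dtype=float)
    rows = P_U[sample.indices]
    pi = np.broadcast_to(np.asarray(sample.inclusion_prob, dtype=float), (rows.shape[0],))
    return (rows / pi[:, None]).sum(axis=0) / P_U.shape[0]


def predict_3phhy(chain: FittedChain, P_U: np.ndarray, sample: DesignSample) -> float:
    """Hybrid population-mean prediction: HT mean of p times gamma_hat."""
    P_U = np.asarray(P_U, dtype=float)
    if P_U.shape[1] != chain.gamma_hat.shape[0]:
        raise ValueError("P_U and gamma_hat dimensions do not match")
    return float(ht_mean(P_U, sample) @ chain.gamma_hat)
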