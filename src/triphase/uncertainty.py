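"""Analytic variances, plug-in estimators and MSEs for the chained predictors.

The covariance of the composed coefficient estimate gamma_hat =
Gamma*_hat A*_hat beta_hat is decomposed with the law of total covariance.
Writing G_X, G_Z, G_P for the inverse Gram matrices of the three fits, the
exact decomposition (all estimates independent across datasets) is

    Cov_G(alpha_hat) = delta^2 G_Z + A* Cov_F(beta_hat) A*'
                       + Tr(Delta* Cov_F(beta_hat)) G_Z
    Cov(gamma_hat)   = theta^2 G_P + Gamma* Cov_G(alpha_hat) Gamma*'
                       + Tr(Theta* Cov_G(alpha_hat)) G_P

with Cov_F(beta_hat) = omega^2 G_X, delta^2 = beta' Delta* beta and
theta^2 = alpha' Theta* alpha.  The two Tr(.)-weighted matrices are the
"trace terms"; the remaining three sources (final-phase fit, intermediate
fit, field fit) are the main terms.  The quadratic-form contraction
v' Cov(M_hat) v for a multivariate fit collapses through the Kronecker
structure of Cov(vec(M_hat)) = ErrorCov (x) GramInv to
(v' ErrorCov v) * GramInv, which avoids materializing any Kronecker
product.

The model-based predictor variance is p_bar_U Cov(gamma_hat) p_bar_U'.
The hybrid predictor adds a design term: under SRSWOR,
(1/n_IV)(1 - n_IV/N) gamma' Cov(P_U) gamma, plus its own (negligible)
design-model trace Tr[Cov_D Cov(gamma_hat)].

Two trace accountings coexist and are both reported.  The *top-level*
trace of each predictor's own total-covariance decomposition (the
gamma-level trace for the model-based predictor, the design-model trace
for the hybrid one) is the headline "trace contribution"; the inner,
alpha-level trace is a component of Cov_G(alpha_hat) and hence of the
intermediate-model term.  The full-vs-approximate identity
(five-term total minus three-term approximation equals the sum of all
trace terms) holds exactly by construction and is asserted in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import FittedChain, gram_inverse
from .datagen import FixedDesigns
from .superpop import DerivedModelParams

__all__ = [
    "CovGammaParts",
    "VarianceReport",
    "cov_coeff_blocks",
    "cov_gamma_hat",
    "cov_gamma_from_params",
    "cov_gamma_from_chain",
    "variance_3phmb",
    "variance_3phhy",
    "estimate_variance",
    "mse_under_independence",
]


def _check_psd(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if not np.allclose(M, M.T, rtol=1e-10, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(M)
    if w.min() < -1e-10 * max(1.0, abs(w.max())):
        raise ValueError(f"{name} must be positive semi-definite")
    return M


def cov_coeff_blocks(gram_inv: np.ndarray, error_cov, v: np.ndarray | None = None) -> np.ndarray:
    """OLS coefficient covariance block.

    With a scalar error variance s2, returns s2 * gram_inv (the familiar
    Cov(beta_hat) = omega^2 (X'X)^-1).  With a matrix error covariance and
    a contraction vector v, returns the covariance of M_hat v, i.e.
    (v' error_cov v) * gram_inv.
    """
    gram_inv = _check_psd(gram_inv, "gram_inv")
    if np.isscalar(error_cov) or np.ndim(error_cov) == 0:
        s2 = float(error_cov)
        if s2 < 0:
            raise ValueError("error variance must be non-negative")
        return s2 * gram_inv
    error_cov = _check_psd(error_cov, "error_cov")
    if v is None:
        raise ValueError("a contraction vector v is required with a matrix error covariance")
    v = np.asarray(v, dtype=float)
    return float(v @ error_cov @ v) * gram_inv


@dataclass(frozen=True)
class CovGammaParts:
    """Term-by-term decomposition of Cov(gamma_hat), all (t+1, t+1) matrices."""

    term_Q: np.ndarray            # theta^2 G_P                      (final-phase fit)
    term_G: np.ndarray            # Gamma* (delta^2 G_Z) Gamma*'     (intermediate fit)
    term_F: np.ndarray            # Gamma* A* CovF A*' Gamma*'       (field fit)
    trace_alpha_level: np.ndarray  # Gamma* [Tr(Delta* CovF) G_Z] Gamma*'
    trace_gamma_level: np.ndarray  # Tr(Theta* Cov_G(alpha_hat)) G_P
    cov_F_beta: np.ndarray        # omega^2 G_X
    cov_alpha: np.ndarray         # full Cov_G(alpha_hat), traces included

    def total(self, include_traces: bool = True) -> np.ndarray:
        t = self.term_Q + self.term_G + self.term_F
        if include_traces:
            t = t + self.trace_alpha_level + self.trace_gamma_level
        return t


def cov_gamma_hat(
    beta: np.ndarray,
    A_star: np.ndarray,
    Gamma_star: np.ndarray,
    omega2: float,
    Delta_star: np.ndarray,
    Theta_star: np.ndarray,
    xtx_inv: np.ndarray,
    ztz_inv: np.ndarray,
    ptp_inv: np.ndarray,
) -> CovGammaParts:
    """Exact decomposition of Cov(gamma_hat) from chain parameters and Gram inverses.

    Pass true parameters for the analytic variance, or the fitted chain's
    estimates for the plug-in variance estimator (see
    :func:`cov_gamma_from_params` / :func:`cov_gamma_from_chain`).
    """
    beta = np.asarray(beta, dtype=float)
    A_star = np.asarray(A_star, dtype=float)
    Gamma_star = np.asarray(Gamma_star, dtype=float)
    Delta_star = np.asarray(Delta_star, dtype=float)
    Theta_star = np.asarray(Theta_star, dtype=float)
    alpha = A_star @ beta

    cov_F = cov_coeff_blocks(xtx_inv, omega2)
    delta2 = float(beta @ Delta_star @ beta)
    theta2 = float(alpha @ Theta_star @ alpha)

    cov_alpha_main = cov_coeff_blocks(ztz_inv, Delta_star, beta)  # delta^2 G_Z
    cov_alpha_field = A_star @ cov_F @ A_star.T
    cov_alpha_trace = float(np.trace(Delta_star @ cov_F)) * ztz_inv
    cov_alpha = cov_alpha_main + cov_alpha_field + cov_alpha_trace

    term_Q = cov_coeff_blocks(ptp_inv, Theta_star, alpha)  # theta^2 G_P
    term_G = Gamma_star @ cov_alpha_main @ Gamma_star.T
    term_F = Gamma_star @ cov_alpha_field @ Gamma_star.T
    trace_alpha_level = Gamma_star @ cov_alpha_trace @ Gamma_star.T
    trace_gamma_level = float(np.trace(Theta_star @ cov_alpha)) * ptp_inv

    return CovGammaParts(
        term_Q=term_Q,
        term_G=term_G,
        term_F=term_F,
        trace_alpha_level=trace_alpha_level,
        trace_gamma_level=trace_gamma_level,
        cov_F_beta=cov_F,
        cov_alpha=cov_alpha,
    )


def cov_gamma_from_params(
    params: DerivedModelParams, designs: FixedDesigns
) -> CovGammaParts:
    """Analytic Cov(gamma_hat) with true parameters, conditional on realized designs."""
    return cov_gamma_hat(
        params.beta,
        params.A_star,
        params.Gamma_star,
        params.omega2,
        params.Delta_star,
        params.Theta_star,
        gram_inverse(designs.X_I, "S_I (field data)"),
        gram_inverse(designs.Z_II, "S_II (intermediate RS data)"),
        gram_inverse(designs.P_III, "S_III (final-phase RS data)"),
    )


def cov_gamma_from_chain(chain: FittedChain) -> CovGammaParts:
    """Plug-in Cov(gamma_hat): every unknown replaced by its estimate."""
    return cov_gamma_hat(
        chain.beta_hat,
        chain.A_star_hat,
        chain.Gamma_star_hat,
        chain.omega2_hat,
        chain.Delta_star_hat,
        chain.Theta_star_hat,
        chain.xtx_inv_I,
        chain.ztz_inv_II,
        chain.ptp_inv_III,
    )


@dataclass(frozen=True)
class VarianceReport:
    """Predictor variance with its per-term decomposition (all scalars).

    ``total`` equals the sum of the listed terms: the three main model
    terms, the design term (hybrid mode only) and — when
    ``includes_traces`` — all trace terms.  ``top_level_trace`` is the
    trace of the predictor's own total-covariance decomposition, the
    quantity whose negligibility licenses the three-term approximation.
    """

    mode: str  # "3phmb" | "3phhy"
    total: float
    term_Q: float
    term_G: float
    term_F: float
    trace_alpha_level: float
    trace_gamma_level: float
    design_term: float = 0.0
    trace_design: float = 0.0
    includes_traces: bool = True

    @property
    def trace_terms(self) -> float:
        """Sum of every trace contribution relevant to this mode."""
        t = self.trace_alpha_level + self.trace_gamma_level
        if self.mode == "3phhy":
            t += self.trace_design
        return t

    @property
    def top_level_trace(self) -> float:
        """Trace of the predictor's own top-level decomposition."""
        return self.trace_design if self.mode == "3phhy" else self.trace_gamma_level

    @property
    def model_terms(self) -> float:
        return self.term_Q + self.term_G + self.term_F

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "total": self.total,
            "term_Q": self.term_Q,
            "term_G": self.term_G,
            "term_F": self.term_F,
            "trace_alpha_level": self.trace_alpha_level,
            "trace_gamma_level": self.trace_gamma_level,
            "design_term": self.design_term,
            "trace_design": self.trace_design,
            "includes_traces": self.includes_traces,
            "trace_terms": self.trace_terms,
            "top_level_trace": self.top_level_trace,
        }


def _quad(v: np.ndarray, M: np.ndarray) -> float:
    return float(v @ M @ v)


def variance_3phmb(
    parts: CovGammaParts, p_bar_U: np.ndarray, include_traces: bool = True
) -> VarianceReport:
    """Model-based predictor variance p_bar_U Cov(gamma_hat) p_bar_U'.

    With ``include_traces`` False this is the three-term approximation;
    the difference from the full form is exactly the summed trace terms.
    """
    p = np.asarray(p_bar_U, dtype=float)
    tq, tg, tf = _quad(p, parts.term_Q), _quad(p, parts.term_G), _quad(p, parts.term_F)
    tra = _quad(p, parts.trace_alpha_level)
    trg = _quad(p, parts.trace_gamma_level)
    total = tq + tg + tf + ((tra + trg) if include_traces else 0.0)
    return VarianceReport(
        mode="3phmb",
        total=total,
        term_Q=tq,
        term_G=tg,
        term_F=tf,
        trace_alpha_level=tra,
        trace_gamma_level=trg,
        includes_traces=include_traces,
    )


def _finite_pop_cov(P: np.ndarray, ddof: int = 1) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.shape[0] < 2:
        raise ValueError("need at least two rows to form a covariance")
    return np.cov(P, rowvar=False, ddof=ddof)


def variance_3phhy(
    parts: CovGammaParts,
    gamma: np.ndarray,
    P_U: np.ndarray,
    n_IV: int,
    p_bar_U: np.ndarray | None = None,
    include_traces: bool = True,
) -> VarianceReport:
    """Hybrid predictor variance: SRSWOR design term plus the model term.

    design term = (1/n_IV)(1 - n_IV/N) gamma' Cov(P_U) gamma with Cov(P_U)
    the finite-population covariance (divisor N - 1); the model term is
    p_bar_U Cov(gamma_hat) p_bar_U'.  The design-model trace
    Tr[Cov_D Cov(gamma_hat)] is reported separately and included in the
    total only when ``include_traces``.
    """
    P_U = np.asarray(P_U, dtype=float)
    N = P_U.shape[0]
    if n_IV > N:
        raise ValueError(f"n_IV ({n_IV}) exceeds population size N ({N})")
    if N == 0:
        raise ValueError("empty population")
    gamma = np.asarray(gamma, dtype=float)
    if p_bar_U is None:
        p_bar_U = P_U.mean(axis=0)
    fpc = 1.0 - n_IV / N
    cov_D = (fpc / n_IV) * _finite_pop_cov(P_U)
    design_term = _quad(gamma, cov_D)
    model = variance_3phmb(parts, p_bar_U, include_traces=include_traces)
    trace_design = float(np.trace(cov_D @ parts.total(include_traces=True)))
    total = design_term + model.total + (trace_design if include_traces else 0.0)
    return VarianceReport(
        mode="3phhy",
        total=total,
        term_Q=model.term_Q,
        term_G=model.term_G,
        term_F=model.term_F,
        trace_alpha_level=model.trace_alpha_level,
        trace_gamma_level=model.trace_gamma_level,
        design_term=design_term,
        trace_design=trace_design,
        includes_traces=include_traces,
    )


def estimate_variance(
    chain: FittedChain,
    mode: str = "3phmb",
    *,
    p_bar_U: np.ndarray | None = None,
    p_sample: np.ndarray | None = None,
    N: int | None = None,
    include_traces: bool = True,
) -> VarianceReport:
    """Plug-in variance estimator: the analytic formulas at the fitted chain.

    For the model-based mode the known population mean row ``p_bar_U`` is
    required.  For the hybrid mode the final-phase covariates are known
    only on the probability sample: pass the sampled rows ``p_sample``
    (n_IV, t+1) and the population size ``N``; the design covariance is
    the SRSWOR sample covariance (divisor n_IV - 1) times the
    fpc-corrected factor, and the Horvitz-Thompson mean stands in for
    p_bar_U in the model term.
    """
    parts = cov_gamma_from_chain(chain)
    if mode == "3phmb":
        if p_bar_U is None:
            raise ValueError("p_bar_U is required for the model-based estimator")
        return variance_3phmb(parts, p_bar_U, include_traces=include_traces)
    if mode != "3phhy":
        raise ValueError(f"unknown mode {mode!r}")
    if p_sample is None or N is None:
        raise ValueError("p_sample and N are required for the hybrid estimator")
    p_sample = np.asarray(p_sample, dtype=float)
    n_IV = p_sample.shape[0]
    if n_IV > N:
        raise ValueError(f"sample size ({n_IV}) exceeds population size N ({N})")
    fpc = 1.0 - n_IV / N
    cov_D_hat = (fpc / n_IV) * _finite_pop_cov(p_sample)
    ht = p_sample.mean(axis=0)  # HT mean under SRSWOR
    model = variance_3phmb(parts, ht, include_traces=include_traces)
    design_term = _quad(chain.gamma_hat, cov_D_hat)
    trace_design = float(np.trace(cov_D_hat @ parts.total(include_traces=True)))
    total = design_term + model.total + (trace_design if include_traces else 0.0)
    return VarianceReport(
        mode="3phhy",
        total=total,
        term_Q=model.term_Q,
        term_G=model.term_G,
        term_F=model.term_F,
        trace_alpha_level=model.trace_alpha_level,
        trace_gamma_level=model.trace_gamma_level,
        design_term=design_term,
        trace_design=trace_design,
        includes_traces=include_traces,
    )


def mse_under_independence(variance: VarianceReport, params, N: int) -> float:
    """Predictor MSE assuming independent, non-autocorrelated error terms.

    MSE = variance.total + (theta^2 + delta^2 + omega^2) / N.  The add-on
    is the averaged model noise of the finite population itself.  The
    independence assumption is strong — spatially autocorrelated errors
    would change it — so every consumer of this number should carry the
    "independence assumed" caveat along (the CLI and reports do).
    ``params`` may be true parameters or a fitted chain (plug-in).
    """
    if N <= 0:
        raise ValueError("N must be positive")
    omega2 = getattr(params, "omega2", None)
    if omega2 is None:
        omega2, delta2, theta2 = params.omega2_hat, params.delta2_hat, params.theta2_hat
    else:
        delta2, theta2 = params.delta2, params.theta2
    return variance.total + (theta2 + delta2 + omega2) / N
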