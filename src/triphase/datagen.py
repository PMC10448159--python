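"""Synthetic data generation for the three-phase validation protocol.

The protocol conditions on *fixed* explanatory designs: the covariate
columns of all four datasets are drawn once from their marginal normal
distributions and held fixed, while the responses (the field response for
model F and the multivariate responses of G* and Q*) are regenerated from
the model chain with fresh noise for every Monte-Carlo iteration.
Covariate columns across datasets are drawn independently — the protocol
conditions on designs, so no cross-dataset coupling is imposed even though
the superpopulation is jointly normal.

Reproducibility: every entry point takes a seed (an int or a
``numpy.random.SeedSequence``).  Iteration-level sub-seeds are derived by
the documented counter scheme ``SeedSequence(master, spawn_key=(stream, i))``
so any single iteration can be replayed in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .superpop import SuperpopulationSpec, DerivedModelParams

__all__ = ["FixedDesigns", "HierarchicalDatasets", "generate_designs", "generate_responses"]


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class FixedDesigns:
    """The four fixed design matrices, each with a leading unit column."""

    X_I: np.ndarray    # (n_I, h+1) field covariates
    Z_II: np.ndarray   # (n_II, q+1) intermediate RS covariates
    P_III: np.ndarray  # (n_III, t+1) final-phase covariates, training sample
    P_U: np.ndarray    # (N, t+1) final-phase covariates over the whole AOI
    generating_moments: dict  # column name -> (mean, sd) used to draw it

    def __post_init__(self) -> None:
        for name in ("X_I", "Z_II", "P_III", "P_U"):
            m = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, m)
            if m.ndim != 2 or not np.all(m[:, 0] == 1.0):
                raise ValueError(f"{name} must be 2-D with a leading unit column")

    @property
    def p_bar_U(self) -> np.ndarray:
        """Population mean row of final-phase covariates (first entry 1)."""
        return self.P_U.mean(axis=0)


@dataclass(frozen=True)
class HierarchicalDatasets:
    """Per-iteration simulated responses on the fixed designs."""

    y_I: np.ndarray     # (n_I,) field response of model F
    X_II: np.ndarray    # (n_II, h+1) multivariate response of G* over Z_II
    Z_III: np.ndarray   # (n_III, q+1) multivariate response of Q* over P_III
    iteration_seed: object

    def __post_init__(self) -> None:
        for name in ("y_I", "X_II", "Z_III"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("X_II", "Z_III"):
            if not np.all(getattr(self, name)[:, 0] == 1.0):
                raise ValueError(f"unit column of {name} must be exactly one")


def generate_designs(spec: SuperpopulationSpec, seed) -> FixedDesigns:
    """Draw the fixed covariate designs once from their marginals.

    Independent N(mu, sd) draws per column; deterministic given the seed.
    A zero sd yields a constant column (allowed here; rejected at fit time
    as a singular design).
    """
    rng = _rng(seed)
    x = rng.normal(spec.mu_X, spec.sd_X, size=spec.n_I)
    z = rng.normal(spec.mu_Z, spec.sd_Z, size=spec.n_II)
    p3 = rng.normal(spec.mu_P, spec.sd_P, size=spec.n_III)
    pu = rng.normal(spec.mu_P, spec.sd_P, size=spec.N)

    def with_unit(col: np.ndarray) -> np.ndarray:
        return np.column_stack([np.ones(col.shape[0]), col])

    return FixedDesigns(
        X_I=with_unit(x),
        Z_II=with_unit(z),
        P_III=with_unit(p3),
        P_U=with_unit(pu),
        generating_moments={
            "x": (spec.mu_X, spec.sd_X),
            "z": (spec.mu_Z, spec.sd_Z),
            "p": (spec.mu_P, spec.sd_P),
        },
    )


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    """Square-root factor L with L L' = cov for a (possibly singular) PSD matrix."""
    w, v = np.linalg.eigh(np.asarray(cov, dtype=float))
    if np.min(w) < -1e-10 * max(1.0, np.max(np.abs(w))):
        raise ValueError("error covariance is not positive semi-definite")
    return v * np.sqrt(np.clip(w, 0.0, None))


def generate_responses(
    designs: FixedDesigns, params: DerivedModelParams, seed
) -> HierarchicalDatasets:
    """Simulate the hierarchical responses for one Monte-Carlo iteration.

    y_I = X_I beta + eps with eps ~ N(0, omega^2);
    X_II = Z_II A* + ups* with rows ~ N(0, Delta*);
    Z_III = P_III Gamma* + e* with rows ~ N(0, Theta*).

    Components whose error variance is exactly zero (in particular the
    unit columns of the multivariate responses) receive exactly zero
    noise, keeping the unit columns identically one.
    """
    if designs.X_I.shape[1] != params.beta.shape[0]:
        raise ValueError("X_I and beta dimensions do not match")
    if designs.Z_II.shape[1] != params.A_star.shape[0]:
        raise ValueError("Z_II and A_star dimensions do not match")
    if designs.P_III.shape[1] != params.Gamma_star.shape[0]:
        raise ValueError("P_III and Gamma_star dimensions do not match")

    rng = _rng(seed)
    y_I = designs.X_I @ params.beta + rng.normal(
        0.0, np.sqrt(params.omega2), size=designs.X_I.shape[0]
    )

    def multiresponse(design: np.ndarray, coef: np.ndarray, cov: np.ndarray) -> np.ndarray:
        mean = design @ coef
        L = _psd_factor(cov)
        noise = rng.standard_normal(mean.shape) @ L.T
        noise[:, np.diag(cov) == 0.0] = 0.0  # exact-zero components stay exact
        return mean + noise

    X_II = multiresponse(designs.Z_II, params.A_star, params.Delta_star)
    Z_III = multiresponse(designs.P_III, params.Gamma_star, params.Theta_star)
    return HierarchicalDatasets(y_I=y_I, X_II=X_II, Z_III=Z_III, iteration_seed=seed)
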