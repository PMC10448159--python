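"""Superpopulation model underlying the three-phase inference chain.

The data-generating world is a multivariate-normal superpopulation over four
variables per population element: the response Y (e.g. aboveground biomass
density, Mg/ha), a field covariate X (e.g. mean stem diameter), an
intermediate remote-sensing covariate Z (e.g. an airborne-laser height
metric) and a final-phase covariate P (e.g. a spaceborne sensor metric that
is available wall-to-wall or as a probability sample).  The dependence
structure is a correlation chain Y—X—Z—P: conditioning successively on X,
Z and P yields the linear model chain

    F : Y_i  = x_i beta  + eps_i,       eps_i  ~ N(0, omega^2)
    G*: X_i  = z_i A*    + ups*_i,      ups*_i ~ N(0, Delta*)
    G : X_i beta = z_i alpha + ups_i,   ups_i  ~ N(0, delta^2)
    Q*: Z_i  = p_i Gamma* + e*_i,       e*_i   ~ N(0, Theta*)
    Q : Z_i alpha = p_i gamma + e_i,    e_i    ~ N(0, theta^2)

with the algebraic identities alpha = A* beta, gamma = Gamma* alpha,
delta^2 = beta' Delta* beta and theta^2 = alpha' Theta* alpha.  Each
modeling step replaces the response by its conditional expectation given
the next covariate, which multiplies the response variance by the squared
chain correlation (see :func:`variance_reduction_factor`).

Only the chain correlations are part of the superpopulation description;
off-chain correlations are the Markov-chain products implied by the
conditional-expectation derivations (r_YZ = r_YX r_XZ, etc.), which makes
the joint distribution a conditional-independence chain.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import numpy as np

__all__ = [
    "SuperpopulationSpec",
    "DerivedModelParams",
    "derive_chain_params",
    "full_correlation_matrix",
    "variance_reduction_factor",
    "boreal_reference_spec",
]


@dataclass(frozen=True)
class SuperpopulationSpec:
    """Means, standard deviations, chain correlations and dataset sizes.

    The four dataset sizes are the field sample (n_I), the intermediate
    remote-sensing sample (n_II), the final-phase training sample (n_III)
    and the probability sample of final-phase covariates (n_IV, hybrid
    mode only); N is the number of grid cells tessellating the area of
    interest.  No ordering among the sizes is required.
    """

    mu_Y: float
    mu_X: float
    mu_Z: float
    mu_P: float
    sd_Y: float
    sd_X: float
    sd_Z: float
    sd_P: float
    r_YX: float
    r_XZ: float
    r_ZP: float
    n_I: int
    n_II: int
    n_III: int
    n_IV: int
    N: int

    # univariate covariate chain: each design has an intercept plus one slope
    _N_PARAMS = 2

    def __post_init__(self) -> None:
        for name in ("sd_Y", "sd_X", "sd_Z", "sd_P"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        for name in ("r_YX", "r_XZ", "r_ZP"):
            r = getattr(self, name)
            if not abs(r) < 1:
                raise ValueError(
                    f"|{name}| must be < 1 (degenerate conditional variance), got {r}"
                )
        for name in ("n_I", "n_II", "n_III"):
            n = getattr(self, name)
            if n < self._N_PARAMS + 1:
                raise ValueError(
                    f"{name} must be at least {self._N_PARAMS + 1} for a feasible fit, got {n}"
                )
        if self.n_IV < 1:
            raise ValueError(f"n_IV must be positive, got {self.n_IV}")
        if self.N < 1:
            raise ValueError(f"N must be positive, got {self.N}")
        if self.n_IV > self.N:
            raise ValueError(f"n_IV ({self.n_IV}) cannot exceed N ({self.N})")

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SuperpopulationSpec":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown superpopulation keys: {sorted(unknown)}")
        missing = known - set(d)
        if missing:
            raise ValueError(f"missing superpopulation keys: {sorted(missing)}")
        ints = {"n_I", "n_II", "n_III", "n_IV", "N"}
        coerced = {k: (int(v) if k in ints else float(v)) for k, v in d.items()}
        return cls(**coerced)


@dataclass(frozen=True)
class DerivedModelParams:
    """True coefficients and error (co)variances of the model chain.

    All arrays follow the row-vector convention of the model chain:
    ``A_star`` maps a (1, q+1) z-row to a (1, h+1) x-row, ``Gamma_star``
    maps a p-row to a z-row.  The unit component of the multivariate
    responses regresses perfectly, so the corresponding rows/columns of
    ``Delta_star`` and ``Theta_star`` are identically zero.
    """

    beta: np.ndarray          # (h+1,)
    omega2: float
    A_star: np.ndarray        # (q+1, h+1)
    Delta_star: np.ndarray    # (h+1, h+1)
    alpha: np.ndarray         # (q+1,)
    delta2: float
    Gamma_star: np.ndarray    # (t+1, q+1)
    Theta_star: np.ndarray    # (q+1, q+1)
    gamma: np.ndarray         # (t+1,)
    theta2: float

    def __post_init__(self) -> None:
        for name in ("beta", "alpha", "gamma"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("A_star", "Delta_star", "Gamma_star", "Theta_star"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if min(self.omega2, self.delta2, self.theta2) < 0:
            raise ValueError("error variances must be non-negative")


def derive_chain_params(spec: SuperpopulationSpec) -> DerivedModelParams:
    """Derive the true chain parameters implied by the superpopulation.

    Each step is the conditional expectation of the previous step's
    response given the next covariate, under joint normality:

    * F:  slope r_YX sd_Y/sd_X, residual variance sd_Y^2 (1 - r_YX^2);
    * G*: x-on-z slope r_XZ sd_X/sd_Z, residual sd_X^2 (1 - r_XZ^2);
    * Q*: z-on-p slope r_ZP sd_Z/sd_P, residual sd_Z^2 (1 - r_ZP^2);

    with the contractions alpha = A* beta, gamma = Gamma* alpha,
    delta^2 = beta' Delta* beta = sd_Y^2 r_YX^2 (1 - r_XZ^2) and
    theta^2 = alpha' Theta* alpha = sd_Y^2 r_YX^2 r_XZ^2 (1 - r_ZP^2).
    """
    for name in ("sd_Y", "sd_X", "sd_Z", "sd_P"):
        if getattr(spec, name) <= 0:
            raise ValueError(f"{name} must be strictly positive to derive chain parameters")

    b1 = spec.r_YX * spec.sd_Y / spec.sd_X
    b0 = spec.mu_Y - b1 * spec.mu_X
    beta = np.array([b0, b1])
    omega2 = spec.sd_Y**2 * (1.0 - spec.r_YX**2)

    a1 = spec.r_XZ * spec.sd_X / spec.sd_Z
    a0 = spec.mu_X - a1 * spec.mu_Z
    # rows indexed by z components (unit, z); columns by x components (unit, x)
    A_star = np.array([[1.0, a0], [0.0, a1]])
    Delta_star = np.diag([0.0, spec.sd_X**2 * (1.0 - spec.r_XZ**2)])
    alpha = A_star @ beta
    delta2 = float(beta @ Delta_star @ beta)

    g1 = spec.r_ZP * spec.sd_Z / spec.sd_P
    g0 = spec.mu_Z - g1 * spec.mu_P
    Gamma_star = np.array([[1.0, g0], [0.0, g1]])
    Theta_star = np.diag([0.0, spec.sd_Z**2 * (1.0 - spec.r_ZP**2)])
    gamma = Gamma_star @ alpha
    theta2 = float(alpha @ Theta_star @ alpha)

    return DerivedModelParams(
        beta=beta,
        omega2=omega2,
        A_star=A_star,
        Delta_star=Delta_star,
        alpha=alpha,
        delta2=delta2,
        Gamma_star=Gamma_star,
        Theta_star=Theta_star,
        gamma=gamma,
        theta2=theta2,
    )


def full_correlation_matrix(spec: SuperpopulationSpec) -> np.ndarray:
    """Correlation matrix of (Y, X, Z, P) under the chained superpopulation.

    On-chain entries are the spec's correlations; off-chain entries are the
    Markov products r_YZ = r_YX r_XZ, r_YP = r_YX r_XZ r_ZP and
    r_XP = r_XZ r_ZP.  Raises if the resulting matrix is not positive
    definite (cannot happen for |r| < 1, but guards pathological input).
    """
    ryx, rxz, rzp = spec.r_YX, spec.r_XZ, spec.r_ZP
    R = np.array(
        [
            [1.0, ryx, ryx * rxz, ryx * rxz * rzp],
            [ryx, 1.0, rxz, rxz * rzp],
            [ryx * rxz, rxz, 1.0, rzp],
            [ryx * rxz * rzp, rxz * rzp, rzp, 1.0],
        ]
    )
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("implied correlation matrix is not positive definite") from exc
    return R


def variance_reduction_factor(correlations) -> float:
    """Product of squared chain correlations.

    After k modeling steps the proxy response carries only this fraction of
    the original response variance: one step with r = 0.8 leaves 0.64 of
    sigma_Y^2, two steps with r = 0.9 each leave 0.6561, and so on.  This
    is the factor by which mapped variability shrinks when predictions are
    chained, and the reason weakly correlated chains should be treated
    with caution.
    """
    rs = np.asarray(correlations, dtype=float)
    if rs.ndim != 1:
        raise ValueError("correlations must be a flat sequence")
    if np.any(np.abs(rs) > 1):
        raise ValueError("each |correlation| must be <= 1")
    return float(np.prod(rs**2))


def boreal_reference_spec() -> SuperpopulationSpec:
    """Reference configuration mimicking boreal forest conditions.

    Y is field-measured aboveground biomass density (Mg/ha), X mean stem
    diameter (cm), Z an airborne-laser canopy-height metric and P a
    spaceborne-LiDAR height metric, with magnitudes typical of northern
    Finland.  Used as the package's default worked example and as the
    Monte-Carlo validation world.
    """
    return SuperpopulationSpec(
        mu_Y=62.62, mu_X=10.94, mu_Z=7.16, mu_P=8.28,
        sd_Y=49.53, sd_X=6.30, sd_Z=4.34, sd_P=5.69,
        r_YX=0.77, r_XZ=0.75, r_ZP=0.76,
        n_I=102, n_II=943, n_III=1721, n_IV=5760, N=38_400,
    )
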