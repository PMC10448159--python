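# Methods

## Model and assumptions

The package implements population-mean prediction through three nested
linear models.  The statistical model is a multivariate-normal
superpopulation over (Y, X, Z, P) per population element, with a
correlation *chain* Y—X—Z—P: the only free correlations are r_YX, r_XZ,
r_ZP, and off-chain correlations are their products (r_YZ = r_YX r_XZ,
r_YP = r_YX r_XZ r_ZP, r_XP = r_XZ r_ZP).  This conditional-independence
structure is an assumption, not a theorem: it is exactly the joint
distribution under which the stepwise conditional expectations produce the
model chain F, G*, G, Q*, Q with the stated coefficients, and
`full_correlation_matrix` documents it explicitly.  Chain derivation
(`derive_chain_params`):

* F: slope r_YX σ_Y/σ_X, residual variance ω² = σ_Y²(1 − r_YX²);
* G*: x-on-z slope r_XZ σ_X/σ_Z, residual Δ* = diag(0, σ_X²(1 − r_XZ²));
* Q*: z-on-p slope r_ZP σ_Z/σ_P, residual Θ* = diag(0, σ_Z²(1 − r_ZP²));
* contractions α = A*β, γ = Γ*α, δ² = β′Δ*β = σ_Y² r_YX²(1 − r_XZ²),
  θ² = α′Θ*α = σ_Y² r_YX² r_XZ²(1 − r_ZP²).

The unit component of the multivariate responses regresses perfectly, so
the corresponding rows/columns of Δ* and Θ* are identically zero; the data
generator preserves this exactly (unit columns are never perturbed).

All types are dimensioned for h, q, t ≥ 1 covariates, but the validated
configuration is univariate (one covariate per phase), which is also what
the superpopulation specification can express.

## Estimation

All fits are ordinary least squares via QR decomposition
(`numpy.linalg.qr` + triangular solves); the inverse Gram matrices needed
by the variance formulas are formed from R⁻¹.  Rank deficiency is a hard
error naming the offending dataset — silent pseudo-inversion would corrupt
the variance formulas.  Residual (co)variances use the
degrees-of-freedom divisor n − p uniformly (ω̂², Δ̂*, Θ̂*); this choice is
what makes the plug-in variance estimator's near-unbiasedness achievable
(observed relative bias <0.5% at 10⁴ replications).

The chained estimates are composed (γ̂ = Γ̂* Â* β̂) rather than obtained by
re-regressing predictions; the two routes are algebraically identical and
the test suite verifies their agreement to 1e−10 relative tolerance as the
module's main oracle.

## Variance decomposition

The exact law-of-total-covariance decomposition is

    Cov_G(α̂) = δ² G_Z + A* Cov_F(β̂) A*′ + Tr(Δ* Cov_F(β̂)) G_Z
    Cov(γ̂)   = θ² G_P + Γ* Cov_G(α̂) Γ*′ + Tr(Θ* Cov_G(α̂)) G_P

with G_X = (X′X)⁻¹ etc. and Cov_F(β̂) = ω² G_X.  The trace coefficients
follow from the Kronecker structure of a multivariate OLS coefficient
covariance, Cov(vec M̂) = ErrorCov ⊗ GramInv, which also gives the
contraction identity v′Cov(M̂)v = (v′ ErrorCov v) · GramInv used throughout
(`cov_coeff_blocks`); no Kronecker product is ever materialized.  The
decomposition (including both trace terms) matches the brute-force
empirical covariance of γ̂ over 10⁵ independent refits within Monte-Carlo
error (tested).

Two trace accountings are reported side by side:

* **top-level trace** — the trace term of the *predictor's own* total-
  covariance decomposition: Tr(Θ* Cov_G(α̂)) G_P contracted with p̄_U for
  the model-based predictor, and Tr[Cov_D Cov(γ̂)] for the hybrid one.
  This is the headline "trace contribution" figure.  The α-level trace is,
  under this accounting, a component of Cov_G(α̂) and hence of the
  intermediate-model term.
* **all traces** — the sum of every Tr(·) contribution, which is exactly
  the difference between the five-term total and the three-term
  approximation (`include_traces=False`); this identity is asserted at
  machine precision.

Both are far below 0.1% of the total in the reference world, so the
three-term approximation is safe there.

The hybrid variance adds, under SRSWOR, the design term
(1/n_IV)(1 − n_IV/N) γ′Cov(P_U)γ with the finite-population covariance
using divisor N − 1; the design-based *estimator* uses the sample
covariance (divisor n_IV − 1) with the same fpc factor, and substitutes
the Horvitz–Thompson mean for the unknown p̄_U in the model term — forced
by the hybrid setting, where P is known only on the sample.  General
unequal-probability designs are represented (per-element π in
`DesignSample`) but only SRSWOR is exercised end to end.

The MSE adds (θ² + δ² + ω²)/N to the variance **under an explicit
assumption of independent, non-spatially-autocorrelated error terms**;
every MSE output carries this caveat, and spatially autocorrelated MSEs
are out of scope.

## Synthetic data and the validation protocol

`generate_designs` draws each covariate column once, independently, from
its marginal normal; designs are then *fixed* and only responses are
regenerated per Monte-Carlo iteration (`generate_responses`).  This
mirrors the validation protocol of conditioning on designs and means the
generator does **not** emulate: joint sampling of (x, z, p) per element,
non-normal or heteroscedastic errors, spatial autocorrelation, or
measurement error in covariates.  Passing tests therefore validate the
variance algebra and estimators *conditional on fixed designs*, not
robustness to those real-data features.

The reference world (`boreal_reference_spec`) mimics boreal-forest
conditions in northern Finland: AGBD mean 62.62 Mg/ha (sd 49.53), field
covariate 10.94 (6.30), intermediate RS covariate 7.16 (4.34), final-phase
covariate 8.28 (5.69), chain correlations 0.77/0.75/0.76, dataset sizes
n_I = 102, n_II = 943, n_III = 1721, n_IV = 5760, N = 38 400.  No ordering
among the sizes is required by the method.

RNG discipline: one master seed; sub-seeds by the counter scheme
`SeedSequence(master, spawn_key=(stream, i))` with stream 0 = designs
(drawn once), stream 1 = per-iteration responses, stream 2 = per-iteration
SRSWOR draws.  The SRSWOR sample is redrawn every iteration.  Any
iteration is replayable in isolation from its spawn key, which the
harness reports on failure.

The harness default is 10⁴ replications — enough to resolve the ~1%
questions at stake here, since every summary carries a Monte-Carlo
standard error and all comparisons are z-tests; a full-fidelity 10⁶ run
is available via `triphase validate --full`.  At 10⁴ replications the
reference world runs in well under a minute; memory is O(1) in the
replication count (running sums only, per-iteration dumps opt-in).

## Numerical and design choices

* Analytic (Step-1c style) variances are conditional on the realized
  designs; across master seeds they move by ~±1.5% (the dominant wobble is
  the realized field-sample Gram matrix).  Reports echo the realized p̄_U
  so the conditioning is explicit.
* The population final-phase covariates P_U and the training sample's
  P_III are independent draws (they are distinct datasets in the
  protocol); they share only the marginal distribution.
* Singular-PSD error covariances (the zero unit rows of Δ*, Θ*) are
  factored by symmetric eigendecomposition with negative eigenvalues
  clipped at −1e−10 relative; exactly-zero-variance components receive
  exactly zero noise.
* Zero-sd covariates are allowed in the generator (degenerate constant
  columns) and rejected at fit time as rank deficiency.
* A superpopulation cannot express an exactly noise-free world (|r| < 1
  strictly); zero-noise behavior is exercised by constructing chain
  parameters directly.
* Config files are flat YAML; datasets are header-row CSV with unit
  columns omitted on disk.  Dataset schemas: `s_i: y,x`, `s_ii: x,z`,
  `s_iii: z,p`, `p_u: p` (+ optional population size `N` in the io block
  for hybrid runs where `p_u` holds only the sample).

## Known limitations

* Univariate covariates per phase are the validated path; multivariate
  (h, q, t > 1) inputs flow through the algebra but have no dedicated
  superpopulation derivation or tests.
* MSE formulas assume independent errors; with spatial autocorrelation
  they understate the truth to an unquantified degree.
* Only SRSWOR is implemented end to end for the hybrid design stage.
* The variance-reduction analysis implies mapped predictions understate
  landscape variability by the product of squared chain correlations;
  calibration approaches to restore it are not implemented.
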