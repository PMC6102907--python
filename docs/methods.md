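# Methods

## Model

`kmrmix` estimates the joint effect of M concurrent exposures on a health
outcome with the kernel machine regression model

    y_i = h(z_i1, ..., z_iM) + x_i' beta + eps_i,        eps_i ~ N(0, sigma^2)

for a continuous outcome, and its probit analogue for a binary outcome,

    P(Y_i = 1) = Phi( h(z_i) + x_i' beta ),

expressed through a latent normal response Y_i* = h(z_i) + x_i'beta + e_i,
e_i ~ N(0, 1), with Y_i = 1{Y_i* > 0}. The exposure-response surface h is
unknown and may be nonlinear and non-additive; a parametric alternative
that expands each exposure in a DF-degree-of-freedom basis and includes all
interactions needs (1 + DF)^M − 1 coefficients (255 at M = 4, DF = 3),
which motivates regularizing h instead of enumerating bases.

h receives a Gaussian-process prior induced by the component-weighted
Gaussian kernel

    K(z, z') = exp{ − Σ_m r_m (z_m − z'_m)^2 },       r_m ≥ 0,

with variance tau^2 = lam * sigma^2. Observations with similar exposure
profiles therefore have correlated surface values. The weight r_m controls
both smoothness in exposure m and its inclusion: r_m = 0 removes exposure m
from the surface entirely. Distances use the unscaled sum convention (no
division by M), on exposures standardized internally to mean 0, sd 1
(disable with `standardize=False`; all output is reported on the original
exposure scale through the stored centers and scales).

### Variable selection

Each r_m carries a spike-and-slab prior: a point mass at 0 with probability
1 − pi, and a slab density given inclusion (indicator delta_m). The
posterior frequency of delta_m = 1 is the posterior inclusion probability
(PIP). Hierarchical (grouped) selection assigns probability 1 − pi to
"group off" and pi × (1/|g|) × slab(r_m) to "on with member m active":
within an active group exactly one member is selected, reflecting groups
built from highly correlated pollutants that act as near-exchangeable
proxies; reported output is the group PIP and conditional within-group PIPs
(which sum to 1 in a group).

### Clustered outcomes

A cluster random intercept b_i ~ N(0, tau_b^2) is handled by
marginalization: it contributes a block term tau_b^2 * G G' to the outcome
covariance (G the cluster indicator matrix), so no per-cluster parameters
are sampled in the main loop. Explicit intercept draws are available on
demand for diagnostics (`draw_random_intercepts`).

## Posterior computation

With h integrated out analytically the marginal covariance is

    Sigma = sigma^2 ( I + lam * K_r + lam_b * G G' ),

where lam = tau^2/sigma^2 and lam_b = tau_b^2/sigma^2 are variance ratios.
The sampler is a hybrid Gibbs / Metropolis-Hastings scheme; per iteration:
(probit) latent draw → beta → sigma^2 → lam → (r, delta) sweeps →
(clustered) lam_b.

* **beta** — conjugate GLS draw under a flat prior.
* **sigma^2** — conjugate inverse-gamma draw (fixed at 1 for probit,
  required for identifiability of the latent scale).
* **lam, lam_b** — random-walk MH on the log scale with Jacobian
  correction.
* **(r, delta)** — per sweep, each component (random order) receives a
  birth (spike → slab), death (slab → spike), or log-scale random walk
  within the slab; one global swap proposal per sweep exchanges the weight
  of a random active and a random inactive exposure, which resolves
  inclusion contention between correlated exposures far faster than
  birth/death chains. Hierarchical groups use toggle / member-swap / walk
  moves that preserve the one-active-member constraint. Three sweeps run
  per iteration (`McmcControl.n_r_sweeps`): the selection indicators are
  the slowest-mixing part of the chain and get proportionally more
  proposals than the scalar blocks.
* **probit latent step** — draw h from its Gaussian full conditional given
  the current y*, then each y*_i from N(h_i + x_i'beta, 1) truncated to the
  side implied by y_i, then discard h (a partially collapsed Gibbs step;
  all other blocks remain marginal over h).

Birth moves draw the proposed r_m from an equal mixture of a lognormal
(median 0.3, log-sd 1.5) concentrated on the informative weight range and
the slab itself; the MH ratio carries the exact slab(r')/proposal(r')
correction, so the posterior is untouched. A proposal drawn from a wide
slab alone almost never lands where the kernel is informative, and the
sampler then cannot separate active from inert exposures in realistic
budgets.

### Priors and defaults

| Parameter | Prior | Default | Notes |
|---|---|---|---|
| beta | flat (improper) | — | conjugate GLS step |
| sigma^2 | Inverse-Gamma(a, b) | a = b = 0.001 | weakly informative |
| lam | Gamma(shape, rate) | (1, 0.1) | mean 10; surface-to-noise ratio |
| r_m given inclusion | Gamma(shape, rate) | (1, 1) | see below; `uniform(0, r_max)` selectable |
| pi | fixed | 0.5 | prior inclusion probability |
| lam_b | Gamma(shape, rate) | (1, 0.1) | random-intercept variance ratio |
| proposal sds (log scale) | — | 0.25 (lam, lam_b), 0.2 (r walk) | `PriorSpec` |

The slab on r_m doubles as the smoothness prior of the surface. On
standardized exposures, weights roughly in (0.01, 3) give informative
kernels; much larger weights drive K toward the identity, where the
"surface" degenerates into per-observation noise and the likelihood
becomes flat in the selection indicators (every PIP then drifts to the
prior 0.5). A slab uniform over a wide interval such as (0, 100) puts
almost all of its mass in that degenerate regime, so the default here is
Gamma(1, 1), concentrated on the informative range — the same motivation
behind the inverse-uniform slab of the original R implementation. The
uniform slab remains available through `PriorSpec(r_slab="uniform")`, and
PIP magnitudes are known to be sensitive to this choice (their ordering
much less so); a sensitivity analysis over slab settings is a one-line
configuration change.

The random-intercept prior is placed on the *ratio* lam_b = tau_b^2/sigma^2
(Gamma, matching lam) rather than on tau_b^2 itself: this keeps sigma^2
conjugate with the covariance written as sigma^2 × C. The reported and
persisted quantity is tau_b^2 = lam_b × sigma^2 per draw.

Sampler defaults: 10,000 iterations, 50% burn-in, thinning 1. All examples
in the tests and acceptance checks use shorter, stated budgets (2,000
iterations for the two benchmark fixtures; 1,000 for the calibration
replicates), chosen as the package's standard reduced-scale demonstration
sizes.

### Gaussian predictive process (fast mode)

With knots u_1..u_K covering the exposure space (default: k-means
centroids of the standardized exposures, a reproducible space-covering
choice; random subsets also available), the kernel is replaced by the
projection

    K~ = K_Zu (K_uu + nugget I)^{-1} K_uZ = A A',   A = K_Zu L^{-T},

with L the Cholesky factor of K_uu + nugget·I (nugget 1e-6 by default, for
factorization stability). Likelihood algebra runs through the Woodbury
identity and matrix-determinant lemma on I + U U' (U also absorbs the
cluster indicator block), so only knot-dimension matrices are ever
factorized. With knots at all distinct exposure rows, K~ equals the exact
kernel up to the nugget; the test suite verifies likelihood agreement to
1e-6 and that the approximation error is non-increasing in the number of
knots.

## Estimands

All summaries are functionals of h at exposure profiles built from
empirical quantiles (linear-interpolation / type-7 convention) of the
training exposures, with covariates held constant:

* overall effect Delta_tot(q1, q2) = h(z^{q2}) − h(z^{q1}), all exposures
  moved jointly;
* single-exposure effect Delta_m(q1, q2 | q), one exposure moved with the
  others fixed at their q-quantile;
* interactive effect Delta_m(25, 75 | 75) − Delta_m(25, 75 | 25), nonzero
  when exposure m's effect depends on co-exposure levels;
* univariate and bivariate cross-sections of the surface, the latter
  paneled over quantiles of a third exposure to diagnose three-way
  interaction;
* probit scale: event probabilities Phi(h + x'beta), risk differences
  between exposure settings at fixed covariate values, and the logit
  conversion beta_logit ≈ 1.6 × beta_probit (accurate away from extreme
  event probabilities).

Per stored MCMC state, the joint Gaussian conditional of h at all points
of a contrast is drawn once ("full-posterior" mode), so contrast
uncertainty reflects the posterior covariance of the surface; duplicated
points receive identical values, making a contrast of identical settings
exactly zero. A "mean-only" mode skips the conditional noise (narrower
bands; used for posterior-mean surfaces and plots) and the mode is recorded
in the output. Conditional draws are seeded from the stored chain seed and
the prediction points, so every summary is a deterministic function of the
persisted samples. Intervals are equal-tailed 2.5/97.5% sample quantiles.

## Synthetic-data generators

The generators define the package's study conditions and expose the truth
for calibration testing:

* **Continuous** (n = 500, M = 7, exchangeable correlation rho = 0.3, one
  covariate, noise sd 0.5): h_true combines a saturating logistic
  (plateau) term in z7 — steeper at low exposure, flattening at high —
  linear terms of both signs (z1, z2 positive; z4, z5 negative), a z1×z5
  product interaction, and two inert exposures (z3, z6). This mimics a
  biologically based dose-response benchmark with a strong, identifiable
  signal.
* **Binary probit** (n = 200, M = 30 independent exposures, one
  covariate): latent mean Σ_{m≤4} a_m (z_m^2 − 1) + 0.5 z1 z2 with
  a = (0.8, 0.8, 0.6, 0.6) — centered quadratics keep prevalence near 0.5
  and give the u-shaped exposure-response the probit example illustrates.
  The exposures are independent here: with 30 mutually correlated
  exposures at n = 200, inert exposures genuinely enter the posterior
  through chance correlation with the strong quadratic signal, and no
  correct sampler would separate them; the independent design is the
  regime in which variable selection is demonstrable at this sample size.
* **Clustered**: the continuous generator plus b_i ~ N(0, tau_b^2) over a
  stated partition; with tau_b = 0 it reproduces the unclustered dataset
  bit-for-bit at the same seed.

Truth records evaluate h_true anywhere and return every estimand in closed
form at the empirical quantiles (probit event probabilities are exact
Phi evaluations, so risk-difference truths need no Monte-Carlo step).

What the generators do **not** emulate: skewed or bounded exposure
distributions, measurement error, missing data, confounding structures
beyond a single independent covariate, and non-exchangeable correlation
other than user-supplied matrices. Passing tests therefore demonstrate
correctness of the algorithmic machinery and calibration under Gaussian
exposures with known truth — not robustness to the messiness of real
cohort data.

## Numerical choices

* All covariance solves go through Cholesky factorizations, with a
  symmetric-eigenvalue fallback (eigenvalues clipped at 1e-10) for
  borderline matrices; conditional-draw covariances use escalating jitter
  then eigenvalue clipping, and an exactly zero covariance returns the
  mean (no jitter noise).
* Single-component selection proposals update the dense kernel matrix
  multiplicatively, K' = K ∘ exp(−Δr_m D_m), guarded against exp overflow
  (full rebuild past |Δr_m|·max(D_m) = 40).
* The Gelman-Rubin PSRF uses the classic (non-rank-normalized) form and is
  clamped at 1 from below: values under 1 arise only from the (L−1)/L
  finite-sample factor.
* `posterior_estimates` uses plug-in (empirical-CDF) moments and
  quantiles, which are invariant under duplicating a chain; effect
  summaries use type-7 quantiles of the draws.
* Grids outside the observed exposure range warn (extrapolation) rather
  than error.

## Known limitations

* Proposal scales are fixed, not adapted; badly scaled data (bypassing
  standardization) may need manual tuning of `PriorSpec` proposal sds.
* PIP estimates from short chains carry episode-level autocorrelation;
  ranking stabilizes much earlier than magnitudes. Run multiple chains and
  check the PSRF before interpreting marginal PIP values.
* Equal-tailed intervals of spike-dominated contrasts (an exposure that is
  almost never selected) concentrate at 0 and can exclude the posterior
  mean; this is a property of equal-tailed intervals, not an error.
* Counts/Poisson outcomes, non-Gaussian kernels, and categorical exposures
  are out of scope, as are formal kernel-decomposition interaction tests.
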