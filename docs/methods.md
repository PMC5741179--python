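# Methods

## The model

`semijm` implements a shared-random-effects joint model for a Gaussian
longitudinal outcome truncated by *semicompeting* dropout and death: death can
censor dropout, but death remains observable (e.g. from registry linkage)
after dropout, so the reverse is not true.  Time is discrete — the follow-up
window is partitioned into M intervals, each containing one scheduled
measurement — and a patient's data are

* outcome rows `Y_ij = x_ij' beta + z_ij' b_i + eps_ij`, `eps_ij ~ N(0, sigma2_eps)`
  iid, `b_i ~ N(0, Sigma)` (random intercept and slope in all shipped
  configurations);
* a discrete-time probit dropout hazard
  `P(D_i = j | D_i >= j, b_i) = 1 - Phi(x_D,ij' alpha_D + (W_D b_i)' gamma_D)`;
* a discrete-time probit death hazard of the same form with
  `(alpha_S, gamma_S)`.

Observables follow the semicompeting mapping with independent censoring `C_i`:
`D* = min(D, S, C)`, `delta_D = 1[D <= C, D <= S]`, `S* = min(S, C)`,
`delta_S = 1[S <= C]`.  Given `b_i` the three processes are independent; the
gammas carry all outcome–event dependence, and `gamma = 0` recovers the
ignorable (MAR-type) case exactly.

`Sigma` is parameterized by its modified Cholesky decomposition
`L Sigma L' = G` (generalized autoregressive coefficients `lambda_kl`,
innovation variances `sigma2_k`), so positivity of the innovation variances is
the only constraint and unconstrained optimization/sampling is safe.

## Closed-form marginal likelihood

Rewriting every hazard factor through `1 - Phi(x) = Phi(-x)`, the event-history
likelihood given `b` is a product of `K = D* + S*` signed probit terms
`Phi(s_k (a_k + c_k' b))` (up to `2M` of them).  Introducing iid standard
normal `eps_k` with `Phi(t) = P(eps_k <= t)` and integrating `b ~ N(mu, Sigma_b)`
gives

    E prod_k Phi(s_k(a_k + c_k' b)) = Phi_K(u; I + A Sigma_b A'),
    u_k = s_k (a_k + c_k' mu),  A row k = s_k c_k',

a K-dimensional zero-mean normal orthant probability.  The patient marginal
log-likelihood is the Gaussian marginal of the observed outcome rows (via the
Woodbury identity) plus the log of this expectation under the posterior of
`b` given those rows.  Terms with `c_k = 0` factor out as exact scalar
`log Phi` values, so the `gamma = 0` factorization is exact to machine
precision, not to integration tolerance.  This reduction is locked in by
tests against an adaptive Gauss–Hermite quadrature oracle (posterior-
standardized tensor grid) and plain Monte Carlo, rather than trusted.

### MVN CDF evaluation

The orthant probabilities are evaluated by a Genz-type sequential-conditioning
quasi-Monte-Carlo algorithm (`semijm._mvncdf`) using scrambled Sobol point
sets derived from a fixed internal seed, so likelihood values are
deterministic across calls and optimizers see a smooth objective — the
documented failure mode of Monte-Carlo-noisy likelihoods (optimizer
non-convergence, unusable numerical Hessians) is avoided by construction.
Defaults: relative tolerance `3e-5` with adaptive doubling up to 4096 points
per scramble; `MvnOptions.fast()` (`5e-4`, 1024) and `MvnOptions.batched()`
(fixed 512-point budget shared across patients, vectorized over same-dimension
problems) trade tolerance for throughput inside fitting loops.  scipy's
independently implemented `multivariate_normal.cdf` serves as the oracle in
tests, never as the production path.

## Maximum likelihood

`fit_mle` maximizes the marginal likelihood over the unconstrained vector
(raw coefficients, log variances, raw lambdas) with Nelder–Mead plus one
restart by default (iteration cap 2000, tolerance 1e-5 on the log-likelihood).
Standard errors come from a hand-rolled central-difference Hessian and are
flagged unreliable when the MVN integration tolerance is within an order of
magnitude of the curvature differences.  `profile_ci` evaluates the profile
log-likelihood on a 10-point grid (warm-started nuisance re-optimization),
smooths it by quadratic least squares — the grid placement and smoother are
pragmatic choices, as only "smoothing" is specified by the approach this
follows — and inverts the likelihood-ratio drop of 1.92 for a 95% interval,
widening once with a warning if the fitted quadratic is non-concave.
`fit_lmm_ignorable` is the joint fit with the gammas frozen at zero and the
then-separable event factors dropped; it is the ignorable-missingness
comparator whose time slope is attenuated under informative truncation.

## Bayesian estimation

`sample_posterior` targets the complete-data posterior with `b_i` retained as
latents, so no orthant probabilities are needed.  Priors follow the
motivating analysis: `N(0, 100)` on `beta` and `lambda`, weakly informative
`N(0, 4)` on the probit-scale hazard coefficients, `IG(0.001, 0.001)` on
`sigma2_eps`, `IG(0.01, 1)` on the innovation variances; all overridable.

The sampler is Gibbs with truncated-normal augmentation of every probit
Bernoulli (event iff the latent `h_ij <= 0`), which makes all full
conditionals conjugate.  Two well-known slow directions of this augmentation
are addressed by extra Metropolis-within-Gibbs moves, both exact:

* **b-collapsed move** — `(alpha, gamma)` for each process is updated from its
  conditional with the random effects integrated out analytically (given the
  latents, `b_i` is Gaussian, and the process's latent rows then have an
  exchangeable one-factor normal marginal with a closed-form likelihood).
  Immediately followed by the `b` redraw, this is a valid blocked
  `(alpha, gamma, b)` update and breaks the `gamma`–`b` ridge ("regression on
  latent covariates").
* **h-collapsed move** — `(alpha, gamma)` is also updated against the exact
  Bernoulli-probit likelihood given `b` (latents integrated out), placed last
  in the sweep so the latents are refreshed before reuse.  This removes the
  latent-memory slowdown of probit data augmentation when event probabilities
  are far from 1/2 (deaths are rare by design).

Both moves use an adaptive proposal (covariance learned from warmup draws,
scale tuned to ~28% acceptance, frozen after warmup; 14 steps per sweep).
With them, the minimum effective sample size per 2400 iterations on the
scaled study conditions rises from ~5 to ~55.  Exactness of the targeted
posterior is verified by prior recovery on an empty dataset, a closed-form
GLS conjugate subcase, and simulation-based calibration on a reduced model
(uniform rank statistics, chi-square test).

Defaults mirror the motivating analysis (3 chains, 5000 warmup, 45000 pooled
draws); tests and the acceptance script use far fewer, with problem sizes
stated below.  Chains are initialized from data-driven values (least-squares
beta, ridge-probit alphas) dispersed by prior-scale jitter.  Visit-varying
gamma and non-identity W are supported in the likelihood/ML path; the Gibbs
sampler assumes the visit-constant, constant-W configuration used throughout
the motivating analysis.

## Mortal-cohort (partly conditional) profiles

Conditioning on survival to visit j multiplies the `N(0, Sigma)` law of `b`
by the j-1 survived probit factors, yielding a multivariate skew-normal
distribution.  Its mean has the closed form

    E(b | S >= j) = Sigma A' grad_u log Phi_{j-1}(u; I + A Sigma A'),

(Stein's lemma), with each CDF partial derivative a normal density times a
conditional (j-2)-dimensional MVN CDF.  The partly conditional profile is
`E(Y_ij | S >= j) = x_ij' beta + z_ij' E(b | S >= j)`; posterior bands come
from evaluating it per posterior draw.  "Alive at visit j" is encoded by
default as having survived the hazards of visits 1..j-1 (so `S >= 1` is
vacuous and at most an 11-dimensional CDF is needed when M = 12); the
alternative convention that also includes visit j's own hazard is available
via `alive_through=True`, as the choice is ambiguous in discrete time.  The
re-derived conditional mean is pinned by a scalar analytic identity (q = 1),
a numerical-gradient identity, and rejection-sampling oracles.

Note the ordering intuition "survivors sit above the unconditional mean with
a growing gap" is a theorem only when the selection acts through a
positively-weighted component: with `gamma_S1 = 0`, `gamma_S2 > 0` and a
*negative* intercept–slope covariance, the intercept's conditional mean is
slightly negative and can produce a tiny negative gap at early visits.  At
the full fitted-scale parameters the ordering holds at every visit.

## Posterior predictive check

The chi-square discrepancy normalizes outcome residuals by their marginal law
(random effects integrated out): `T = sum_i r_i' Omega_i^{-1} r_i / n_total`
with `Omega_i = Z_i Sigma Z_i' + sigma2_eps I` on the observed visits.  For
each posterior draw a replicated observed dataset is generated (dropout,
death, complete outcome vector; truncation at `min(D_rep, S_rep, M)`;
censoring and intermittent missingness are not replicated — only the
truncation process), and the reported probability is
`P(T_rep > T_obs)` over draws with ties counting one half.  Replicated
dropout and death times are drawn independently given `b`, matching the
model's conditional-independence assumption.

## Synthetic data

The generator (`semijm.synthetic_data`) is the study-conditions module, not a
fixture: sequential-Bernoulli event times with the sentinel `M + 1` for "no
event during follow-up", administrative censoring at M by default (an
arbitrary censoring distribution over visits is accepted), iid intermittent
missingness at 7.6% sparing the enrolment visit, and no measurement in the
death interval (configurable, since whether such a measurement exists is a
data-collection convention).  A MAR-on-previous-outcome skip option exists
for robustness experiments and is not used in any shipped test.  Per-patient
seed substreams make datasets bit-reproducible and stable under changes of N.

Two configurations ship:

* `hers_like_config()` — the full-size conditions: M = 12 (a 3-month interval
  then eleven 6-month intervals to day 2093), N = 827, sqrt-CD4-scale
  outcome, 4-level baseline viral-load factor, 0–5 symptom score, binary
  therapy, with all true parameters set to the fitted posterior means
  (e.g. time slope −0.863, `gamma_D = (0.029, 0.443)`,
  `gamma_S = (0.128, 1.192)`, `var(b1) = 29.120`, `var(b2) = 0.539`,
  `corr = −0.305`, `sigma2_eps = 7.304`).  Covariate frequencies (uniform
  viral-load groups, Binomial(5, 0.25) symptoms, 35% therapy) are realistic
  round numbers, chosen once; matching the cohort's exact marginals is a
  non-goal.
* `scaled_config(N=500, M=6)` — the recovery-study conditions: one binary
  baseline group covariate, hazard trends on the j/M scale, coefficients at
  the magnitudes of the full-size fit.  Used wherever hundreds of fits are
  required.

What passing tests on these data do *not* show: robustness to non-Gaussian
outcomes, informative censoring, residual serial correlation beyond the
random effects (V_i is sigma2_eps I by design), or misspecified hazard forms.
The generator draws from exactly the fitted model family, so recovery tests
validate the estimation machinery, not the model's adequacy for any real
cohort.

## Numerical choices and problem sizes

* log-domain accumulation throughout; `log Phi` arguments floored at −38
  (`log_ndtr(-38) ≈ −726`), orthant log-probabilities floored at −745.
* Non-PD covariances are rejected with the failing leading minor named.
* Survival-probability underflow below 1e-13 makes the conditional mean
  undefined and raises, rather than returning noise.
* Test problem sizes are chosen for a single CPU: the recovery study runs 100
  replicates at N = 500, M = 6 with one chain of 300 warmup + 1700 draws per
  fit, re-using Metropolis proposals adapted once on a preliminary fit;
  simulation-based calibration uses 80 replicates of a reduced q = 1, M = 3,
  N = 25 model; profile-CI coverage uses 60 replicates at N = 30 with the
  hazard parameters held at truth (the likelihood then factorizes and the CI
  machinery is exercised on the longitudinal block it actually profiles).
* Chains are initialized from a two-stage estimate: least-squares beta, crude
  BLUPs of the random effects from the outcome rows, then a ridge-probit
  regression of each event sequence on (hazard design, BLUP) for the alphas
  and gammas, dispersed by prior-scale jitter.  This places the weakly
  identified associations in the right region so short warmups carry no
  initialization drag.
* The acceptance script fits N = 500, M = 6 with 2 chains of 500 + 2000
  draws (proposals pre-adapted by a single-chain first pass) and reports
  posterior means, a recovery z-score, convergence and PPC summaries, profile
  gaps and marginal log-likelihoods; every random stream derives from the
  single `--seed`.

## Known limitations

* The Gibbs sampler's effective sample size for the death-model coefficients
  is modest (deaths are rare at the study conditions, mirroring the
  motivating cohort); interval estimates from short test-scale chains carry
  visible quantile noise.  The weakly identified dropout–slope association
  has a right-skewed posterior whose mean sits slightly above the generating
  value at these conditions — a property of the estimand, not a sampler
  defect (verified against long gold-standard chains).
* Continuous-time hazards, frailty terms beyond `b_i`, non-Gaussian outcomes,
  general `V_i`, and sensitivity analysis for the unverifiable
  conditional-independence assumption are out of scope.
* ML fitting is practical at test scales but inherently expensive at M = 12
  (24-dimensional orthant probabilities per patient per evaluation); the
  Bayesian route is the recommended default, as in the motivating analysis.
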