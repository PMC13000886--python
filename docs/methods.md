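# Methods

## Model

For patient i in subtrial k of a randomized controlled basket trial, let
Y_ik be a continuous outcome, T_ik ∈ {0,1} the treatment indicator and
X_ik a vector of baseline covariates.  The three data models are normal
linear regressions sharing one outcome variance σ_y²:

* unadjusted:  E(Y_ik) = α_k + θ_k T_ik
* ANCOVA I:    E(Y_ik) = α_k + θ_k T_ik + β_k′ X_ik
* ANCOVA II:   E(Y_ik) = α_k + θ_k T_ik + β_k′ X_ik + γ_k′ (T_ik X_ik)

θ_k is the subtrial-specific average treatment effect *provided the
covariates have zero mean within each subtrial*; `center_covariates`
enforces this (X_ik − X̄_k), and adjusted fits refuse uncentered data
unless overridden.  The parameter model makes the effects exchangeable:

    θ_k | μ_θ, σ_θ ~ N(μ_θ, σ_θ²),   μ_θ ~ N(0, v),   σ_θ ~ HT(s_HT, d),

where HT is a half-t distribution (location 0, scale s_HT, d degrees of
freedom, truncated positive).  σ_θ measures between-subtrial
heterogeneity; s_HT sets how readily the model attributes differences
among the θ̂_k to real heterogeneity rather than noise, so a larger s_HT
means less borrowing.  Remaining priors: α_k, β_k, γ_k ~ N(0, v) i.i.d.
(no hierarchy over covariate coefficients), σ_y² ~ InvGamma(a, b).

Defaults (units are those of the outcome): v = 100 (variance, i.e. SD
10 — weakly informative on an outcome of order a few units), s_HT = 2
with d = 5 (a near-flat alternative s_HT = 100 is exposed as the
"2"-suffixed methods), a = 2, b = 20 (prior mean of σ_y² is 20).
"N(0,100)" is read as variance 100 and "inverse-Gamma(2,20)" as
shape 2 / scale 20; μ_θ's hyperprior uses μ = 0, σ² = v = 100.

## Posterior computation

The normal-outcome posterior is sampled by a blocked Gibbs sampler
operating on per-subtrial sufficient statistics (X′X, X′y, y′y), so the
cost per iteration is independent of the number of patients:

1. each subtrial's coefficient block (α_k, θ_k, β_k, γ_k) jointly from
   its multivariate-normal full conditional (joint updates mix better
   than scalar updates and are exactly conjugate);
2. μ_θ from its normal conditional;
3. σ_θ² and an auxiliary scale from inverse-gamma conditionals, using the
   scale-mixture identity σ_θ²|a ~ IG(d/2, d/a), a ~ IG(1/2, 1/s_HT²)
   ⇔ σ_θ ~ HT(s_HT, d) — an exact representation that avoids tuned
   Metropolis steps;
4. σ_y² from its inverse-gamma conditional (a single variance shared
   across subtrials and arms).

Chains run 10 000 iterations with the first 2 000 discarded (8 000
retained, read as "total length 10 000"; results are insensitive at this
length) and are exactly reproducible from the integer seed.  Point-mass
"priors" on σ_θ and σ_y² are supported solely to validate the sampler
against dense-grid quadrature of the exact posterior (the test suite
checks 2% relative agreement on posterior means and SDs).

Point estimate: posterior mean.  Interval: the smallest half-width h such
that at least 95% of retained draws lie in [mean−h, mean+h] (a credible
interval symmetric about the posterior mean).  The normal approximation
mean ± z·SD is available via `BhmSpec.interval_method="normal"`; the
empirical symmetric-mass form is the default because it is exact for the
draws at hand.  H0k: θ_k = 0 is rejected when the closed interval
excludes 0; a boundary hit (L_k = 0) is conservatively a non-rejection.

For a Bernoulli outcome with logistic link, coefficient blocks are
updated by random-walk Metropolis with proposal shape from the logistic
Fisher-information bound X′X/4 and a scalar step size adapted toward 30%
acceptance during burn-in only (frozen afterwards to preserve detailed
balance).  Complete 0–1 separation makes the likelihood monotone in some
coefficient direction; the sampler flags (rather than raises) divergence,
detected as monotonically drifting or implausibly large coefficient draws
(|coef| > 30 on the N(0,100) prior scale).

## Frequentist comparators

Stratified AN(C)OVA: per-subtrial OLS on the same three mean structures,
classical residual-variance SEs, t-based confidence intervals (exact
under the normal linear model at small n_k).  Random-effect AN(C)OVA:
one linear mixed model (REML, statsmodels MixedLM) with subtrial-level
random intercept and random treatment slope (unstructured 2×2
covariance); covariate and treatment-by-covariate terms enter as
subtrial-specific fixed effects.  The subtrial effect is the fixed
treatment coefficient plus the BLUP random slope; its SE adds the BLUP
conditional variance to the fixed-coefficient variance (their covariance
is not exposed by the backend and is ignored), with normal quantiles.

Convergence of mixed models: the optimizer is retried over
bfgs/lbfgs/powell/nm; a fit counts as converged when any method reports
convergence.  Boundary (zero-variance) REML estimates are *kept*: under
the benchmark generators the random-intercept variance is truly zero, so
a boundary estimate is the correct answer, and discarding such fits would
empty the random-effects rows.  Nonconverged replicates are excluded from
bias/SD/RMSE (with B reduced) and counted as non-rejections in rate
metrics; the convergence rate is reported alongside.  This exclusion rule
is a package choice — published tables do not state one — and both it and
the rate denominators are visible in the report objects.

## Synthetic data

The benchmark generator emulates a 4-subtrial trial with sizes in ratio
2:3:4:5, complete randomization at a fixed ratio (treated counts are
exact, via permutation of a fixed-count assignment vector, so allocation
is deterministic), one covariate X ~ N(0,1), noise ~ N(0,1), and outcome
models

* S1: Y = 1 + θ_k T − 2X + 4TX + ε   (predictive covariate; correctly
  specified only for ANCOVA II)
* S2: Y = 1 + θ_k T − 2X + ε         (prognostic only; ANCOVA I correct,
  ANCOVA II correct with γ_k = 0)
* S3: Y = 1 + θ_k T − 2X + TX³ + ε   (mis-specified for every linear model)

with θ = (0,0,1,1) by default and a homogeneous variant θ = (1,1,1,1).
The drawn covariate is standardized to exact zero mean within each
subtrial *before* outcomes are computed.  This enforces the model's
identifiability condition E(X_ik) = 0 exactly; without it the
generation-time covariate mean X̄_k ~ N(0, 1/n_k) enters every estimator
of θ_k (as 4X̄_k under S1) and inflates all sampling variances — the
benchmark's operating characteristics correspond to the standardized
convention.  The raw-draw behaviour is available via
`standardize_covariates=False`.

The two-subtrial generator mimics a phase II trial in two blood-cancer
subtypes (PV: n=180, 93 treated; ET: n=110, 58 treated) with covariates
sex ~ Bernoulli, driver-mutation status ~ Bernoulli and baseline
haemoglobin ~ normal, and a continuous log-odds-ratio outcome
Y = linear predictor + noise.  The linear-predictor coefficients are
required configuration with no defaults (the source coefficients derive
from external trial publications and are not built in).  Signal-to-noise
is defined empirically on the generated cohort: Var(noise) =
Var(linear predictor)/SNR with SNR = 10 by default; a constant linear
predictor is therefore a configuration error in continuous mode.  A
binary mode draws Y ~ Bernoulli(logit⁻¹(linear predictor)).

What the generators do *not* emulate: covariate measurement error,
missing data, non-normal noise, staggered enrollment, or correlation
between covariates; passing tests therefore demonstrate correctness of
the estimators and of the simulation machinery under the stated
conditions, not robustness to those real-data features.

## Simulation metrics

Over B replicate estimates θ̂_k^b: bias = mean − θ_k (MCSE SD/√B);
SD with denominator B−1 (MCSE SD/√(2(B−1))); RMSE = √(Σ(θ̂−θ)²/B) —
note the B denominator, giving the exact identity RMSE² = bias² +
SD²(B−1)/B, verified on every report.  RMSE reduction of method 2 versus
method 1 is (1 − RMSE₂/RMSE₁)×100; its MCSE is the delta-method
transform of the MCSE of MSE₂/MSE₁, whose covariance term is estimated
from the paired per-replicate squared errors — this requires both methods
to have analyzed identical datasets, which the runner guarantees by
deriving each replicate's data seed from (base seed, cell labels,
replicate index) only, never from the method roster.  Rejection rates
carry binomial MCSEs; family-wise error is the proportion of replicates
rejecting at least one truly-null subtrial, disjunctive power at least
one effective subtrial.  The nominal family-wise reference level for m
tests at level α is 1 − (1−α)^m (9.75% for two tests at 5%).

## Problem sizes

The acceptance script runs the n=560 cells with 300 replicates for
MCMC-based methods and 1000 for the stratified-only cell; the test suite
uses 100–200 replicates for MCMC cells and 1000 for pure-OLS checks.
These sizes put Monte Carlo SEs comfortably below the 3×-combined-MCSE
comparison bands while keeping a full run to a few minutes on one CPU.

## Known limitations

* Single chain per fit; convergence diagnostics beyond the separation
  heuristic and reproducibility checks are out of scope (arviz can be
  applied to `PosteriorDraws.to_frame()` if desired).
* No borrowing over covariate coefficients; no non-exchangeable or
  mixture parameter models.
* Mixed-model intervals ignore the fixed/BLUP covariance term and may be
  conservative; whether published random-effects intervals account for
  BLUP shrinkage uncertainty is not stated, so small discrepancies in
  their rejection rates are expected.
* Time-to-event and count outcomes are not supported.
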