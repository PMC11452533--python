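# Methods

## Model

The package implements the random-intercept cross-lagged panel model
(RI-CLPM) for K constructs over T waves. Each observed composite decomposes
into a wave-specific grand mean, a person-specific time-invariant random
intercept, and a within-person deviation that follows a first-order vector
autoregression:

    x_kt = mu_kt + RI_k + w_kt
    RI_k = b_k (g − mu_g) + u_k,   u ~ MVN(0, Psi)
    w_.1 ~ MVN(0, Sigma_w1)
    w_.t = B_t w_.(t−1) + eps_t,   eps_t ~ MVN(0, Theta_t)

Assumptions: joint normality of all components; the within-person process is
Markov of order one; the covariate g (a polygenic index here, but any
numeric covariate) is exogenous, acts only on the random intercepts (a
variant regressing g directly on every observed composite is available as
`predictor="on_observed"`), and enters the joint likelihood with free mean
and variance so that subjects missing g are retained under FIML. The
regression on g is written against centered g so the grand means keep their
interpretation; this is a pure reparameterization with an identical
likelihood. Wave-1 within-person components are exogenous with a free K×K
covariance — the standard initialization that makes the likelihood
well-defined without stationarity assumptions.

Identification requires T ≥ 3 in general (at T = 2 the free scheme has more
parameters than saturated moments); the package builds T = 2 specifications
but fitting them will fail with a singular-information error.

### Constraint schemes

Three nested schemes tie the transition matrices B_t (autoregressive and
cross-lagged paths) over time: `constrained` (one shared B, "model 1"),
`first_free` (B_2 free, B_3..B_T shared, "model 2"), and `free` ("model 3").
The within-wave residual covariances Theta_t stay free per wave in every
scheme; only regression paths are tied. With K = 4 and T = 4 this puts the
free-parameter differences at exactly 32 (free vs constrained) and 16 (free
vs first_free), and tying the grand means over waves removes K(T−1) = 12
parameters — the degrees of freedom behind the nested chi-square tests.
An `equal_over_waves` mean structure expresses the grand-mean constraint.

## Estimation

### Likelihood

The log-likelihood is the casewise multivariate-normal likelihood over each
subject's observed variables (full-information maximum likelihood, valid
under MAR). Subjects are grouped by missingness pattern; each pattern
contributes through its count, mean and scatter, so one likelihood
evaluation costs O(#patterns · p³) regardless of n. With wave-level
attrition there are at most 2^T · 2 patterns.

### Optimization

Fisher scoring on the free-parameter vector. The gradient is assembled by
contracting the analytic pattern-level gradient with respect to (mu, Sigma)
with the Jacobian of the moment map theta → (mu(theta), Sigma(theta)):
Jacobian columns for slots that enter the moments with theta-free structure
(means, predictor moments, random-intercept covariances, predictor paths)
are exact, and columns that run through the transition recursion (wave-1
covariance, transitions, residual covariances) use central differences on
the small moment-assembly map (error ~1e-10). The expected information is
assembled from the same Jacobian, so a Newton-quality step costs little more
than a gradient; an Armijo backtracking line search guards ascent, and box
constraints keep variance slots nonnegative via projection with an
active-set screen (at an active bound, the Newton system is restricted to
the coordinates free to move). A quasi-Newton method on the natural
parameterization was tried first and needed >1000 iterations on realistic
problems — variances of order 0.005 sit next to means of order 1.6 and the
Hessian is badly conditioned — while Fisher scoring converges in about 7.

Starting values are method-of-moments: a quick saturated EM estimate is
decomposed into a between-person covariance (mean of distant-lag cross-wave
covariances), within-wave covariances by subtraction, transitions by linear
regression of lagged blocks, and residual covariances by the VAR identity,
all projected to the PSD cone. A data-agnostic fallback start (available-case
means, half the pooled variance per variance component, paths at 0.1) is
used when the moment start fails.

Convergence requires the projected gradient's infinity norm ≤
tolerance · (1 + |loglik|), tolerance 1e-6 by default. Non-convergence
triggers up to two seeded, jittered restarts; a fit that still fails raises
an explicit error carrying diagnostics — a non-converged solution is never
returned silently. Variance estimates on the boundary are reported with a
warning, not hidden. Identical data and options give bit-identical results;
subject order does not matter beyond floating-point tolerance because
pattern order is canonicalized.

### Standard errors and robustness

Standard errors default to the observed information: the negative Hessian of
the FIML log-likelihood by central differences on the semi-analytic gradient
(step 1e-4 relative; the gradient itself is accurate to ~1e-9, so the
Hessian is good to ~1e-5 relative). A sandwich estimator A⁻¹BA⁻¹, with B the
sum of per-subject score outer products, is available as the robustness
analogue of "MLR" standard errors. The Yuan–Bentler/Satorra–Bentler scaled
test statistics themselves are not implemented: the point estimator is
identical, the scaling touches only test statistics, and chi-square
difference degrees of freedom — the checkable bookkeeping — are
scaling-invariant.

### Derived quantities

- ICC_k = (b_k² var_g + Psi_kk) / mean_t Var(x_kt): between-person share of
  a construct's variance, averaged over waves in the denominator because
  within-wave variance varies by wave (a documented convention choice).
- Per-indicator R² from the random intercept = between variance / implied
  indicator variance = squared standardized RI loading.
- Standardized PGI effect beta_k = b_k sigma_g / SD(RI_k total); the share
  of indicator variance explained by g equals beta_k² · R²_kt exactly.
- Standardized transitions scale each B_t entry by the within-process SD
  ratio of sender and receiver; residual and random-intercept covariances
  are reported as correlations.

## Fit indices and model comparison

The model chi-square is 2(ll_sat − ll_model) against the saturated
(unstructured mean + covariance) FIML fit, computed by EM over the same
missingness patterns; the independence baseline (free means and variances,
zero covariances) is closed-form because a diagonal covariance factorizes
the casewise likelihood per variable. CFI, TLI, RMSEA, AIC and BIC follow
the standard definitions; RMSEA uses n (not n−1) in the denominator, and at
df = 0 it is reported as 0 when there is no excess misfit and NaN (flagged)
otherwise. Nested fits are compared with central chi-square difference
tests; the selection report drops any restricted model rejected at alpha
= 0.05 against a fuller one and picks the lowest BIC (then AIC, then fewer
parameters) among the survivors, alongside the conventional CFI/TLI ≥ 0.95
and RMSEA ≤ 0.08 flags. The p < 0.01 coefficient-significance threshold is a
reporting annotation only; estimation and saved estimates are unaffected.

## Scale scoring

Composites are per-wave means of the instrument's items (Relationship
Satisfaction Scale: 10 items at waves 1–3, 5 at wave 4, 1–6; enjoyment
subscale: 3 items, 1–5; SCL-8 depressive and anxiety subscales: 4 items
each, 1–4), defined when at least half the items are answered
(configurable); mean scoring keeps the 5- and 10-item waves on one metric.
Composites are natural-log transformed before modelling to reduce skewness
(per-construct configurable, default all four). Cronbach's alpha uses
listwise-complete rows per scale per wave; descriptive correlations default
to pairwise deletion because wave-wise attrition would gut listwise samples;
partial correlations residualize both variables on the covariates over
complete cases.

## The synthetic cohort generator

The generator is the package's stand-in for an access-restricted pregnancy
cohort and defines the conditions every experiment runs under. Defaults are
calibrated once to the published profile:

- intra-class correlations (0.63, 0.58, 0.49, 0.49) for relationship
  satisfaction, positive affect, depressive and anxiety symptoms;
- standardized PGI effects on the random intercepts (0.09, 0.10, −0.18,
  −0.17), with g standard normal and 82.1% genotyped;
- grand means at the log of the published raw composite means (e.g. 5.36
  for wave-1 relationship satisfaction) and log-scale total SDs near the
  published coefficients of variation (0.14, 0.17, 0.32, 0.29);
- random-intercept correlations spanning the reported −0.32..0.83 band
  (depressive–anxiety at 0.83);
- wave-level participation at (95.51, 89.77, 76.9, 58.65)% and the
  exclusion cascade of 324 stillbirths then 11,688 never-participants out
  of 95,136 (exact deterministic counts on request, Bernoulli otherwise);
- item noise calibrated by bisection on a fixed internal Monte-Carlo panel
  so that measured alphas hit the published bands (0.90–0.93, 0.81–0.83,
  0.73–0.77) *after* rounding to integer responses and clipping to the
  scale range — near a scale ceiling the analytic parallel-item solution
  is off by several points of alpha, so the calibration mirrors the
  generator's discretization exactly.

Within-person dynamics are wave-varying plausibility choices (standardized
paths ≤ 0.4 in magnitude, the pregnancy-to-postpartum transition weakest,
autoregressions strengthening postpartum), chosen once; no published
numerical path values exist to target. Residual covariances are derived to
keep the within-process covariance stationary at its wave-1 value, which
produces the qualitative co-development sign pattern (wellbeing constructs
positively correlated, wellbeing–illbeing negative).

What the generator does not emulate, and what that means for the tests:
attrition is MCAR (independent per-wave Bernoulli; an optional monotone
once-out-stay-out mode exists for sensitivity runs), whereas real cohort
attrition is selective — so passing recovery tests show estimator
correctness under MAR-compatible missingness, not robustness to informative
dropout. Items are parallel (equal loadings) with normal noise, so ordinal
asymmetries and item-specific factor structure are absent; floor and ceiling
clipping biases item-scored raw composite means upward near the floor
(depressive-symptom means score ~1.46 against a generating 1.32) and
attenuates ICCs and PGI betas estimated from item-scored composites by
roughly 15–20% relative — the estimation target is the composite process,
which the panel view delivers exactly.

## Problem sizes

Desk-scale defaults keep the full suite around five minutes: the pipeline
and fitting examples use cohorts of 20,000 before exclusions; the
parameter-recovery experiment runs 200 replicates of the two-construct,
four-wave reduced design at n = 5,000 under the study attrition profile
(bias within 3 Monte-Carlo SEs per parameter, 95% CI coverage within the
binomial band, SE calibration within ±15%); the nested-test size experiment
runs 500 replicates at n = 1,000 under a true time-invariant process
(empirical rejection at the 5% level within [0.03, 0.07]). The
study-scale exclusion arithmetic runs at the full n = 95,136, which costs
about a second without item generation.

## Known limitations

- No measurement model: composites enter directly, as in the target
  analysis; item-level misspecification surfaces only as attenuation.
- No robust (scaled) test statistics; sandwich SEs are the only
  non-normality concession.
- No MNAR machinery: FIML is MAR-valid, and the generator cannot produce
  informative dropout beyond the monotone sensitivity mode.
- The chi-square difference test is the central (uncorrected) one; with
  strongly non-normal data its size is not guaranteed.
- Fisher scoring assumes the expected information is positive definite away
  from boundaries; under-identified specifications fail with a singular
  Hessian at the standard-error stage rather than at specification time.
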