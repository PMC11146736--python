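# Methods

This note documents the models trajmix implements, the choices made where
the design was genuinely open, and what the synthetic cohorts do and do not
emulate.

## Measurement model (`trajmix.rasch`)

Seven physical-aggression behaviors (hit, push, pull-hair, pinch, throw,
bite, kick) are reported in two formats: a 7-point frequency scale on
questionnaire waves and yes/no on phone waves. Both load on one latent
aggression dimension θ:

- binary items: dichotomous Rasch, P(x=1|θ) = logistic(θ − b_i);
- 7-category items: partial-credit model,
  P(x=c|θ) ∝ exp(Σ_{s=2..c} (θ − τ_is)), with threshold disordering
  permitted (the partial-credit convention).

**Calibration.** Concurrent marginal maximum likelihood: all occasions from
both formats are pooled into one calibration, which places the formats on a
common scale by construction (vertical equating through the shared latent
distribution). The latent density is Normal, integrated with 61
Gauss–Hermite nodes; the optimizer is L-BFGS with analytic gradients
(tolerance 1e-8 on the gradient). The Rasch likelihood has a single
location invariance, so identification fixes the grand mean of item
locations — binary difficulties pooled with the polytomous threshold means
— at zero, and the latent mean is estimated freely. (Fixing each format's
location separately would impose two constraints on one invariance and is
not possible without distorting the model.) Items with zero response
variance are dropped with a warning and carry NaN parameters.

**Scoring.** Per-occasion Warm weighted-likelihood estimates (WLE), the
bias-reduced ML variant that stays finite for all-minimum / all-maximum
patterns; the root of the weighted score equation is found by Brent
bracketing on [−15, 15] (expanded if needed) and the SE is the inverse
square root of the test information at the estimate. Occasions are scored
independently — no longitudinal smoothing — because the growth model
consumes per-occasion scores. Occasions with every item missing are
omitted and logged.

**Known limitation — format floors.** Below the easiest item the score of
an all-minimum pattern saturates at a format-specific floor (the binary
floor is higher than the 7-category floor because the frequency scale
reaches further down). Equating holds where both formats are informative;
dual-format comparisons in the tails reflect these instrument floors, not
scale misalignment. The equating check therefore evaluates dual-format
children at latent levels around the item locations.

## Growth mixture (`trajmix.lcga`)

Latent class growth analysis: child i belongs to one of K classes with
probability π_k; given class k,

    y_ij = Σ_{p=0..4} β_kp (a_ij − 2.2)^p + ε_ij,  ε_ij ~ N(0, σ²),

a quartic mean curve in age centered at 2.2 years, **no within-class
variability** in the growth components, and one residual variance shared
across times and classes. Children are the independent units; residuals are
independent given class. Parameter count is 5K + (K−1) + 1.

**Estimation.** EM: the E-step computes class posteriors from the product
of Normal densities over each child's observations; the M-step solves a
posterior-weighted polynomial least-squares per class, pools σ² over all
observations, and sets π to mean posteriors. Defaults: 50 starts (random
child partitions plus one quantile split on child mean score), absolute
log-likelihood tolerance 1e-7, at most 2000 iterations, variance floor
1e-6. A start in which a class's posterior mass falls below one child is
redrawn (up to 10 times). Powers are computed on centered age directly (no
orthogonalization) so coefficients keep their curve interpretation; a
condition-number warning is emitted for ill-conditioned designs. Label
switching is resolved deterministically by sorting classes on the
model-predicted score at age 5, so class 1 always has the lowest endpoint.

## Class enumeration (`trajmix.enumeration`)

AIC = −2LL + 2p; BIC = −2LL + p·ln n; CAIC = −2LL + p·(ln n + 1);
saBIC = −2LL + p·ln((n+2)/24). n is the **number of children** — the
likelihood's independent units — not the observation count.

The bootstrap likelihood ratio test (BLRT) of K vs K+1 classes simulates
replicate panels from the fitted K-class model **at the observed (child,
age) design** (standard parametric-bootstrap conditioning), refits both
models to each replicate, and reports p = (1 + #{bootstrap LRT ≥ observed})
/ (reps + 1). Replicate fits default to 10 starts — fewer than the
observed-data fit — reflecting the test's heavy computational burden; a
degenerate replicate is redrawn (cap 3) and logged.

## Manual 3-step structural models (`trajmix.three_step`)

Step 1 fits the mixture without covariates; step 2 assigns each child the
modal class N_i (ties to the lowest index) and estimates the
classification-error matrix q_st = P(N=t | C=s) by posterior-weighted
cross-tabulation, Σ_i p_is 1[N_i=t] / Σ_i p_is; step 3 fits structural
models in which N is a fallible indicator of the true class C with the
measurement logits log(q_st / q_sK) held fixed (floor 1e-8 on q).
Proportional pseudo-class draws are not implemented; modal assignment is
the declared variant.

All step-3 likelihoods marginalize over C:

- predictor → class: Σ_s P(C=s|x) q_{s,N}, multinomial logistic with
  class 1 the reference; overall LRT vs the zero-slope model, df = K−1
  (8 for nine classes);
- class → outcome: Σ_s π_s q_{s,N} N(y; m_s, v) with a common within-class
  variance; overall LRT vs equal means; R = √(1 − v/total variance);
- fully adjusted: Σ_s P(C=s|x) q_{s,N} N(y; m_s + δ'x, v) with all
  predictor → class paths, class means and direct predictor → outcome
  paths simultaneous; each predictor's overall class test zeroes its K−1
  multinomial slopes.

Optimization is L-BFGS with analytic gradients; coefficient covariances
come from the observed information (central differences of the analytic
gradient). Detected separation (|slope| > 10 logits) triggers a refit with
a light ridge (1e-3) on the multinomial slopes, flagged on the result. An
optional constraint fixes chosen direct paths to zero — the published rule
against adjusted direct effects that reverse the sign of their unadjusted
counterpart — and is off by default.

**Effect sizes and contrasts.** Cohen's ω (pseudo-R) = √(χ²/n) for overall
class tests; the LRT χ² is used directly (a robust-weighted χ² variant
would require estimation internals that are not public; the printed-χ²
conversions are unaffected). Coefficients are standardized by sample SDs
(ddof 1); standardized class-mean differences divide by the total-sample
outcome SD, making the reference class exactly 0.00. Contrasts between any
two classes are coefficient differences with Wald SEs from the coefficient
covariance; the K(K−1)/2 pairwise tests (36 for K=9) are reported
unadjusted for multiplicity, annotated with the chance expectation
n_tests × α hits (each hit produces two table markers).

## Preprocessing (`trajmix.preprocess`)

Transform steps, applied in declared order with constants frozen at fit
time: trim (values outside the 2nd/98th percentiles recoded to the cut
values — linear-interpolation percentiles, the documented convention for
the "approximately 2nd and 98th" rule), reverse (bounded scales:
(max+min) − x), recenter-min-zero, center-mean, square-root (guarded to
non-negative input). Missing values propagate. Missing-data policies:
complete-case (per-model row deletion with counts) or simple imputation
(mean for continuous, mode for binary, imputed cells flagged); a full
multiple-imputation engine is out of scope and would be standard package
territory, not modelling substance.

## Synthetic cohorts (`trajmix.simulate`)

The generator emulates the study's data structure so every stage is
testable without external data. Defaults (the study conditions):

- 1,141 children; nine classes with proportions
  (.14, .22, .16, .07, .05, .17, .09, .07, .03);
- 21 waves between ages 1 and 5 — four 7-category questionnaire waves
  (ages 1–4, 15% missingness) and seventeen binary phone waves (49.4%
  missingness) — giving an expected 4×0.85 + 17×0.506 = 12.0 realized
  waves per child, the reported average; wave ages are jittered
  (SD 0.08/0.06 years) and truncated to [0.6, 5.4] to reproduce irregular
  timing; missingness is completely at random per wave;
- quartic class curves solved through five hand-chosen anchor values per
  class reproducing the published taxonomy (low-stable; two medium-peak
  low-endpoint; two high-start low-endpoint; three intermediate-endpoint;
  one high-stable peaking near age 2.2), with age-5 endpoints strictly
  ascending in class index. The anchor values are synthetic — the source
  figure prints no coefficients — and are shipped as a documented constant;
- residual SD 1.0 around the class curve; item responses drawn from the
  measurement model at θ = noisy score using a default bank whose binary
  difficulties span −2..2 and whose threshold grids span roughly −4..4;
- eight early predictors with the descriptive means/SDs/prevalences of the
  study's transformed scales (gender .52, similar-aged sibling .38, harsh
  parenting, education, couple relationship, maternal depression/anxiety,
  activity level); class membership follows a multinomial logistic model
  whose per-SD coefficients echo the published unadjusted effect pattern
  (gender and sibling strongest); with zero coefficients the class
  marginals equal the stated proportions exactly;
- four distal outcomes with class means set from the published
  standardized-difference patterns, a direct gender effect on each outcome,
  and residual SDs implying the published class→outcome R; all other
  predictors act on outcomes only through class, which supplies a purely
  indirect predictor for testing.

**What the generator does not emulate:** informative attrition, sibling
correlation, per-child visit schedules, time-varying predictors, and any
non-Normal residual structure. Passing tests therefore demonstrate the
estimators' correctness and calibration under the assumed model, not
robustness to those real-data features.

## Problem sizes used in tests

Simulation-based checks run at sizes chosen to keep the full suite quick
while leaving conclusions unchanged: BLRT type-I calibration uses 100 null
cohorts of 100 children × 5 observations with 39 bootstrap replicates
(rejection count compared with the binomial 95% interval around .05); BIC
recovery uses 20 cohorts of 150 children; growth-coefficient recovery uses
1000 children × 10 observations; 3-step recovery uses 20 full-size
(n=1141) default cohorts with classification taken at the true measurement
model, which isolates the step-3 machinery from mixture-fitting
variability.

One documented shortfall: the median absolute error of the standardized
predictor→class coefficient matrix under the default conditions is ≈0.12,
with an essentially unbiased estimator (regression of error on truth has
slope ≈0.01). The per-coefficient sampling SD at n=1141 with nine classes
(the smallest holding ~3% of children) is ≈0.16 — and ≈0.13 even for the
infeasible estimator that observes true classes — so a ±0.1 recovery
tolerance lies below the design's sampling-noise floor; the corresponding
test is left failing rather than loosened.
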