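# trajmix

Latent-trajectory analysis of physical aggression across early childhood:
a tested Python implementation of the full analytic chain used in
group-based trajectory studies of toddler aggression — measurement scaling,
trajectory-class estimation, class enumeration, and structural models
linking early predictors and school-age outcomes to the trajectories.

**Who it is for.** Developmental and epidemiological researchers fitting
latent class growth models (LCGA) to irregularly timed repeated measures,
and methodologists who need a transparent, fully scriptable version of the
manual 3-step auxiliary-variable procedure with its effect-size and
contrast conventions.

## The models

1. **Measurement** (`trajmix.rasch`). Seven aggression behaviors are
   reported on two formats: a 7-point frequency scale (questionnaire waves)
   and yes/no (phone waves). Both formats are calibrated concurrently on
   one latent scale — dichotomous Rasch P(x=1|θ) = logistic(θ − b_i) and
   partial-credit P(x=c|θ) ∝ exp(Σ_{s≤c}(θ − τ_is)) — by marginal maximum
   likelihood, and each occasion is scored with Warm's weighted-likelihood
   estimator θ̂.

2. **Trajectories** (`trajmix.lcga`). A K-class mixture of quartic growth
   curves on age centered at 2.2 years,
   y_ij = Σ_p β_kp (a_ij − 2.2)^p + ε_ij, ε ~ N(0, σ²),
   with no within-class growth variance and a single residual variance —
   fitted by multi-start EM, classes labeled by ascending age-5 endpoint.

3. **Enumeration** (`trajmix.enumeration`). AIC / BIC / sample-size
   adjusted BIC / CAIC on the number of children, plus the parametric
   bootstrap likelihood ratio test (BLRT) for K vs K+1.

4. **Structural models** (`trajmix.three_step`). The manual 3-step
   procedure: modal class assignment, a posterior-weighted
   classification-error matrix held fixed as measurement logits, then
   maximum-likelihood multinomial predictor→class models, class-specific
   distal-outcome means, and fully adjusted simultaneous models. Effect
   sizes follow the field's conventions: Cohen's ω = √(χ²/n) for overall
   class tests, R = √(1 − within/total variance) for class→outcome
   effects, coefficients standardized by sample SDs, pairwise class
   contrasts by subtraction.

5. **Synthetic cohorts** (`trajmix.simulate`). A first-class generator
   reproducing the study conditions — 1,141 children, nine trajectory
   classes with proportions (.14, .22, .16, .07, .05, .17, .09, .07, .03),
   21 mixed-format waves averaging ~12 realized measures per child, early
   predictors with multinomial class effects, and four distal outcomes —
   so every stage is testable without any external data.

## Worked example

The numbered scripts under `analysis/` run the whole chain on a synthetic
cohort and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py      # cohort tables
python analysis/02_scale_aggression.py     # item bank + person locations
python analysis/03_select_classes.py       # information criteria over K
python analysis/04_fit_trajectories.py     # final 9-class model
python analysis/05_structural_models.py    # 3-step predictor/outcome models
```

Script 02 reports the calibration — difficulties recovered near their
generating values and scores tracking the latent curve:

```
calibrated item bank:
  binary difficulties: [-2.04, -1.01, -0.52, -0.01, 0.46, 0.99, 2.07]
  ...
corr(person location, generating score) = 0.858
person location M = -2.05, SD = 1.69
```

Script 05 prints the structural summary (seed 1):

```
  child_gender                 chi2(8) =   39.0 *** omega = 0.18
  similar_aged_sibling         chi2(8) =   65.2 *** omega = 0.24
  maternal_harsh_parenting     chi2(8) =  155.9 *** omega = 0.37
  ...
  trajectory -> externalizing          R = 0.29 (chi2(8) = 70.2, p = 4.47e-12)
contrast tables: 36 pairwise tests per row; 1.8 chance hits (3.6 markers)
expected under the null
```

Each predictor row is an 8-degree-of-freedom likelihood ratio test of the
predictor's eight class-discrimination effects (nine classes, class 1 the
reference), with Cohen's ω = √(χ²/1141) as the effect size — e.g. the
similar-aged-sibling χ² of 65.2 gives ω = .24, meaning sibling presence
shifts trajectory membership by about a quarter of a standard deviation in
the effect-size metric. The trajectory→outcome rows give R, the square
root of the proportional reduction in outcome variance achieved by the
class means. The final line is the multiplicity annotation for the
36-contrast tables: under a null association, 1.8 of the 36 pairwise
contrasts per row are expected significant at α = .05 by chance alone.

A one-command variant of the same pipeline is available via the CLI:

```sh
trajmix init config.yaml   # write defaults
trajmix run -c config.yaml
```

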