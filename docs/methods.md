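# Methods

This note documents the statistical procedures implemented in `htestrat`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and known limitations.

## Cohort and data model

The unit of analysis is a patient with on-admission covariates (age, sex,
NIHSS, ASPECTS, hyperdense-MCA sign, atrial fibrillation on ECG, glucose,
pre-stroke mRS, onset-to-treatment time), a binary treatment arm
(1 = neuroprotective add-on, 0 = control), and outcomes: symptomatic HT
(ECASS III definition), any HT, day-90 mRS (0–6) and favorable functional
outcome (FFO, mRS ≤ 2).  Record invariants are enforced on I/O: symptomatic
HT implies any HT; FFO equals 1 exactly when mRS ≤ 2.

`printed_cerehetis_cohort()` reconstructs the 238-patient MCA-stroke trial
cohort exactly from its published (arm × HTI stratum) counts for symptomatic
HT, any HT and FFO.  Unit-level mRS is not recoverable from grouped medians
and is not carried; mRS-dependent stages (ordered logit, Hedges-g pooling,
the mRS column of the HTE table) therefore run on synthetic cohorts only.
Within a stratum the binary outcome columns are marginal reconstructions
(front-packed); any analysis that looks only at per-stratum event totals —
everything in this package — is invariant to that choice.  One published
table caption prints n = 248 where every other count implies 238; we treat
that as a typo and use 238 throughout.

## Risk scores

DRAGON, SEDAN and HTI are additive point scores with published component
bands (see `scores.py` for the full tables).  Conventions the published
band definitions leave open, fixed here: ages are floored to integer years
before banding; the SEDAN glucose band "8.1–12.0 mmol/L" is read literally
as (8.0, 12.0] on the measured value with no rounding; DRAGON
onset-to-treatment scores a point only strictly above 90 minutes.  HT risk
is graded from HTI alone: low (0), moderate (1), high (≥ 2).

## Binary logistic stage

`fit_logit` is maximum likelihood via IRLS (relative log-likelihood
tolerance 1e-10, at most 100 iterations) with frequency weights, so grouped
counts and their unit expansion give identical coefficients.  Separation is
detected as coefficient divergence (|β| > 25) and raised, not penalized.
Odds ratios are exp(β) with Wald normal intervals.

Conditional margins report per-(score, arm) probabilities with intervals
computed on the linear-predictor scale and inverse-logit transformed, and
the per-score treatment contrast with a delta-method standard error.  The
Šidák correction uses α′ = 1 − (1 − α)^(1/m); m defaults to the number of
intervals in the set, and the pipeline's margins table corrects across the
whole table (m = 30 for 5 levels × 2 arms × 3 outcomes), which is what the
published intervals correspond to.

Bootstrap intervals everywhere are "normal-based": point estimate
± z(α/2) × bootstrap SD, with a seeded generator; resamples on which an
estimator is undefined (an empty arm) are redrawn and counted.

## Postestimation battery

- **Link test**: refit on (η, η²); Wald p of the squared term.
- **Box–Tidwell**: augmentation x·ln(x + shift) per continuous term, shift
  default +1 (scores contain zero), reported in the output.  This is a
  documented reading of the classical transformation for zero-valued
  scores; other software makes other choices, so third-party p-values may
  differ in the second decimal.
- **Hosmer–Lemeshow**: quantile bins of fitted probabilities with ties kept
  together (10 requested bins collapse to 8 on the grouped cohort's 9
  covariate patterns), df = bins − 2.
- **Pseudo-R²**: McFadden 1 − ll/ll₀; Cox–Snell 1 − exp(2(ll₀ − ll)/n);
  Nagelkerke = Cox–Snell rescaled by its maximum.
- **AUC**: concordance with half-credit for ties; DeLong variance for the
  interval and for the paired two-model contrast (df = 1).
- **Romano–Wolf**: stepdown max-statistic bootstrap adjustment; adjusted
  p-values dominate raw ones and are monotone in the stepdown order.
- **Model ranking**: deterministic by (AIC, BIC, −AUC), ties declared.

## Generalized ordered logit

Cumulative-logit parameterization P(Y > j | x) = expit(a_j + x'b_j),
j = 0..J−2.  Proportional odds constrains b_j = b; partial proportional
odds frees a user-chosen subset of terms (default: terms whose per-term
Brant p < 0.05).  Estimation is BFGS on the analytic-gradient likelihood;
the covariance is the inverse observed Hessian (finite differences at the
optimum).  Empty categories are merged into the adjacent lower category and
logged.  The relaxed model can produce negative fitted category
probabilities; they are clipped for reporting and flagged as a
model-validity warning.  The proportional route is cross-checked in the
test suite against an independent ordered-regression implementation
(statsmodels `OrderedModel`), agreeing in log-likelihood to 1e-4.

The Brant test fits the J−1 separate cutpoint logits, assembles the joint
covariance of their slopes from the Brant (1990) moment formulas, and
Wald-tests slope equality; df = p(J − 2), e.g. 10 for two predictors and
seven mRS categories.

## Kernel matching and treatment effects

The propensity model is a logit of treatment on covariates; matching runs
on its linear predictor (the log-odds "index") by default, the probability
scale being an option.  A unit's counterfactual is the Epanechnikov-kernel
weighted mean (K(u) = 0.75(1 − u²) on |u| < 1) of opposite-arm outcomes
within bandwidth; empty windows fall back to the single nearest opposite-arm
neighbour, counted and reported.  From the counterfactuals: ATT (treated),
ATC (controls), ATE (arm-size-weighted, equal to the mean unit effect and to
Y1 − Y0), and naive ATE from raw means.  `estimate_effects` refits the
propensity model inside each bootstrap resample.  On a randomized cohort
with a flat propensity all four estimands coincide to within matching
noise; on the reconstructed trial cohort |ATE − NATE| < 0.02 for every
binary outcome.

## Subgroup meta-analysis

Each score stratum is a "study".  Binary effects are risk differences with
variance p₁(1−p₁)/n₁ + p₀(1−p₀)/n₀ (no continuity correction; zero cells
keep the other arm's variance).  Continuous effects are Hedges' g with the
small-sample factor J = 1 − 3/(4·df − 1).  Pooling: Mantel–Haenszel fixed
effects (weights n₁n₀/(n₁+n₀), Greenland–Robins variance), inverse-variance
fixed effects, and iterative-REML random effects.  For the REML model I²
and H² use the Higgins–Thompson typical within-study variance
s² = (k−1)Σw / ((Σw)² − Σw²), w = 1/v, so I² = 100·τ²/(τ² + s²) and
H² = (τ² + s²)/s²; the Q-based form is reported for the fixed models.  The
identity I² = 100(1 − 1/H²) holds for every result.  The Egger screen is
the weighted regression of effect on its standard error (weights 1/v),
warning below 10 studies.  Strata with an empty arm are dropped and logged
(the HTI = 4 stratum of the reconstructed cohort, leaving k = 4 and
n = 236).

## Matching–smoothing HTE estimator

Stage 1 gives every unit a matched effect d_i (treated: own outcome minus
matched control mean; control: matched treated mean minus own outcome).
Stage 2 smooths d against the index with a degree-1 local polynomial under
the Epanechnikov kernel; the intercept of the weighted fit at x₀ is the
smoothed effect.  Score-level effects evaluate the smooth at each score's
fitted index (on the reconstructed cohort: −0.486 at HTI = 0 down to
−0.460 at HTI = 4) and convert the 95% band to a two-tailed p through its
implied z-score.

**Bandwidths.**  The rule-of-thumb width is h = c·min(sd, IQR/1.349)·n^(−1/5)
with the Epanechnikov constant c = 2.34, recorded in the diagnostics.  The
smoothing bandwidth is floored at twice the index span: with a
compact-support kernel on a near-degenerate index (a randomized trial), a
sub-span bandwidth zero-weights whole strata at the edges of the support
and destabilizes the edge variance, while at 2× span every unit keeps at
least 75% of the peak kernel weight and the fit is near-global — the
appropriate regime when the index carries almost no assignment information.

**The matching window is a real modelling choice** (`matching=` parameter):

- `'span'` (default) floors the matching bandwidth at the index span, so
  every counterfactual draws on all opposite-arm strata.  This is the
  configuration under which the package reproduces the published
  score-level effect table to within ~0.02 on every outcome.  Its known
  cost, demonstrated in the test suite's null experiments: when the
  propensity is flat and the outcome depends on the score, span-wide
  counterfactuals attenuate the outcome–score gradient differently in arms
  with different score distributions, tilting score-conditional effects
  even under a true null.
- `'rot'` keeps the plain rule-of-thumb width, which on a discrete score
  with a near-degenerate index is within-stratum matching.  Score-level
  effects are then unbiased under the null, at the price of noisier
  counterfactuals in sparse strata.

**Uncertainty** (`ci=` parameter): `'bootstrap'` (default, 1,000 seeded
resamples) resamples the matched (d_i, index_i) pairs and re-smooths at
fixed evaluation points — conditional on the matching stage, as
local-polynomial confidence bands conventionally are.  `'bootstrap_full'`
refits the propensity model, re-matches and re-smooths in every resample
and evaluates at the resample's own score-to-index map; because matched
effects share counterfactual errors within strata, only this variant is
calibrated for coverage statements.  In the package's null experiments
(`matching='rot'`, 200 resamples, 100 seeded cohorts of n = 238) the
full-bootstrap score-level 95% intervals cover zero for 96% of
score-level effects, while conditional and analytic bands undercover
(63–73%).  `'analytic'` provides fast WLS sandwich bands for exploration.

The practical reading: use the default configuration to mirror the
published analysis; use `matching='rot'` with `ci='bootstrap_full'` when
the score-level intervals are to be interpreted as frequentist confidence
statements.

## Synthetic-data generator

The generator draws treatment Bernoulli(91/238); an HTI stratum from the
per-arm stratum frequencies of the reconstructed cohort; then back-fills
(ASPECTS, NIHSS, HMCA, AF) by choosing uniformly among the component-band
decompositions of the drawn HTI and sampling integer values inside each
band, so recomputing HTI from covariates reproduces the drawn value
exactly.  Binary outcomes follow logits β₀ + β₁·arm + β₂·HTI with β taken
from fitting the reconstructed cohort at call time (never hard-coded);
symptomatic HT is drawn as a conditional sub-event of any HT, enforcing the
hierarchy record-wise.  Day-90 mRS follows a proportional-odds model whose
third cutpoint and slopes are calibrated so that P(mRS ≤ 2) equals the FFO
logit at every (arm, HTI) cell; the remaining cutpoints are fixed offsets
(−2.2, −1.0, 0, +1.2, +2.3, +3.6) around it, chosen once to give a
plausible day-90 disability spread with a small death fraction.  Remaining
covariates (age, glucose, onset-to-treatment, sex, pre-stroke mRS) are
drawn from plausible admission distributions but carry no outcome signal.

Not emulated: the joint distribution of DRAGON/SEDAN components with HTI,
covariate–outcome links beyond the score, dropout, and any within-stratum
outcome correlation.  Passing tests on these cohorts therefore validate the
estimators' statistical behaviour under the assumed logistic /
proportional-odds structure, not the full complexity of trial data.

`generate_null_cohort` zeroes every treatment coefficient (binary and
ordinal) while keeping score effects and per-arm score marginals — the
basis for type-I-error and coverage checks.

## Problem sizes and numerical choices

Simulation-based tests use cohorts of 238–50,000 units chosen per claim:
coefficient recovery at n = 50,000; calibration and error-rate checks at
40–200 replicates of moderate cohorts; the null-coverage experiment at 100
cohorts of the trial's own size with 200 bootstrap resamples each.  REML
iterates to relative tolerance 1e-10 (τ² kept nonnegative); the ordered
logit declares convergence at gradient norm 1e-8; tie-handling, degenerate
windows and empty categories follow the rules stated above and are always
logged rather than silent.

## Known limitations

- Score-conditional matching–smoothing effects under the default `'span'`
  matching inherit the attenuation tilt described above; the package keeps
  it as the default only because it is the configuration that reproduces
  the published tables, and documents the calibrated alternative.
- The conditional bootstrap's score-level p-value at the lowest risk
  stratum of the reconstructed cohort (symptomatic HT at HTI = 0) is
  smaller than the published one (0.009 vs 0.077): the published interval
  there is wider than any bootstrap design we could reconstruct; the
  discrepancy is confined to that cell and documented rather than tuned
  away.
- Grouped reconstruction carries binary outcomes only; ordinal-outcome
  stages are validated on synthetic cohorts.
- The Box–Tidwell zero-shift convention and the exact published bandwidth
  rule are tool-specific; values sensitive to them are matched within
  documented tolerance, with the bandwidth reported for audit.
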