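# htestrat

Risk-stratified heterogeneous-treatment-effect (HTE) analysis for acute
ischemic stroke cohorts treated with intravenous thrombolysis (IVT), with or
without a neuroprotective add-on.

## The problem

Trials of neuroprotective add-ons to IVT usually report a single average
treatment effect, yet the patients most likely to benefit are plausibly those
at the highest risk of hemorrhagic transformation (HT) of the infarct.
`htestrat` implements the full analysis chain for asking *who benefits*:

1. **Clinical HT-risk scoring.** The additive on-admission scores DRAGON
   (0–10), SEDAN (0–6) and HTI (0–8), computed from NIHSS, ASPECTS, the
   hyperdense-MCA sign, atrial fibrillation on ECG, glucose, age, pre-stroke
   mRS and onset-to-treatment time; HT risk graded low (HTI = 0), moderate
   (HTI = 1), high (HTI ≥ 2).
2. **Model selection.** Binary logits of an outcome on treatment plus each
   score, screened by a postestimation battery: link test, Box–Tidwell
   nonlinearity check, Hosmer–Lemeshow calibration, variance inflation,
   likelihood-ratio and Romano–Wolf-adjusted significance, McFadden /
   Cox–Snell / Nagelkerke pseudo-R², AIC/BIC and DeLong AUC contrasts.
3. **Conditional margins.** Per-score predicted probabilities and treatment
   contrasts with delta-method intervals, Šidák-corrected across the
   reported set.
4. **Ordinal outcome.** Generalized ordered logit for day-90 mRS under
   proportional and partial proportional odds, with the Brant test.
5. **Matched treatment effects.** Propensity-score Epanechnikov kernel
   matching on the log-odds index: ATE, ATT, ATC, naive ATE and potential
   outcome averages Y0/Y1 with seeded normal-based bootstrap intervals.
6. **Subgroup meta-analysis.** Each score stratum treated as a "study":
   Mantel–Haenszel fixed-effects risk differences, Hedges'-g inverse-variance
   pooling, REML random effects with Q, τ², I², H², and the Egger test.
7. **Matching–smoothing HTE.** Per-unit matched effects d_i smoothed against
   the propensity index with a degree-1 local polynomial (Epanechnikov
   kernel, rule-of-thumb bandwidth), read out at each score's index with
   z-based p-values.

Everything runs either on synthetic cohorts from the built-in generator or on
the grouped 238-patient MCA-stroke trial cohort reconstructed exactly from
published per-stratum counts (`printed_cerehetis_cohort()`).

## Worked example

```python
from htestrat import PipelineConfig, run_pipeline, render_report

bundle = run_pipeline(PipelineConfig(bootstrap_reps=200, seed=7))
print(render_report(bundle))
```

prints (abridged):

```
Endpoints (treated vs control):
  sht      3/91 vs 17/147  chi2=4.992 p=0.025
  any_ht   15/91 vs 37/147  chi2=2.484 p=0.115
  ffo      69/91 vs 98/147  chi2=2.252 p=0.133

Model fit (treatment + score logit):
  sht      AIC=117.78 BIC=128.20 AUC=0.83 McFadden=0.186

Heterogeneity (risk differences by score stratum):
  sht      k=4 REML tau2=0.00192 I2=35.8% H2=1.56
  any_ht   k=4 REML tau2=0.00140 I2=10.9% H2=1.12

Matching-smoothing treatment effects by score:
  sht      score=0 index=-0.486 TE=-0.045 CI=(-0.078, -0.012) p=0.007
  sht      score=4 index=-0.460 TE=-0.206 CI=(-0.407, -0.005) p=0.044
  ffo      score=0 index=-0.486 TE=+0.014 CI=(-0.051, +0.078) p=0.674
  ffo      score=4 index=-0.460 TE=+0.336 CI=(+0.133, +0.540) p=0.001
```

Reading: symptomatic HT occurred in 3.3% of treated vs 11.6% of control
patients (χ² p = 0.025).  The treatment + HTI logit discriminates
symptomatic HT well (AUC 0.83).  Treatment-effect heterogeneity across HTI
strata is moderate for symptomatic HT (I² = 35.8%) and mild for any HT
(I² = 10.9%).  The matching-smoothing readout shows the treatment effect
growing with HT risk: for favorable functional outcome the effect is neutral
at HTI = 0 (+1.4 points of probability, p = 0.67) and large at HTI = 4
(+33.6 points, p = 0.001).

A command-line interface mirrors the library:

```sh
htestrat report --fixture --reps 1000 --seed 7
htestrat simulate --n 238 --seed 1 --out cohort.csv
htestrat scores cohort.csv --out scored.csv
```

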