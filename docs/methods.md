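# Methods

This document is the package's scientific account of what it computes, the
parameter choices it ships with, and the design decisions behind the
synthetic cohort generator and the statistical machinery.

## 1. Creatinine-based AKI staging

All serum creatinine (SCr) is handled internally in µmol/l; mg/dl inputs are
converted by × 88.4.

A measurement is staged against the patient baseline by the KDIGO creatinine
criteria with half-open ratio bands:

| stage | condition |
|---|---|
| 1 | SCr/baseline ∈ [1.5, 2.0), or absolute rise ≥ 26.5 µmol/l |
| 2 | SCr/baseline ∈ [2.0, 3.0) |
| 3 | SCr/baseline ≥ 3.0, or SCr ≥ 353.6 µmol/l with stage 1 already met, or renal replacement therapy |

The ≥ 353.6 µmol/l promotion requires that stage 1 was met earlier in the
episode *or* by the same measurement through the ratio/absolute-rise rules; a
chronically elevated SCr that never satisfies a stage-1 criterion is not AKI.
Within an episode the stage is revised on a rolling basis as each
in-admission measurement arrives; the episode summary is the worst stage,
together with the triggering rule and the stage implied by the first
in-admission value (to separate community-acquired from hospital-acquired
injury). Patients on maintenance dialysis and episodes with no in-admission
SCr are excluded from staging with logged reason codes.

## 2. Baseline and CKD stage

The baseline is the mean of all SCr values 7–365 whole days before
admission ("whole days" uses floor of elapsed time / 24 h, so values in the
week before admission — which may already reflect the injury — are
excluded). When no such values exist, the baseline is estimated by solving
the 4-variable MDRD equation

eGFR = 175 · (SCr/88.4)^−1.154 · age^−0.203 · 0.742[female] · 1.212[black]

for SCr at an assumed eGFR of 75 ml/min/1.73 m². The inversion is
analytic: SCr = 88.4 · (eGFR / (175 · age^−0.203 · s · r))^(−1/1.154) with
s, r the sex and ethnicity multipliers.

CKD is staged from eGFR at baseline: G1 ≥ 90, G2 [60, 90), G3A [45, 60),
G3B [30, 45), G4 [15, 30), G5 < 15. The model covariate `ckd_3b_5`
(eGFR < 45) uses the measured pre-admission baseline when one exists; with
no baseline the patient is imputed to stage G2 and the indicator is 0. The
same convention is used consistently in staging, covariate extraction and
the generator, which is what makes exact round trips possible. Renal
recovery after an AKI episode is classified from post-discharge values
(7–90 whole days after discharge by default) relative to baseline.

## 3. Frailty and risk scores

The Nottingham Hip Fracture Score sums: age 66–85 → 3, age ≥ 86 → 4, and one
point each for male sex, admission abbreviated mental test score (AMTS) < 7,
haemoglobin < 100 g/l, institutional residence, malignancy and ≥ 2
comorbidities (range 0–10; missing AMTS or haemoglobin scores 0).

The primary AKI model ("Model 1") is a logistic regression:

logit P = −2.264 + 0.358·male + 0.266·ckd_3b_5 + 0.705·age_65_85
        + 1.023·age_gt_85 + 0.518·two_plus_comorbidities

`two_plus_comorbidities` counts diabetes, stroke history, cardiovascular
disease and chronic renal failure. A variant ("Model 2") replaces the age
bands with age in years (+0.028/year), and a companion model predicts
30-day mortality from AKI stage, AMTS < 7, male sex and age. Coefficients
ship as JSON resources under `hipaki/model_specs/`.

The integer point score is derived as round(4 × coefficient):
male 1, CKD 3B–5 1, age 65–85 3, age > 85 4, ≥ 2 comorbidities 2 (max 8).
Its predicted risk is 1/(1 + exp(2.264 − points/4)), which reproduces the
published risk column 0.09 … 0.43 for scores 0 … 8 after rounding to 2 dp.
Over all 24 feasible covariate patterns the pointwise rounding changes the
predicted probability by < 0.05.

Model fitting follows the original strategy: univariate screening (chi-squared
without continuity correction for binary predictors, Mann–Whitney for
continuous, retain p < 0.2), then backward elimination minimising AIC, with
ties broken by the larger Wald p-value. Non-convergent or separated fits
raise rather than silently returning garbage.

## 4. Validation statistics

* **Stratified split**: within each outcome stratum, round(ratio · n)
  episodes go to training (default ratio 0.66); strata with < 2 members go
  entirely to training with a warning.
* **AUROC**: DeLong's method via midranks and placement values; the point
  estimate is exactly the tie-corrected Mann–Whitney statistic (verified
  against brute-force pair counting), and the CI is the Wald interval on the
  AUC scale truncated to [0, 1].
* **Hosmer–Lemeshow**: Σ (O−E)²/(E(1−E/n_g)) over groups formed either from
  predicted-probability quantiles (ties assigned to the lower group) or from
  supplied labels such as the integer score; df = max(1, groups − 2).
  The χ²(g−2) reference is calibrated when the model was fitted on the data
  being tested; applied to externally fixed probabilities the statistic is
  stochastically larger, which is why the acceptance null simulation refits
  per replicate.
* **Proportion intervals**: Wilson score CI for a single proportion; Koopman
  chi-squared inversion for a ratio of proportions, solved with Brent root
  finding on the constrained-MLE score statistic. Note that statsmodels'
  `method="score"` additionally inflates the variance by N/(N−1)
  (Miettinen–Nurminen); this package implements the classical Koopman
  statistic, and the unit tests verify both that the bounds sit exactly on
  the χ²(1) critical value and that they match statsmodels once the
  inflation is accounted for.

## 5. Synthetic cohort generator

`generate_cohort` emulates an elderly hip-fracture population:

| parameter | default | rationale |
|---|---|---|
| age | Beta(2.866, 2.826) scaled to [60, 105] | calibrated so median ≈ 83 and IQR ≈ 76–89 |
| male fraction | 0.272 | population prevalence |
| CKD stage mix | G1 .14, G2 .42, G3A .24, G3B .13, G4 .06, G5 .01 | baseline renal function distribution |
| missing baseline | 0.28 | fraction with no pre-admission SCr |
| comorbidities | diabetes .138, stroke .13, CVD .55, renal .10 (independent) | marginal prevalences |
| AKI severity mix | stage 1 .707, 2 .199, 3 .094 | conditional stage distribution |
| measurement noise | lognormal, CV 0.05, mean 1 | assay/biological variability |

The generative order matters: demographics and comorbidities are drawn
first; a latent CKD stage fixes a true baseline SCr (via MDRD inversion at
an eGFR drawn within the stage band); pre-admission values are emitted with
noise; the **observed** baseline (the measured mean, or the imputed value
when the patient has no pre-admission values) is then computed exactly as
the analysis pipeline computes it, and the AKI outcome is drawn from
Model 1 applied to the covariates **as the pipeline will extract them**.
This closes the loop: refitting the model on a staged synthetic cohort is a
correctly specified estimation problem, and coefficient recovery is a
meaningful test of the whole pipeline rather than of the generator.

In-admission trajectories are constructed relative to the engine's own
baseline. Peak ratios are drawn inside safety margins within each KDIGO
band so that noise at the default CV cannot cross a band boundary;
measurement days are drawn strictly inside the admission window; stage-3
episodes use the ratio rule; very high baselines are rescaled (caps 165
µmol/l for stage-2 and 310 µmol/l for stage-1 assignments) so noisy peaks
stay below the 353.6 µmol/l promotion threshold — it is provable that these
caps cannot flip the `ckd_3b_5` indicator at any adult age/sex. At zero
noise the staging round trip is exact by construction; at the default noise
it remains exact because of the margins.

`parameter_recovery_experiment` repeats generate → stage → extract → refit
over many replicates and reports bias, RMSE and 95 %-Wald coverage per
coefficient. Replicates with separated fits (or any |coefficient| > 10) are
excluded and counted, since a quasi-separated replicate contributes an
arbitrarily large, meaningless estimate.

## 6. Known limitations

* The under-65 reference age class is rare (~1.2 % of a cohort, ~3 events
  per 3000 episodes). The age-band and intercept estimates consequently
  carry a small positive/negative finite-sample MLE bias (~+0.05 at
  n = 3000 over 100 replicates) with per-replicate SD ≈ 0.56; coverage
  stays nominal. This is a property of logistic MLE with a near-empty
  reference cell, not of the pipeline; coefficients with well-populated
  cells recover with |bias| ≈ 0.01.
* Comorbidities are generated independently; real comorbidity clustering
  would change the `two_plus_comorbidities` prevalence for the same
  marginals.
* The generator does not emulate community-acquired AKI timing structure,
  renal recovery trajectories, or mortality; those components are exercised
  with hand-constructed series in the unit tests instead.
* MDRD (coefficient 175) is used for consistency with the modelling
  conventions above rather than CKD-EPI; estimated baselines inherit its
  known biases at high GFR.
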