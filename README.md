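# hipaki

Acute kidney injury (AKI) staging, chronic kidney disease (CKD) grading and
risk modelling for elderly hip-fracture admissions.

Patients admitted with a fragility hip fracture are at high risk of
creatinine-defined AKI in the perioperative period. `hipaki` implements the
full analysis pipeline for studying that risk:

* **KDIGO creatinine staging** of serum-creatinine (SCr) time series against a
  per-patient baseline, with rolling stage revision and worst-of-episode
  summary;
* **baseline estimation**: the mean of SCr values 7–365 whole days before
  admission when available, otherwise an estimated value obtained by
  inverting the 4-variable MDRD equation at an assumed eGFR of
  75 ml/min/1.73 m²;
* **CKD staging** (G1–G5) from pre-admission or post-discharge eGFR, with
  stage G2 imputed when no baseline exists;
* **frailty scoring** via the Nottingham Hip Fracture Score (NHFS, 0–10);
* **logistic AKI risk models** with published coefficients, and a simplified
  integer point score (0–8) whose predicted risk is
  `1 / (1 + exp(2.264 − points/4))`;
* **validation statistics**: stratified train/test splits, DeLong AUROC with
  confidence interval, Hosmer–Lemeshow calibration, Wilson and Koopman
  intervals;
* a **synthetic cohort generator** calibrated to the same population, used
  for round-trip and parameter-recovery testing.

## The risk model

The primary AKI model is a logistic regression on five binary covariates:

```
logit P(AKI) = −2.264 + 0.358·male + 0.266·ckd_3b_5
             + 0.705·age_65_85 + 1.023·age_gt_85
             + 0.518·two_plus_comorbidities
```

where `ckd_3b_5` indicates baseline eGFR < 45 (CKD stages 3B–5) and
`two_plus_comorbidities` indicates at least two of diabetes, stroke history,
cardiovascular disease and chronic renal failure. Rounding `4 × coefficient`
gives the integer point score (1/1/3/4/2, maximum 8). See
[docs/methods.md](docs/methods.md) for the complete scientific account.

## Worked example

```python
from datetime import datetime, timedelta

from hipaki import (
    CreatinineSeries, establish_baseline, assess_episode, ckd_stage,
    builtin_model, model_predict, nh_risk,
)

admit = datetime(2010, 3, 14, 9, 30)
discharge = admit + timedelta(days=9)
series = CreatinineSeries(
    times=[admit - timedelta(days=40), admit + timedelta(hours=2),
           admit + timedelta(days=2), admit + timedelta(days=4),
           admit + timedelta(days=6)],
    values=[78.0, 84.0, 131.0, 172.0, 119.0],   # µmol/l
    admission_ts=admit, discharge_ts=discharge,
)

baseline = establish_baseline(series, age_years=81.0, sex="F")
print(f"baseline: {baseline.value:.1f} umol/l ({baseline.provenance.value})")

assessment = assess_episode(series, baseline)
print(f"worst stage: {assessment.worst_stage} "
      f"(admission stage {assessment.admission_stage})")

ckd = ckd_stage(series, age_years=81.0, sex="F")
print(f"CKD stage: {ckd.stage.value} (eGFR {ckd.egfr:.1f})")

cov = {"male": 0.0, "ckd_3b_5": 0.0, "age_65_85": 1.0, "age_gt_85": 0.0,
       "two_plus_comorbidities": 1.0}
p = model_predict(builtin_model("model1"), cov)
score = nh_risk(cov)
print(f"Model 1 risk: {p:.3f}; NH-RISK: {score.points} points "
      f"-> {score.predicted_risk:.2f}")
```

Output:

```
baseline: 78.0 umol/l (measured_mean)
worst stage: 2 (admission stage 0)
CKD stage: G2 (eGFR 61.5)
Model 1 risk: 0.261; NH-RISK: 5 points -> 0.27
```

The peak of 172 µmol/l is 2.2× the 78 µmol/l pre-admission baseline, hence
stage 2; the value at admission (84) triggers nothing, so the episode is
hospital-acquired.

## Command line

```sh
hipaki simulate --n 3000 --seed 1 --out-dir cohort/     # synthetic cohort
hipaki stage    --episodes cohort/episodes.csv --creatinine cohort/creatinine.csv --out staging.csv
hipaki score    --episodes cohort/episodes.csv --creatinine cohort/creatinine.csv --out scores.csv
hipaki fit      --episodes cohort/episodes.csv --creatinine cohort/creatinine.csv --out model.json
hipaki validate --episodes cohort/episodes.csv --creatinine cohort/creatinine.csv --seed 1 --out-dir report/
hipaki report   --report report/report.json
```

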