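{
  "name": "mortality30d",
  "description": "30-day mortality after hip fracture; banded age",
  "intercept": -3.786,
  "coefficients": {
    "male": 1.05,
    "ckd_3b_5": 0.717,
    "age_65_85": 0.981,
    "age_gt_85": 1.801,
    "amts_lt_7": 0.505,
    "aki": 1.008,
    "two_plus_comorbidities": 0.383
  },
  "age_handling": "banded"
}
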