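{
  "name": "model1",
  "description": "AKI risk after hip fracture; banded age, published coefficients",
  "intercept": -2.264,
  "coefficients": {
    "male": 0.358,
    "ckd_3b_5": 0.266,
    "age_65_85": 0.705,
    "age_gt_85": 1.023,
    "two_plus_comorbidities": 0.518
  },
  "age_handling": "banded"
}
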