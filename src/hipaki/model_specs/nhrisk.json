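{
  "name": "nhrisk",
  "description": "Simplified integer point score (0-8) for AKI risk; risk = 1/(1+exp(2.264 - points/4))",
  "intercept": -2.264,
  "divisor": 4,
  "points": {
    "male": 1,
    "ckd_3b_5": 1,
    "age_65_85": 3,
    "age_gt_85": 4,
    "two_plus_comorbidities": 2
  }
}
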