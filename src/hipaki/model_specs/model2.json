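{
  "name": "model2",
  "description": "AKI risk after hip fracture; continuous age per year",
  "intercept": -3.78,
  "coefficients": {
    "male": 0.37,
    "ckd_3b_5": 0.216,
    "age_per_year": 0.028,
    "two_plus_comorbidities": 0.521
  },
  "age_handling": "continuous"
}
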