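{
  "seed": 42,
  "out_dir": "results/demo",
  "n_respondents": 300,
  "n_items": 18,
  "n_factors": 3,
  "loading": 0.7,
  "outlier_fraction": 0.05,
  "outlier_magnitude": 4.0,
  "retest_reliability": 0.87,
  "criterion_validity": 0.65,
  "cohort_subjects": 300,
  "scale_effect": 0.8,
  "text_effect": 0.6,
  "prosody_effect": 1.0,
  "interview_noise": 0.05,
  "fusion_weights": [6, 1.5, 3.5],
  "threshold": 0.5
}
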