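{
  "description": "Risk-factor marginals of the randomised high-risk cohort (screen arm, n=2028), used as the synthetic-cohort generator's anchors.",
  "n": 2028,
  "male_fraction": 0.754,
  "age_mean": 67.1,
  "age_sd": 4.1,
  "never_smokers": 0.001,
  "current_smokers": 0.383,
  "ex_smokers": 0.616,
  "smoking_duration_10_19": 0.058,
  "smoking_duration_20_plus": 0.934,
  "asbestos_exposed": 0.376,
  "respiratory_disease_history": 0.521,
  "prior_solid_tumour": 0.186,
  "prior_blood_cancer": 0.0128,
  "family_history_lung_early": 0.106,
  "family_history_lung_late": 0.140,
  "mean_risk_score": 0.0887
}
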