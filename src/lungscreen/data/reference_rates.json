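{
  "description": "Printed outcome rates of the pilot (percentages, one decimal place), used as the expected values for the fixture-evaluation check.",
  "detection_rate": 2.1,
  "baseline_prevalence": 1.7,
  "mdt_referral_rate": 5.7,
  "false_positive_rate": 3.6,
  "interval_imaging_rate": 23.2,
  "stage_I_fraction": 66.7,
  "stage_I_II_fraction": 85.7,
  "surgical_resection_fraction": 83.3,
  "benign_resection_rate": 10.3,
  "further_ct_fraction": 47.7,
  "cat2_cancer_yield": 0.2,
  "cat4_cancer_yield": 50.0
}
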