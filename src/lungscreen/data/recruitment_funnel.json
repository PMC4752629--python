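{
  "description": "Participant flow of the pilot, first mailing to CT scan. The 6-subject gap between recruited (4061) and randomised (4055) is kept as printed, without reconciliation.",
  "approached": 247354,
  "non_responders": 148608,
  "negative_responders": 22788,
  "positive_responders": 75958,
  "high_risk": 8729,
  "second_questionnaire_returned": 5967,
  "excluded": 1291,
  "changed_mind_or_did_not_attend": 582,
  "declined_at_clinic": 33,
  "recruited": 4061,
  "randomised_total": 4055,
  "screen_arm": 2028,
  "control_arm": 2027,
  "scanned": 1994,
  "mean_risk_high": 0.088,
  "mean_risk_low": 0.010
}
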