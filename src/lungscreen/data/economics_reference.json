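{
  "description": "Published single-screen cost-effectiveness figures (UK pilot) and the US three-screen comparison, used as reference constants; the exchange rate is implied by the printed GBP/USD ICER pair.",
  "uk": {
    "yield_pct": 2.1,
    "screening_workup_cost_pp_gbp": 212,
    "net_treatment_cost_pp_gbp": 60,
    "qaly_gain_pp": 0.03,
    "icer_gbp_per_qaly": 8466,
    "icer_ci_gbp": [5542, 12569],
    "icer_usd_per_qaly": 13071,
    "icer_ci_usd": [8556, 19405],
    "perspective": "NHS (patient time and travel excluded)"
  },
  "us": {
    "yield_pct": 2.0,
    "screening_workup_cost_pp_usd": 1965,
    "net_treatment_cost_pp_usd": 175,
    "qaly_gain_pp": 0.02,
    "icer_usd_per_qaly": 81000,
    "perspective": "societal (patient time and travel included)"
  },
  "gbp_to_usd_rate": 1.5440
}
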