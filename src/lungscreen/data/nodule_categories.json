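{
  "description": "Per-subject nodule category counts of a 1994-subject single-screen LDCT pilot: subjects per category, MDT referrals and confirmed lung cancers.",
  "n_screened": 1994,
  "categories": {
    "1": {"subjects": 979, "mdt_referrals": 0, "cancers": 0},
    "2": {"subjects": 479, "mdt_referrals": 7, "cancers": 1},
    "3": {"subjects": 472, "mdt_referrals": 43, "cancers": 9},
    "4": {"subjects": 64, "mdt_referrals": 64, "cancers": 32}
  },
  "further_ct_subjects": 951,
  "benign_surgeries": 4,
  "cancers_baseline": 34,
  "cancers_12m": 8
}
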