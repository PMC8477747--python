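{
  "mouse": {
    "body_weight": 0.02,
    "liver_blood_flow": 1.8,
    "factor_mpbpk": 936,
    "factor_lymph": 1009,
    "factor_lbf": 889
  },
  "rat": {
    "body_weight": 0.25,
    "liver_blood_flow": 13.8,
    "factor_mpbpk": 130,
    "factor_lymph": 94,
    "factor_lbf": 116
  },
  "monkey": {
    "body_weight": 3.5,
    "liver_blood_flow": 158.0,
    "factor_mpbpk": 10,
    "factor_lymph": 10,
    "factor_lbf": 10
  },
  "human": {
    "body_weight": 70.0,
    "liver_blood_flow": 1600.0
  }
}
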