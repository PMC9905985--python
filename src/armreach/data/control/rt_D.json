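{
  "kp": [
    685.3755227687391,
    125.35176488262964,
    9.966688283434099
  ],
  "kd": [
    50.0,
    7.560497031751475,
    0.6603320756141294
  ],
  "n_pred": 15,
  "provenance": {
    "scenario": "D",
    "seed": 22,
    "population": 40,
    "generations": 30,
    "objective_mm": 0.025877434217642267,
    "seeded": true
  }
}
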