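{
  "kp": [
    819.1129409191328,
    189.9965827145366,
    14.804402189402984
  ],
  "kd": [
    50.0,
    7.262103774353331,
    0.5376046980263867
  ],
  "n_pred": 14,
  "provenance": {
    "scenario": "G",
    "seed": 25,
    "population": 40,
    "generations": 30,
    "objective_mm": 0.01576810609151072,
    "seeded": true
  }
}
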