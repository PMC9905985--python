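{
  "kp": [
    733.3323401940687,
    132.8997433937237,
    9.966688283434099
  ],
  "kd": [
    50.0,
    8.290646958454328,
    0.5376046980263867
  ],
  "n_pred": 15,
  "provenance": {
    "scenario": "A",
    "seed": 12,
    "population": 40,
    "generations": 60,
    "objective_mm": 0.02736655846196181,
    "seeded": true
  }
}
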