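{
  "kp": [
    609.1428016993582,
    131.890641346091,
    9.966688283434099
  ],
  "kd": [
    50.0,
    8.290646958454328,
    0.5376046980263867
  ],
  "n_pred": 15,
  "provenance": {
    "scenario": "C",
    "seed": 21,
    "population": 40,
    "generations": 30,
    "objective_mm": 0.027306269484097694,
    "seeded": true
  }
}
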