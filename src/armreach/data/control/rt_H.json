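{
  "kp": [
    869.3399715690435,
    249.50482913817967,
    12.083996437322547
  ],
  "kd": [
    50.0,
    10.330128494307058,
    0.5376046980263867
  ],
  "n_pred": 13,
  "provenance": {
    "scenario": "H",
    "seed": 26,
    "population": 40,
    "generations": 30,
    "objective_mm": 0.013543524919143094,
    "seeded": true
  }
}
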