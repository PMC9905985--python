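{
  "kp": [
    625.9792982902193,
    145.79918998756952,
    7.831124365541881
  ],
  "kd": [
    49.80057786948514,
    8.51140928703299,
    0.5376046980263867
  ],
  "n_pred": 15,
  "provenance": {
    "scenario": "B",
    "seed": 20,
    "population": 40,
    "generations": 30,
    "objective_mm": 0.02674834241727671,
    "seeded": true
  }
}
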