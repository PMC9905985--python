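{
  "kp": [
    818.2782007384377,
    123.04323363412885,
    9.966688283434099
  ],
  "kd": [
    47.49019758204477,
    5.795401975739025,
    0.5376046980263867
  ],
  "n_pred": 15,
  "provenance": {
    "scenario": "E",
    "seed": 23,
    "population": 40,
    "generations": 30,
    "objective_mm": 0.022416553923040552,
    "seeded": true
  }
}
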