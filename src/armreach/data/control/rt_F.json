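{
  "kp": [
    1000.0,
    155.6404327439276,
    13.76900150660664
  ],
  "kd": [
    50.0,
    7.36729344186269,
    0.5376046980263867
  ],
  "n_pred": 14,
  "provenance": {
    "scenario": "F",
    "seed": 24,
    "population": 40,
    "generations": 30,
    "objective_mm": 0.016202685066308453,
    "seeded": true
  }
}
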