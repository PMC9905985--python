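{
  "kp": [
    665.2559392025772,
    135.23429319839067,
    13.76900150660664
  ],
  "kd": [
    50.0,
    7.716455350449389,
    1.0071568541824831
  ],
  "n_pred": 15,
  "provenance": {
    "scenario": "no_passive",
    "seed": 11,
    "population": 40,
    "generations": 60,
    "objective_mm": 0.024465550398318055,
    "seeded": false
  }
}
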