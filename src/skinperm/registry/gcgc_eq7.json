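{
  "model_name": "gcgc_eq7",
  "intercept": -5.35,
  "coefficients": {
    "u1": 0.58,
    "u2": -3.51
  },
  "standard_errors": {
    "intercept": 0.07,
    "u1": 0.02,
    "u2": 0.19
  },
  "output_unit": "cm/s",
  "n_train": 79,
  "notes": "GC x GC retention-parameter LFER calibrated on 79 nonpolar chemicals with theoretically derived u1/u2; response was Zhang-model predicted log Kp."
}
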