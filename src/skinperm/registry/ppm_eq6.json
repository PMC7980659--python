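{
  "model_name": "ppm_eq6",
  "intercept": -5.46,
  "coefficients": {
    "log_kow": 0.47,
    "log_kaw": 0.13
  },
  "standard_errors": {
    "intercept": 0.09,
    "log_kow": 0.03,
    "log_kaw": 0.008
  },
  "output_unit": "cm/s",
  "n_train": 140,
  "notes": "PPM refit on the random 140-chemical training split (external validation variant of ppm_eq5)."
}
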