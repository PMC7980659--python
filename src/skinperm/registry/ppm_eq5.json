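{
  "model_name": "ppm_eq5",
  "intercept": -5.41,
  "coefficients": {
    "log_kow": 0.46,
    "log_kaw": 0.14
  },
  "standard_errors": {
    "intercept": 0.08,
    "log_kow": 0.03,
    "log_kaw": 0.007
  },
  "output_unit": "cm/s",
  "n_train": 175,
  "notes": "Two-parameter partitioning model (PPM) trained on the full 175-chemical neutral set with ASM-estimated log Kow / log Kaw. Output unit follows the training log Kp compilation (log10 cm/s)."
}
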