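{
  "model_name": "gcgc_eq8",
  "intercept": -5.34,
  "coefficients": {
    "u1": 0.58,
    "u2": -3.56
  },
  "standard_errors": {
    "intercept": 0.08,
    "u1": 0.03,
    "u2": 0.22
  },
  "output_unit": "cm/s",
  "n_train": 64,
  "notes": "GC x GC model refit on the random 64-chemical training split (external validation variant of gcgc_eq7)."
}
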