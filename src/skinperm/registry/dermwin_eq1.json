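{
  "model_name": "dermwin_eq1",
  "intercept": -2.8,
  "coefficients": {
    "log_kow": 0.66,
    "mw": -0.0056
  },
  "standard_errors": null,
  "output_unit": "cm/h",
  "n_train": null,
  "notes": "US-EPA DERMWIN (EPI Suite) skin permeability regression on log Kow and molecular weight; output in log10 cm/h."
}
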