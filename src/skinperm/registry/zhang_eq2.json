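{
  "model_name": "zhang_eq2",
  "intercept": -5.328,
  "coefficients": {
    "E": 0.137,
    "S": -0.604,
    "A": -0.338,
    "B": -2.428,
    "V": 1.797,
    "Jplus": -1.485,
    "Jminus": 2.471
  },
  "standard_errors": {
    "intercept": 0.071,
    "E": 0.082,
    "S": 0.057,
    "A": 0.094,
    "B": 0.09,
    "V": 0.079,
    "Jplus": 0.121,
    "Jminus": 0.113
  },
  "output_unit": "cm/s",
  "n_train": 274,
  "notes": "Zhang et al. Abraham-descriptor LFER for skin-water permeability; J+/J- are zero for neutral species; output in log10 cm/s."
}
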