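{
  "target_property": "log_kaw",
  "c": 0.994,
  "e": -0.577,
  "s": -2.549,
  "a": -3.813,
  "b": -4.841,
  "v": 0.869,
  "l": null,
  "source": "Abraham solvation equation for the air-water system (negated gas-to-water form). Externally sourced literature parameterization - verify against the cited solvation-chemistry literature before production use."
}
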