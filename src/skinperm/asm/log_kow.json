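{
  "target_property": "log_kow",
  "c": 0.088,
  "e": 0.562,
  "s": -1.054,
  "a": 0.034,
  "b": -3.46,
  "v": 3.814,
  "l": null,
  "source": "Abraham solvation equation for the octanol-water system (wet octanol). Externally sourced literature parameterization - verify against the cited solvation-chemistry literature before production use."
}
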