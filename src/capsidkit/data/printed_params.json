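{
  "genome_kbp": {
    "log10_a": 0.37,
    "se_log10_a": 0.10,
    "b": 1.47,
    "se_b": 0.09,
    "r_squared": 0.985,
    "n": 7
  },
  "diameter_nm": {
    "log10_a": 1.38,
    "se_log10_a": 0.34,
    "b": 0.52,
    "se_b": 0.03,
    "r_squared": 0.986,
    "n": 7
  }
}
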