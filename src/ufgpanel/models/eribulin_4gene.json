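{
  "drug": "eribulin",
  "terms": [
    {"gene": "CD70", "sign": 1, "divisor": 5.40},
    {"gene": "C5ORF38", "sign": -1, "divisor": 3.21},
    {"gene": "DAAM1", "sign": -1, "divisor": 2.06},
    {"gene": "IRX2", "sign": -1, "divisor": 3.30}
  ],
  "intercept": -8.54,
  "expression_units": "RPKM"
}
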