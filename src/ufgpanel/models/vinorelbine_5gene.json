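{
  "drug": "vinorelbine",
  "terms": [
    {"gene": "EPHA2", "sign": 1, "divisor": 11.55},
    {"gene": "NGEF", "sign": 1, "divisor": 7.75},
    {"gene": "SEPTIN10", "sign": 1, "divisor": 8.40},
    {"gene": "TRIP10", "sign": 1, "divisor": 4.25},
    {"gene": "VSIG10", "sign": 1, "divisor": 4.49}
  ],
  "intercept": -9.81,
  "expression_units": "RPKM"
}
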