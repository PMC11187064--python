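{
  "_comment": "AJCC tumor-stage strings collapsed to the ordinal 1-4 scale used as the Cox covariate. Sub-stages (A/B/C) collapse to their parent stage. Unknown strings map to missing, not errors. Edit to extend.",
  "STAGE I": 1, "STAGE IA": 1, "STAGE IB": 1, "STAGE IC": 1,
  "STAGE II": 2, "STAGE IIA": 2, "STAGE IIB": 2, "STAGE IIC": 2,
  "STAGE III": 3, "STAGE IIIA": 3, "STAGE IIIB": 3, "STAGE IIIC": 3,
  "STAGE IV": 4, "STAGE IVA": 4, "STAGE IVB": 4, "STAGE IVC": 4,
  "I": 1, "IA": 1, "IB": 1, "IC": 1,
  "II": 2, "IIA": 2, "IIB": 2, "IIC": 2,
  "III": 3, "IIIA": 3, "IIIB": 3, "IIIC": 3,
  "IV": 4, "IVA": 4, "IVB": 4, "IVC": 4,
  "1": 1, "2": 2, "3": 3, "4": 4
}
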