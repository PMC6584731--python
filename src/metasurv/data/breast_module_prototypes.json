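{
 "prototypes": [
  "ESR1",
  "ERBB2",
  "STAT1",
  "CASP3",
  "PLAU",
  "VEGF",
  "AURKA"
 ]
}
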