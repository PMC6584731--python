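{
 "genes": [
  "PTCH1",
  "TGFBR2",
  "CXCL14",
  "POSTN",
  "FAP",
  "NUAK1"
 ]
}
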