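{
 "name": "multicancer-53",
 "genes": [
  {
   "symbol": "ACKR3",
   "entrez_id": 57007,
   "direction": 1
  },
  {
   "symbol": "ACTN4",
   "entrez_id": 81,
   "direction": 1
  },
  {
   "symbol": "ARHGAP21",
   "entrez_id": 57584,
   "direction": 1
  },
  {
   "symbol": "C12orf49",
   "entrez_id": 79794,
   "direction": 1
  },
  {
   "symbol": "CACNB3",
   "entrez_id": 784,
   "direction": 1
  },
  {
   "symbol": "CAMK1D",
   "entrez_id": 57118,
   "direction": 1
  },
  {
   "symbol": "CAMSAP3",
   "entrez_id": 57662,
   "direction": -1
  },
  {
   "symbol": "CBFB",
   "entrez_id": 865,
   "direction": 1
  },
  {
   "symbol": "CDC37L1",
   "entrez_id": 55664,
   "direction": -1
  },
  {
   "symbol": "CDK19",
   "entrez_id": 23097,
   "direction": 1
  },
  {
   "symbol": "CLDN4",
   "entrez_id": 1364,
   "direction": 1
  },
  {
   "symbol": "CMBL",
   "entrez_id": 134147,
   "direction": 1
  },
  {
   "symbol": "COP1",
   "entrez_id": 64326,
   "direction": 1
  },
  {
   "symbol": "CRABP2",
   "entrez_id": 1382,
   "direction": 1
  },
  {
   "symbol": "CSE1L",
   "entrez_id": 1434,
   "direction": 1
  },
  {
   "symbol": "DARS2",
   "entrez_id": 55157,
   "direction": 1
  },
  {
   "symbol": "DDB2",
   "entrez_id": 1643,
   "direction": -1
  },
  {
   "symbol": "DPP4",
   "entrez_id": 1803,
   "direction": 1
  },
  {
   "symbol": "EGFR",
   "entrez_id": 1956,
   "direction": 1
  },
  {
   "symbol": "FAM189A2",
   "entrez_id": 29413,
   "direction": -1
  },
  {
   "symbol": "GSTZ1",
   "entrez_id": 2954,
   "direction": -1
  },
  {
   "symbol": "IMPDH1",
   "entrez_id": 3614,
   "direction": 1
  },
  {
   "symbol": "IRF3",
   "entrez_id": 3661,
   "direction": 1
  },
  {
   "symbol": "KATNAL1",
   "entrez_id": 84056,
   "direction": 1
  },
  {
   "symbol": "KIF11",
   "entrez_id": 3832,
   "direction": 1
  },
  {
   "symbol": "LATS2",
   "entrez_id": 26524,
   "direction": 1
  },
  {
   "symbol": "LOXL2",
   "entrez_id": 4017,
   "direction": 1
  },
  {
   "symbol": "MOCS1",
   "entrez_id": 4337,
   "direction": -1
  },
  {
   "symbol": "MREG",
   "entrez_id": 55686,
   "direction": -1
  },
  {
   "symbol": "MSC",
   "entrez_id": 9242,
   "direction": 1
  },
  {
   "symbol": "MYADM",
   "entrez_id": 91663,
   "direction": 1
  },
  {
   "symbol": "MYLK3",
   "entrez_id": 91807,
   "direction": -1
  },
  {
   "symbol": "NAE1",
   "entrez_id": 8883,
   "direction": 1
  },
  {
   "symbol": "NID2",
   "entrez_id": 22795,
   "direction": 1
  },
  {
   "symbol": "OPRM1",
   "entrez_id": 4988,
   "direction": 1
  },
  {
   "symbol": "PLAU",
   "entrez_id": 5328,
   "direction": 1
  },
  {
   "symbol": "PPEF1",
   "entrez_id": 5475,
   "direction": 1
  },
  {
   "symbol": "PWP1",
   "entrez_id": 11137,
   "direction": 1
  },
  {
   "symbol": "RALY",
   "entrez_id": 22913,
   "direction": 1
  },
  {
   "symbol": "RARRES3",
   "entrez_id": 5920,
   "direction": -1
  },
  {
   "symbol": "REX1BD",
   "entrez_id": 55049,
   "direction": 1
  },
  {
   "symbol": "SERPINB2",
   "entrez_id": 5055,
   "direction": 1
  },
  {
   "symbol": "SIPA1L2",
   "entrez_id": 57568,
   "direction": 1
  },
  {
   "symbol": "STK3",
   "entrez_id": 6788,
   "direction": 1
  },
  {
   "symbol": "TERF2",
   "entrez_id": 7014,
   "direction": 1
  },
  {
   "symbol": "TEX261",
   "entrez_id": 113419,
   "direction": 1
  },
  {
   "symbol": "TGFBI",
   "entrez_id": 7045,
   "direction": 1
  },
  {
   "symbol": "TNFRSF18",
   "entrez_id": 8784,
   "direction": -1
  },
  {
   "symbol": "TPD52L2",
   "entrez_id": 7165,
   "direction": 1
  },
  {
   "symbol": "UTP6",
   "entrez_id": 55813,
   "direction": 1
  },
  {
   "symbol": "ZFAND2A",
   "entrez_id": 90637,
   "direction": 1
  },
  {
   "symbol": "ZNF204P",
   "entrez_id": 7754,
   "direction": -1
  },
  {
   "symbol": "ZSCAN32",
   "entrez_id": 54925,
   "direction": -1
  }
 ]
}
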