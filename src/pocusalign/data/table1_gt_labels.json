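{
  "comment": "Majority-vote ground-truth fracture labels per sample (B=buckle, G=greenstick, N=no fracture)",
  "labels": {
    "0": "B",
    "1": "N",
    "2": "N",
    "3": "G",
    "4": "B",
    "5": "B",
    "6": "N",
    "7": "B",
    "8": "N",
    "9": "B",
    "10": "B"
  }
}
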