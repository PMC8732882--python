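{
  "comment": "Start codons and stop types of the 13 mitochondrial protein-coding genes in the Chinese pangolin reference annotation. Stop types: a complete triplet (TAA/AGA), or the incomplete stops 'T--' (trailing T) and 'TA-' (trailing TA) completed to UAA by polyadenylation.",
  "plan": {
    "ND1":  {"start": "ATG", "stop": "TAA"},
    "ND2":  {"start": "ATG", "stop": "T--"},
    "COX1": {"start": "ATG", "stop": "AGA"},
    "COX2": {"start": "ATG", "stop": "TAA"},
    "ATP8": {"start": "ATG", "stop": "TAA"},
    "ATP6": {"start": "ATG", "stop": "TAA"},
    "COX3": {"start": "ATG", "stop": "T--"},
    "ND3":  {"start": "ATA", "stop": "TA-"},
    "ND4L": {"start": "ATG", "stop": "TAA"},
    "ND4":  {"start": "ATG", "stop": "T--"},
    "ND5":  {"start": "ATA", "stop": "TAA"},
    "ND6":  {"start": "ATG", "stop": "AGA"},
    "CYTB": {"start": "ATG", "stop": "AGA"}
  }
}
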