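{
  "solid_glioma": {
    "vocabulary": ["CR", "PR", "MR", "SD", "PD", "NE"],
    "responders": ["CR", "PR"]
  },
  "hcl": {
    "vocabulary": ["CR_MRD_NEG", "CR_MRD_POS", "PR", "MR", "SD", "PD", "NE"],
    "responders": ["CR_MRD_NEG", "CR_MRD_POS", "PR"]
  },
  "mm": {
    "vocabulary": ["sCR", "CR", "VGPR", "PR", "MR", "SD", "PD", "NE"],
    "responders": ["sCR", "CR", "VGPR", "PR"]
  }
}
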