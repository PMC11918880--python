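{
  "_comment": "Default SATB2 DNA-binding domain coordinates, 1-based inclusive amino-acid intervals. CUT1 starts at amino acid 350; interval ends follow UniProt Q9UPW6 annotation and are replaceable configuration, not fixed constants. Arg389 and Arg429 fall in CUT1, Ser649 in the HOX homeodomain.",
  "cut1": [350, 437],
  "cut2": [482, 560],
  "hox": [614, 677]
}
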