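# Kasteren House C (two-story home) folded onto the four-place generic space.
places: [P1, P2, P3, P4]
sensors:
  S05: P1
  S29: P1
  S39: P1
  S07: P2
  S13: P2
  S18: P2
  S20: P2
  S21: P2
  S22: P2
  S23: P2
  S27: P2
  S30: P2
  S08: P3
  S10: P3
  S11: P3
  S16: P3
  S25: P3
  S35: P3
  S38: P3
  S06: P4
  S15: P4
  S28: P4
  S36: P4
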