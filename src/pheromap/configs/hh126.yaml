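# CASAS HH126 testbed folded onto the four-place generic space:
# P1 bedroom, P2 kitchen, P3 bathroom, P4 living room.
places: [P1, P2, P3, P4]
sensors:
  M010: P1
  M011: P1
  M013: P1
  M003: P2
  M004: P2
  M005: P2
  M015: P2
  M012: P3
  M014: P3
  M001: P4
  M002: P4
  M006: P4
  M007: P4
  M008: P4
  M009: P4
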