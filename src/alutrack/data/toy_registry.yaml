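# 120-nt toy consensus registry used by the test-suite and example configs.
# Same lineage shape as the Alu-like registry, at desk scale:
# AluT -> Tb8 -> {Tb9, Tb8a1 -> Tb10 -> Tb11}.
# Edit positions are on the PARENT consensus frame.
consensus:
  name: AluT
  sequence: >-
    CCGTACGAGTCTCTAGTAACACCGGCAGGGGAAGGGTGAACTGGGTGTGTTCTCCCCAAAAATAAAACTTTCTCCGGACCTTTAGTCACTGACTCCTAGAGAACAAAAGTATGTCCGATC
  a_rich_regions: [[58, 67]]
subfamilies:
  - name: Tb8
    parent: AluT
    edits:
      - {position: 80, kind: duplication, length: 7, label: Tb8_dup80_86}
  - name: Tb9
    parent: Tb8
    edits:
      - {position: 20, kind: substitution, ref: C, alt: G, label: Tb9_20C_G}
  - name: Tb8a1
    parent: Tb8
    edits:
      - {position: 108, kind: substitution, ref: G, alt: T, label: Tb8a1_108G_T}
  - name: Tb10
    parent: Tb8a1
    edits:
      - {position: 20, kind: substitution, ref: C, alt: G, label: Tb9_20C_G}
  - name: Tb11
    parent: Tb10
    edits:
      - {position: 42, kind: insertion, alt: T, label: Tb11_42insT}
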