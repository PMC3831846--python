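# Synthetic Alu-like consensus registry (Yb lineage layout).
#
# The base sequence is a SYNTHETIC 311-nt stand-in for the AluY consensus
# (the real consensus is not redistributed here); diagnostic sites sit at
# the canonical Yb-lineage coordinates so the subfamily chain
# AluY -> Yb8 -> {Yb9, Yb8a1 -> Yb10 -> Yb11} can be exercised end to end.
# Edit positions are interpreted on the PARENT consensus frame.
#
# Note on the Yb9 site: its position is quoted both as 174 and as 274 in
# the literature depending on numbering convention; 174 is used here and
# is user-editable.
consensus:
  name: AluY_syn
  sequence: >-
    GGTCCCCTACAGCGTGTGCCGGTGCTGACTAGCCGGGTGTTATACGCTCCGGAGAAAGGCACGCAGGCAGACCTCGCAGCGAGCTCTGGCTGCTCGGGCTGAAGGCGGCGCCACGATGCCGCGGTCAAAAATACAAAAAAAAGAACCCTATCTGTTGATACCAACGGTCCTAACATGCCAAGTATCCCACGCGAACCCGTGTCCAAGAGAAAATAAGCTACACGCGGGACGCCAGACGAGTGGCGATCGTTGGAGTAACCGGAATACAGGACTCTTTCTCGGAGAAAGTACTGCCCCTAACGATTAGGAAA
  a_rich_regions: [[127, 142]]
subfamilies:
  - name: Yb8
    parent: AluY_syn
    edits:
      - {position: 246, kind: duplication, length: 7, label: Yb8_dup246_252}
  - name: Yb9
    parent: Yb8
    edits:
      - {position: 174, kind: substitution, ref: C, alt: G, label: Yb9_174C_G}
  - name: Yb8a1
    parent: Yb8
    edits:
      - {position: 259, kind: substitution, ref: G, alt: A, label: Yb8a1_259G_A}
  - name: Yb10
    parent: Yb8a1
    edits:
      - {position: 174, kind: substitution, ref: C, alt: G, label: Yb9_174C_G}
  - name: Yb11
    parent: Yb10
    edits:
      - {position: 200, kind: insertion, alt: T, label: Yb11_200insT}
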