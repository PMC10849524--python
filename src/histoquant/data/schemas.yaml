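# Variable PTM search spaces per histone family.
# Sites are lysine residue numbers on the mature sequence; every site lists "un".
# H4 additionally carries a fixed N-terminal acetylation (see backbones.fasta),
# which is not part of the variable space and is excluded from bulk acetyl counts.
version: "1.0"
families:
  H4:
    backbone: H4
    sites:
      K5: [un, ac]
      K8: [un, ac]
      K12: [un, ac]
      K16: [un, ac]
      K20: [un, me1, me2, me3]
      K31: [un, ac]
  H3.2:
    backbone: H3.2_tail
    sites:
      K4: [un, me1, me2, me3]
      K9: [un, ac, me1, me2, me3]
      K14: [un, ac]
      K18: [un, ac]
      K23: [un, ac]
      K27: [un, ac, me1, me2, me3]
      K36: [un, me1, me2, me3]
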