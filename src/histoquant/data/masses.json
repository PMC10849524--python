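{
  "version": "1.0",
  "comment": "Element masses: monoisotopic from CODATA/AME; average = IUPAC conventional (abridged) atomic weights. Residue and PTM formulas are standard elemental compositions; all masses are derived from this single table.",
  "proton_da": 1.007276,
  "electron_da": 0.000549,
  "elements": {
    "H": {"mono": 1.007825, "avg": 1.008},
    "C": {"mono": 12.0, "avg": 12.011},
    "N": {"mono": 14.003074, "avg": 14.007},
    "O": {"mono": 15.994915, "avg": 15.999},
    "S": {"mono": 31.972071, "avg": 32.06}
  },
  "residues": {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1}
  },
  "ptms": {
    "ac": {"C": 2, "H": 2, "O": 1},
    "me1": {"C": 1, "H": 2},
    "me2": {"C": 2, "H": 4},
    "me3": {"C": 3, "H": 6}
  }
}
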