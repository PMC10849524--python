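>H4 mature murine histone H4 (initiator Met removed; N-terminus carries fixed acetylation)
SGRGKGGKGLGKGGAKRHRKVLRDNIQGITKPAIRRLARRGGVKRISGLIYEETRGVLKV
FLENVIRDAVTYTEHAKRKTVTAMDVVYALKRQGRTLYGFGG
>H3.2_tail murine histone H3.2 residues 1-50, GluC cleavage after the first Glu (E50)
ARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVKKPHRYRPGTVALRE
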