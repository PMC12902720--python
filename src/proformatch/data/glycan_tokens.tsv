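# Monosaccharide residue (dehydrated) compositions for glycan arithmetic.
# Glycans attach and extend by glycosidic bonds, so each token contributes
# its residue mass (free sugar minus water).
# columns: token<TAB>formula
Hex	C6H10O5
HexNAc	C8H13NO5
Fuc	C6H10O4
NeuAc	C11H17NO8
NeuGc	C11H17NO9
Pent	C5H8O4
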