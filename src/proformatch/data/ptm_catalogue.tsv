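# Starter modification catalogue. User-extensible: pass extra rows or a
# merged catalogue to the parser; this file is a representative subset, not
# an ontology.
# columns: name<TAB>category<TAB>targets<TAB>source_type<TAB>source_value
#   category: PTM | fixed | N-glycan
#   targets: comma list of one-letter residue codes and/or N-term, C-term
#   source_type: formula | glycan
Acetyl	PTM	K,N-term	formula	C2H2O
Phospho	PTM	S,T,Y	formula	HPO3
Methyl	PTM	K,R	formula	CH2
Dimethyl	PTM	K,R	formula	C2H4
Trimethyl	PTM	K	formula	C3H6
Oxidation	PTM	M,W	formula	O
Dioxidation	PTM	M,W	formula	O2
Formyl	PTM	K,N-term	formula	CO
Myristoyl	PTM	G,K,N-term	formula	C14H26O
Palmitoyl	PTM	C,K	formula	C16H30O
Crotonyl	PTM	K	formula	C4H4O
Succinyl	PTM	K	formula	C4H4O3
Malonyl	PTM	K	formula	C3H2O3
GG	PTM	K	formula	C4H6N2O2
Deamidated	PTM	N,Q	formula	H-1N-1O
Nitro	PTM	Y,W	formula	H-1NO2
PyroGlu	PTM	Q	formula	H-3N-1
Carbamidomethyl	fixed	C	formula	C2H3NO
Carboxymethyl	fixed	C	formula	C2H2O2
Propionamide	fixed	C	formula	C3H5NO
Pyridylethyl	fixed	C	formula	C7H7N
G0	N-glycan	N	glycan	HexNAc4Hex3
G0F	N-glycan	N	glycan	HexNAc4Hex3Fuc1
G1	N-glycan	N	glycan	HexNAc4Hex4
G1F	N-glycan	N	glycan	HexNAc4Hex4Fuc1
G2	N-glycan	N	glycan	HexNAc4Hex5
G2F	N-glycan	N	glycan	HexNAc4Hex5Fuc1
Man5	N-glycan	N	glycan	HexNAc2Hex5
Man6	N-glycan	N	glycan	HexNAc2Hex6
Man7	N-glycan	N	glycan	HexNAc2Hex7
Man8	N-glycan	N	glycan	HexNAc2Hex8
Man9	N-glycan	N	glycan	HexNAc2Hex9
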