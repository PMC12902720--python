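# Monoisotopic atomic masses (Da), IUPAC/AME values.
# columns: symbol<TAB>monoisotopic_mass
# Isotopes are written as mass-number prefix + symbol (13C, 2H, ...).
H	1.00782503207
C	12.0
N	14.0030740048
O	15.9949146196
S	31.97207100
P	30.97376163
Na	22.9897692809
K	38.96370668
Ca	39.96259098
Mg	23.98504170
Fe	55.93493750
Zn	63.92914220
Cu	62.92959750
Se	79.91652130
Cl	34.96885268
Br	78.91833710
I	126.90447300
F	18.99840322
2H	2.01410177785
13C	13.00335483780
15N	15.00010889890
18O	17.99916100
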