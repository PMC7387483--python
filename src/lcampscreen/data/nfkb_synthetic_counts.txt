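>KB_SYNTH synthetic NF-kB (kappaB) site count matrix
# SYNTHETIC matrix constructed from the canonical kappaB half-site consensus
# GGGRNNYYCC (REL-family binding sites). It is NOT a TRANSFAC or JASPAR matrix;
# it exists so the scanner runs out of the box. Supply your own matrix for real
# regulatory analysis.
A [  5  3  2 45 30 20  5  4  3  5 ]
C [  5  3  2  5 20 30 45 48 88 83 ]
G [ 85 91 94 45 30 20  5  4  4  5 ]
T [  5  3  2  5 20 30 45 44  5  7 ]
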