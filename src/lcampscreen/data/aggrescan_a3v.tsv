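# AGGRESCAN per-residue aggregation-propensity values (a3v), transcribed from
# Conchillo-Sole et al. (2007) BMC Bioinformatics 8:65, Table 1 (in vivo derived).
# Positive values mark aggregation-prone residues (I, F, V, L ...), negative values
# aggregation-resistant ones (P, D, E, R ...).
# residue	value
A	-0.036
R	-1.240
N	-0.713
D	-1.836
C	0.604
Q	-1.231
E	-1.412
G	-0.535
H	-1.033
I	1.822
L	1.380
K	-0.931
M	0.910
F	1.754
P	-2.303
S	-0.294
T	-0.159
W	1.037
Y	1.159
V	1.594
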