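"""Aggregation-propensity profile (Na4vSS) and the screening gate.

Profiles two synthesised Ciona peptides that were excluded by the
aggregation gate and one that passed it, using the per-residue a3v scale
with a 5-residue window.
"""

from lcampscreen import aggregation_profile, na4vss_gate
from lcampscreen.peptides import SYNTHETIC_PEPTIDES

for gene_id in ("KH.C1.640", "KH.L63.9", "KH.S1007.2"):
    seq = SYNTHETIC_PEPTIDES[gene_id]
    prof = aggregation_profile(seq, window=5)
    verdict = "pass" if na4vss_gate(prof) else "FAIL"
    print(f"{gene_id:11s} N={prof.length:2d} Na4vSS={prof.Na4vSS:7.1f}  gate[-30,30]: {verdict}")

# Na4vSS is the window-averaged aggregation propensity summed over the
# sequence and normalised per 100 residues. Strongly negative values mark
# highly charge-dominated, aggregation-averse peptides — in the screen these
# behaved like weak antimicrobials, so candidates outside [-30, 30] are
# dropped.
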