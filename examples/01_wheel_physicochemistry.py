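"""Helical-wheel physicochemistry of characterised Ciona antimicrobial peptides.

Recomputes mean hydrophobicity <H> (Fauchère–Pliska), Eisenberg hydrophobic
moment muH (δ = 100°) and net charge z for the seven peptides with published
wheel-calculator values, and prints both next to each other. Agreement to
the printed precision shows the engine reproduces the reference calculator.
"""

from lcampscreen import builtin_scale, profile
from lcampscreen.peptides import TABLE_PEPTIDES, TABLE_VALUES

scale = builtin_scale("fauchere_pliska")

print(f"{'gene':12s} {'H':>7s} {'muH':>7s} {'z':>4s}   published (H, muH, z)")
for gene_id, seq in TABLE_PEPTIDES.items():
    p = profile(seq, scale)
    h_ref, muh_ref, z_ref = TABLE_VALUES[gene_id]
    print(
        f"{gene_id:12s} {p.H:7.3f} {p.muH:7.3f} {p.z:+4d}   "
        f"({h_ref:+.3f}, {muh_ref:.3f}, {z_ref:+d})"
    )

# H is the mean residue hydrophobicity; muH measures how strongly hydrophobic
# residues cluster on one helix face (amphipathicity); z is the formal charge
# (K+R minus D+E). Cationic amphipathic antimicrobial helices sit around
# H 0–0.6, muH >= 0.1, z +3..+10.
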