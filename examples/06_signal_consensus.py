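"""Signal-peptide heuristics and the 80% majority-rule consensus.

Runs the rule-based signal-peptide stand-in on instantiations of the two
conserved LCAMP-family signal peptides, then rebuilds an 80% consensus from
a small constructed alignment, marking unconserved columns with X.
"""

from lcampscreen import consensus_sequence, heuristic_signal_peptide

family = [
    "MDRKIVFALALVAALAVSAAAA",
    "MDRKIVFALVLVSALSVSALSA",
    "MDRKIVFALLLVAVLAVSSAVA",
    "MDRKIVFALSLVLSLVVSAASA",
    "MDRKIVFALALVVALLVSSSLA",
]
mature = "KLAKKLLSSAKKLAQSLESNQTEEAESQDL"

for seq in family:
    pred = heuristic_signal_peptide(seq + mature)
    print(f"{seq}  secretory={pred.is_secretory}  cleavage_after={pred.cleavage_after}")

consensus = consensus_sequence(family, threshold=0.8)
print(f"\n80% consensus: {consensus}")
print(f"conserved columns: {sum(c != 'X' for c in consensus)}/{len(consensus)}")

# The heuristic requires the three classical signal-peptide regions: a
# non-negative n-region charge, a hydrophobic h-region, and small residues
# at the -3/-1 positions of the cleavage site. Consensus columns below the
# 80% threshold are emitted as X, matching how conserved LCAMP-family
# signal peptides are summarised.
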