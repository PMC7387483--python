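"""Published Ciona intestinalis LCAMP peptide sequences.

These are the mature/synthetic antimicrobial peptide sequences characterised
for C. intestinalis (Ghost-database gene identifiers), kept here so examples
and validation can run with no downloads. ``TABLE_PEPTIDES`` are the seven
peptides with published HeliQuest physicochemistry; ``SYNTHETIC_PEPTIDES``
is the full synthesised set, including the four aggregation-prone segments
that were excluded by the Na4vSS gate.
"""

# Gene id -> antimicrobial peptide sequence (physicochemistry table set)
TABLE_PEPTIDES = {
    "KH.C1.640": "WWLSRRRSSLFYWR",
    "KH.C7.94": "SRRRFDFSRRRIYVARRRSLAFAHRRR",
    "KH.S1531.4": "TINKKFRWHGKRKWWLRFVKQ",
    "KH.S908.1": "KGGKFLNFLKKAAKVGAKVGMAALG",
    "KH.S921.1": "KLKTWPKNYWRKVWSKKNWRKFVKKFKHW",
    "KH.C1.100": "WRSLGRTLLRLSHALKPLARRSGW",  # Ci-MAM-A
    "KH.C1.453": "ALRSAVRTVARVGRAVLPHVAI",  # Ci-PAP-A
}

#: Published HeliQuest values (hydrophobicity, hydrophobic moment, net
#: charge) for the peptides above — used as cross-validation targets.
TABLE_VALUES = {
    "KH.C1.640": (0.624, 0.170, 4),
    "KH.C7.94": (-0.033, 0.118, 11),
    "KH.S1531.4": (0.316, 0.151, 8),
    "KH.S908.1": (0.294, 0.319, 6),
    "KH.S921.1": (0.272, 0.141, 12),
    "KH.C1.100": (0.428, 0.380, 6),
    "KH.C1.453": (0.449, 0.350, 4),
}

# Chemically synthesised peptide set (assay inputs); the last four listed
# here were excluded by the aggregation gate (published Na4vSS: KH.C1.365
# -32.9, KH.L63.9 -65.6, KH.S1007.2 -48.1, KH.S930.2 -44.4, computed by the
# AGGRESCAN server on the precursor inputs of the original screen).
SYNTHETIC_PEPTIDES = {
    "KH.C1.640": "WWLSRRRSSLFYWR",
    "KH.C7.94": "SRRRFDFSRRRIYVARRRSLAFAHRRR",
    "KH.S1531.4": "TINKKFRWHGKRKWWLRFVKQ",
    "KH.S908.1": "KGGKFLNFLKKAAKVGAKVGMAALG",
    "KH.S921.1": "KLKTWPKNYWRKVWSKKNWRKFVKKFKHW",
    "KH.C1.365": "RRRRRIAARIGSGVAQTGGELI",
    "KH.L63.9": "FRRRRRRRRHWHHHHHYHYHHHRRRRRRRRRW",
    "KH.S1007.2": "FGRRRRVPGRRRRWWNERAMNEI",
    "KH.S930.2": "AERLMRKAAKDHWSNKMAKDVIWWEQ",
}
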