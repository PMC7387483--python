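"""Sequence and report I/O for the screening funnel.

FASTA parsing goes through Biopython's ``SeqIO``; this module adds the
validation and conventions the funnel relies on: uppercase sequences, the
first header token as the record ID, a protein alphabet that admits ``X``
only as an explicitly flagged unknown, and the upstream-DNA convention that
the last base of a record sits at position −1 relative to the A of the
initiator ATG.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO

log = logging.getLogger(__name__)

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = frozenset("ACGTN")

#: Upstream records longer than this draw a warning (screens use < 2 kb).
MAX_UPSTREAM_LEN = 2000


class FastaError(ValueError):
    """Malformed FASTA input."""


class AlphabetError(ValueError):
    """A sequence contains characters outside the configured alphabet."""


@dataclass(frozen=True)
class PeptideRecord:
    """One protein/peptide sequence under screening."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: illegal protein character(s) {sorted(bad)}"
            )
        if not self.sequence:
            raise AlphabetError(f"record {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def has_unknown(self) -> bool:
        """True when the sequence contains ``X`` (fails all physicochemical gates)."""
        return "X" in self.sequence


@dataclass(frozen=True)
class UpstreamRecord:
    """Upstream DNA, 5'→3', ending at the base immediately before ATG.

    The last base is position −1 relative to the A of the initiator codon.
    """

    gene_id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"record {self.gene_id!r}: illegal DNA character(s) {sorted(bad)}"
            )
        if not self.sequence:
            raise AlphabetError(f"record {self.gene_id!r}: empty sequence")
        if len(self.sequence) > MAX_UPSTREAM_LEN:
            warnings.warn(
                f"upstream record {self.gene_id!r} is {len(self.sequence)} bp "
                f"(> {MAX_UPSTREAM_LEN}); scanning proceeds on the full sequence",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path, alphabet: str = "protein"):
    """Read a FASTA file into :class:`PeptideRecord` or :class:`UpstreamRecord` lists.

    Parameters
    ----------
    path:
        FASTA file path.
    alphabet:
        ``"protein"`` (returns ``PeptideRecord``) or ``"dna"``
        (returns ``UpstreamRecord``).

    IDs are the first whitespace-delimited header token; the full header is
    kept as ``description``. Sequences are uppercased. Illegal characters
    raise :class:`AlphabetError` naming the record and character.
    """
    if alphabet not in ("protein", "dna"):
        raise ValueError(f"alphabet must be 'protein' or 'dna', not {alphabet!r}")
    records = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # Biopython signals malformed entries this way
        raise FastaError(f"{path}: {exc}") from exc
    if not parsed:
        # distinguish empty file from a file with no '>' at all
        with open(path) as handle:
            head = handle.read(1 << 12)
        if head.strip() and not head.lstrip().startswith(">"):
            raise FastaError(f"{path}: not FASTA (first non-blank character is not '>')")
    for entry in parsed:
        seq = str(entry.seq).upper()
        if alphabet == "protein":
            records.append(PeptideRecord(entry.id, seq, description=entry.description))
        else:
            records.append(UpstreamRecord(entry.id, seq, description=entry.description))
    return records


def write_fasta(records: Iterable[PeptideRecord | UpstreamRecord], path) -> None:
    """Write records back to FASTA (IDs and sequences round-trip exactly)."""
    with open(path, "w") as handle:
        for rec in records:
            rec_id = rec.id if isinstance(rec, PeptideRecord) else rec.gene_id
            handle.write(f">{rec_id}\n{rec.sequence}\n")


def length_filter(
    records: Sequence[PeptideRecord], min_len: int, max_len: int
) -> list[PeptideRecord]:
    """Keep records with ``min_len <= length <= max_len`` (both inclusive).

    The screen's first gate; defaults in the pipeline are 50–100 residues,
    the size range of known LCAMP precursors. Order is preserved and the
    operation is idempotent.
    """
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) > max_len ({max_len})")
    return [r for r in records if min_len <= r.length <= max_len]


REPORT_COLUMNS = [
    "id",
    "stage_reached",
    "window_start",
    "window_end",
    "window_seq",
    "H",
    "muH",
    "z",
    "Na4vSS",
    "anionic_start",
    "anionic_end",
    "verdict",
]


def write_report(candidates, path) -> None:
    """Write candidate reports as TSV, one row per record, in input order.

    Coordinates in the report are 1-based inclusive on the full precursor;
    internal coordinates everywhere else in the package are 0-based
    half-open.
    """
    import pandas as pd

    rows = [c.report_row() for c in candidates]
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)
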