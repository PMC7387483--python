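"""Match-style position-weight-matrix scanning of upstream DNA.

The scanner looks for transcription-factor binding sites (the screening
application is NF-κB-like sites upstream of antimicrobial-peptide genes)
using the information-weighted similarity scores of the Match algorithm:

* per-position information ``I(i) = Σ_b f(i,b)·ln(4·f(i,b))`` (natural log,
  ``0·ln 0 = 0``),
* ``matrix similarity = (Current − Min) / (Max − Min)`` where
  ``Current = Σ_i I(i)·f(i, b_i)`` for the scanned word and Min/Max use the
  per-position minimal/maximal frequencies,
* ``core similarity`` — the same score restricted to the 5 consecutive
  positions of highest summed information.

Hits must pass both cut-offs (defaults 0.75 core, 0.8 matrix). Positions are
reported as negative offsets from the initiator ATG: the last base of an
upstream record is −1, and a hit's ``position`` is the offset of its 5'-most
base on the input (+) strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import UpstreamRecord

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

CORE_LEN = 5


class PWMError(ValueError):
    """Malformed or degenerate position-weight matrix."""


@dataclass(frozen=True)
class PWM:
    id: str
    freqs: np.ndarray  # L x 4, rows sum to 1
    info: np.ndarray = field(init=False)  # per-position information (nats)
    core_positions: tuple = field(init=False)  # contiguous run of 5 positions

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        if freqs.ndim != 2 or freqs.shape[1] != 4:
            raise PWMError("PWM must be an L x 4 matrix over A,C,G,T")
        if freqs.shape[0] < CORE_LEN:
            raise PWMError(f"PWM must have at least {CORE_LEN} positions")
        if not np.allclose(freqs.sum(axis=1), 1.0, atol=1e-6):
            raise PWMError("PWM rows must each sum to 1")
        object.__setattr__(self, "freqs", freqs)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(freqs > 0, freqs * np.log(4.0 * freqs), 0.0)
        info = terms.sum(axis=1)
        object.__setattr__(self, "info", info)
        sums = np.convolve(info, np.ones(CORE_LEN), mode="valid")
        start = int(np.argmax(sums))  # argmax takes the leftmost maximum
        object.__setattr__(self, "core_positions", tuple(range(start, start + CORE_LEN)))

    def __len__(self) -> int:
        return self.freqs.shape[0]

    @property
    def consensus(self) -> str:
        """Per-position argmax word (scores exactly 1.0 on both similarities)."""
        return "".join(BASES[i] for i in self.freqs.argmax(axis=1))

    @property
    def anticonsensus(self) -> str:
        """Per-position argmin word (matrix similarity exactly 0)."""
        return "".join(BASES[i] for i in self.freqs.argmin(axis=1))


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    position: int  # negative offset from ATG of the site's 5'-most base (+ strand)
    strand: str  # "+" | "-"
    core_sim: float
    matrix_sim: float


def load_pwm(path, pseudocount: float = 0.01) -> PWM:
    """Load a count or frequency matrix from JASPAR-like or plain matrix text.

    Accepted layouts:

    * JASPAR-like: optional ``>id`` header, then four rows
      ``A [ 1 2 3 ... ]`` / ``C [...]`` / ``G [...]`` / ``T [...]``;
    * plain/TRANSFAC-like: a header row naming A C G T (optionally after a
      position column), then one row of four numbers per position.

    Count matrices (rows not summing to 1) are normalised per position after
    adding a pseudocount of *pseudocount* × (position total) spread evenly
    over the four bases. Frequency matrices are used as-is.
    """
    with open(path) as handle:
        lines = [ln.strip() for ln in handle if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise PWMError(f"{path}: empty matrix file")
    pwm_id = "PWM"
    if lines[0].startswith(">"):
        pwm_id = lines[0][1:].split()[0] or "PWM"
        lines = lines[1:]

    by_base: dict[str, list[float]] = {}
    rows: list[list[float]] = []
    for line in lines:
        token = line.split()[0].upper().rstrip(":")
        tail = line.replace("[", " ").replace("]", " ").split()[1:]
        if token in ("A", "C", "G", "T") and tail:
            try:
                by_base[token] = [float(tok) for tok in tail]
                continue
            except ValueError:
                pass  # e.g. an "A C G T" column-header line
        vals = []
        for tok in line.replace("[", " ").replace("]", " ").split():
            try:
                vals.append(float(tok))
            except ValueError:
                pass
        if len(vals) >= 4:
            rows.append(vals[-4:])  # drop a leading position index if present
    if len(by_base) == 4:
        matrix = np.array([by_base[b] for b in BASES], dtype=float).T
    elif rows:
        matrix = np.array(rows, dtype=float)
    else:
        raise PWMError(f"{path}: could not parse a matrix")

    if matrix.shape[0] < CORE_LEN:
        raise PWMError(f"{path}: matrix has fewer than {CORE_LEN} positions")
    row_sums = matrix.sum(axis=1)
    if np.any(row_sums <= 0):
        raise PWMError(f"{path}: matrix has an all-zero position")
    if np.allclose(row_sums, 1.0, atol=1e-3):
        freqs = matrix / matrix.sum(axis=1, keepdims=True)
    else:
        totals = row_sums[:, None]
        freqs = (matrix + pseudocount * totals / 4.0) / (totals * (1.0 + pseudocount))
    return PWM(pwm_id, freqs)


def _score_word(word: str, pwm: PWM, positions) -> float:
    """Information-weighted similarity over *positions* in [0, 1]."""
    info = pwm.info[list(positions)]
    f = pwm.freqs[list(positions)]
    current = 0.0
    for k, i in enumerate(positions):
        current += info[k] * f[k, _BASE_INDEX[word[i]]]
    mn = float((info * f.min(axis=1)).sum())
    mx = float((info * f.max(axis=1)).sum())
    if mx == mn:
        raise PWMError("degenerate PWM: Max == Min (no informative position)")
    return (current - mn) / (mx - mn)


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def match_scan(
    upstream: UpstreamRecord,
    pwm: PWM,
    core_cutoff: float = 0.75,
    matrix_cutoff: float = 0.8,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Scan an upstream record for PWM hits passing both cut-offs.

    Every offset is evaluated on the + strand and (by default) on the
    reverse complement; windows containing ``N`` are skipped. Hit positions
    are negative offsets from ATG of the window's 5'-most base in input
    coordinates regardless of strand.
    """
    seq = upstream.sequence
    L = len(pwm)
    n = len(seq)
    all_positions = list(range(L))
    hits: list[MotifHit] = []
    strands = ["+", "-"] if both_strands else ["+"]
    for j in range(n - L + 1):
        window = seq[j : j + L]
        if "N" in window:
            continue
        for strand in strands:
            word = window if strand == "+" else _revcomp(window)
            matrix_sim = _score_word(word, pwm, all_positions)
            if matrix_sim < matrix_cutoff:
                continue
            core_sim = _score_word(word, pwm, list(pwm.core_positions))
            if core_sim < core_cutoff:
                continue
            hits.append(
                MotifHit(
                    gene_id=upstream.gene_id,
                    position=j - n,
                    strand=strand,
                    core_sim=core_sim,
                    matrix_sim=matrix_sim,
                )
            )
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def scan_upstream_set(
    upstreams,
    pwm: PWM,
    core_cutoff: float = 0.75,
    matrix_cutoff: float = 0.8,
) -> pd.DataFrame:
    """Scan many upstream records; returns a tidy hit table.

    Columns: gene_id, position, end, strand, core_sim, matrix_sim; ordered
    by gene id then ascending position. ``end`` is the (negative) offset one
    past the site's 3'-most base, so a site occupies [position, end).
    """
    rows = []
    for rec in upstreams:
        for hit in match_scan(rec, pwm, core_cutoff, matrix_cutoff):
            rows.append(
                {
                    "gene_id": hit.gene_id,
                    "position": hit.position,
                    "end": hit.position + len(pwm),
                    "strand": hit.strand,
                    "core_sim": round(hit.core_sim, 3),
                    "matrix_sim": round(hit.matrix_sim, 3),
                }
            )
    frame = pd.DataFrame(
        rows, columns=["gene_id", "position", "end", "strand", "core_sim", "matrix_sim"]
    )
    return frame.sort_values(["gene_id", "position"], kind="stable").reset_index(drop=True)


def format_hits_table(upstreams, hits: pd.DataFrame) -> pd.DataFrame:
    """Render one row per gene; genes without hits are marked ``N.D.``.

    Sites are rendered as ``start/end`` pairs of negative offsets from ATG
    (both inclusive, 5' base first).
    """
    rendered = []
    for rec in upstreams:
        sub = hits[hits.gene_id == rec.gene_id]
        if sub.empty:
            rendered.append({"gene_id": rec.gene_id, "sites": "N.D."})
        else:
            spans = ", ".join(
                f"{int(r.position)}/{int(r.end) - 1}" for r in sub.itertuples()
            )
            rendered.append({"gene_id": rec.gene_id, "sites": spans})
    return pd.DataFrame(rendered, columns=["gene_id", "sites"])
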