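"""Deterministic synthetic proteomes for exercising the funnel offline.

The generator plants LCAMP-like precursors with the canonical architecture
(consensus-derived signal peptide → cationic amphipathic 18-mer built by
placing K/R on one helical-wheel face → anionic helical tail) and
stage-labelled decoys, each constructed to pass every stage before its
labelled one and fail exactly there. Rather than trusting construction
arithmetic, every generated record is verified against the real pipeline
(`run_funnel`) and regenerated with a fresh sub-seed on failure, so fixtures
remain valid if scales or thresholds change.

Everything is a pure function of the seed.
"""

from __future__ import annotations

import logging
from contextlib import contextmanager
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motif import PWM
from .pipeline import ScreenConfig, run_funnel
from .seqio import PeptideRecord, UpstreamRecord

_pipeline_log = logging.getLogger("lcampscreen.pipeline")


@contextmanager
def _quiet_pipeline():
    """Silence per-stage logging during internal verify-and-retune calls."""
    old = _pipeline_log.level
    _pipeline_log.setLevel(logging.ERROR)
    try:
        yield
    finally:
        _pipeline_log.setLevel(old)

#: 80%-majority consensus signal peptides of the two conserved LCAMP
#: families (X = unconserved position, filled from small/hydrophobic
#: residues at generation time).
SIGNAL_CONSENSI = ("MDRKIVFALXLVXXLXVSXXXA", "MNKSALLXLLXXGLXVLXEXXXA")
X_FILL = "AVLS"

HELIX_LEN = 18
#: Wheel positions (δ=100°) within ±90° of azimuth 0 — the polar face.
POLAR_FACE = tuple(
    i for i in range(HELIX_LEN) if min((i * 100) % 360, 360 - (i * 100) % 360) <= 90
)
APOLAR_FACE = tuple(i for i in range(HELIX_LEN) if i not in POLAR_FACE)

MAX_ATTEMPTS = 200

DECOY_STAGES = (
    "length",
    "secretory",
    "tm",
    "cys",
    "amphipathic",
    "helical",
    "aggregation",
)


class GenerationError(RuntimeError):
    """The bounded verify-and-retune loop failed to produce a valid record."""


@dataclass(frozen=True)
class FixtureSpec:
    n_planted: int = 5
    decoy_stages: tuple = DECOY_STAGES
    seed: int = 0
    background: str = "uniform"  # residue background for filler stretches

    def __post_init__(self) -> None:
        if self.n_planted < 0:
            raise ValueError("n_planted must be >= 0")
        if self.background != "uniform":
            raise ValueError("only the uniform residue background is implemented")


def _fill_consensus(rng: np.random.Generator, template: str) -> str:
    return "".join(rng.choice(list(X_FILL)) if c == "X" else c for c in template)


def _wheel_segment(rng: np.random.Generator, polar_pool, apolar_pool, n_charged) -> str:
    """18-mer with charged residues on the polar wheel face."""
    seg = [""] * HELIX_LEN
    polar_positions = list(POLAR_FACE)
    rng.shuffle(polar_positions)
    for pos in polar_positions[:n_charged]:
        seg[pos] = str(rng.choice(polar_pool["charged"]))
    for pos in polar_positions[n_charged:]:
        seg[pos] = str(rng.choice(polar_pool["neutral"]))
    for pos in APOLAR_FACE:
        seg[pos] = str(rng.choice(apolar_pool))
    return "".join(seg)


def _cationic_helix(rng: np.random.Generator) -> str:
    n_charged = int(rng.integers(4, 7))  # net charge +4..+6
    return _wheel_segment(
        rng,
        {"charged": list("KKKR"), "neutral": list("STNQ")},
        list("LLAAAF"),
        n_charged,
    )


#: Length of the neutral linker between the cationic helix and the anionic
#: tail. 18-residue windows spanning the junction would otherwise merge the
#: two regions into overlapping segments; ~15 neutral residues keep the
#: most C-terminal anionic segment clear of the cationic one.
LINKER_LEN = 15


def _linker(rng: np.random.Generator, n: int = LINKER_LEN) -> str:
    return "".join(rng.choice(list("AQSTN"), size=n))


def _anionic_tail(rng: np.random.Generator) -> str:
    # acidic residues spread over the whole helix (weak amphipathicity keeps
    # the moment inside the anionic box's muH <= 0.5)
    n_acid = int(rng.integers(5, 7))
    seg = list(rng.choice(list("ASLQSN"), size=HELIX_LEN))
    positions = rng.choice(HELIX_LEN, size=n_acid, replace=False)
    for pos in positions:
        seg[pos] = str(rng.choice(list("EED")))
    return "".join(seg)


def _subseed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def _funnel_stage(sequence: str, rec_id: str, config: ScreenConfig) -> str:
    with _quiet_pipeline():
        reports, _ = run_funnel([PeptideRecord(rec_id, sequence)], config)
    return reports[0].stage_reached


def make_precursor(
    seed: int, rec_id: str = "planted", config: ScreenConfig | None = None
) -> tuple[PeptideRecord, dict]:
    """Generate one LCAMP-like precursor that survives the whole funnel.

    Returns the record and a truth annotation with the construction
    intervals (0-based half-open on the precursor).
    """
    config = config or ScreenConfig()
    rng = np.random.default_rng(seed)
    for _ in range(MAX_ATTEMPTS):
        sub = np.random.default_rng(_subseed(rng))
        signal = _fill_consensus(sub, SIGNAL_CONSENSI[int(sub.integers(2))])
        helix = _cationic_helix(sub)
        linker = _linker(sub)
        tail = _anionic_tail(sub)
        sequence = signal + helix + linker + tail
        record = PeptideRecord(rec_id, sequence)
        with _quiet_pipeline():
            reports, _ = run_funnel([record], config)
        rep = reports[0]
        if rep.is_candidate and rep.architecture_ok:
            tail_start = len(signal) + len(helix) + len(linker)
            truth = {
                "signal": (0, len(signal)),
                "cationic": (len(signal), len(signal) + len(helix)),
                "anionic": (tail_start, len(sequence)),
            }
            return record, truth
    raise GenerationError(f"no valid precursor after {MAX_ATTEMPTS} attempts (seed {seed})")


def _breaker_helix(rng: np.random.Generator) -> str:
    """In the cationic box but a poor helix former (G/P/V-rich face)."""
    return _wheel_segment(
        rng,
        {"charged": list("KKKR"), "neutral": list("SSTT")},
        list("GPPVV"),
        int(rng.integers(4, 7)),
    )


def _sticky_helix(rng: np.random.Generator) -> str:
    """In the cationic box and helical but extremely aggregation-prone."""
    return _wheel_segment(
        rng,
        {"charged": list("KKKR"), "neutral": list("SSTT")},
        list("IIFFFA"),
        int(rng.integers(4, 6)),
    )


def _neutral_filler(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("SNQTGA"), size=n))


def make_decoy(
    stage_to_fail: str, seed: int, rec_id: str | None = None,
    config: ScreenConfig | None = None,
) -> tuple[PeptideRecord, dict]:
    """Generate a record that passes all stages before *stage_to_fail* and
    fails exactly there (verified end-to-end against the funnel)."""
    if stage_to_fail not in DECOY_STAGES:
        raise ValueError(f"unknown decoy stage {stage_to_fail!r}")
    config = config or ScreenConfig()
    rec_id = rec_id or f"decoy_{stage_to_fail}"
    rng = np.random.default_rng(seed)
    for _ in range(MAX_ATTEMPTS):
        sub = np.random.default_rng(_subseed(rng))
        signal = _fill_consensus(sub, SIGNAL_CONSENSI[int(sub.integers(2))])
        helix = _cationic_helix(sub)
        linker = _linker(sub)
        tail = _anionic_tail(sub)
        body = helix + linker + tail
        if stage_to_fail == "length":
            seq = signal + body
            seq += _neutral_filler(sub, 101 - len(seq) + int(sub.integers(0, 10)))
        elif stage_to_fail == "secretory":
            seq = body  # no signal peptide at all
        elif stage_to_fail == "tm":
            seq = signal + helix + "L" * 19 + linker + tail
        elif stage_to_fail == "cys":
            mutated = list(tail)
            mutated[int(sub.integers(len(tail)))] = "C"
            seq = signal + helix + linker + "".join(mutated)
        elif stage_to_fail == "amphipathic":
            seq = signal + _neutral_filler(sub, HELIX_LEN) + linker + tail
        elif stage_to_fail == "helical":
            seq = signal + _breaker_helix(sub) + linker + tail
        else:  # aggregation
            seq = signal + _sticky_helix(sub) + linker + tail
        try:
            record = PeptideRecord(rec_id, seq)
        except ValueError:
            continue
        if _funnel_stage(seq, rec_id, config) == stage_to_fail:
            return record, {"expected_stage": stage_to_fail}
    raise GenerationError(
        f"no valid {stage_to_fail!r} decoy after {MAX_ATTEMPTS} attempts (seed {seed})"
    )


def make_fixture_proteome(
    spec: FixtureSpec, config: ScreenConfig | None = None
) -> tuple[list[PeptideRecord], pd.DataFrame]:
    """Planted precursors plus one decoy per requested stage.

    Returns the records (planted first, then decoys, deterministic order)
    and a truth table with each record's expected funnel outcome.
    """
    config = config or ScreenConfig()
    rng = np.random.default_rng(spec.seed)
    records, truth_rows = [], []
    for i in range(spec.n_planted):
        rec, truth = make_precursor(_subseed(rng), f"planted_{i + 1:02d}", config)
        records.append(rec)
        truth_rows.append(
            {
                "id": rec.id,
                "kind": "planted",
                "expected_stage": "candidate",
                "signal_end": truth["signal"][1],
                "cationic_start": truth["cationic"][0],
                "cationic_end": truth["cationic"][1],
                "anionic_start": truth["anionic"][0],
                "anionic_end": truth["anionic"][1],
            }
        )
    for stage in spec.decoy_stages:
        rec, _ = make_decoy(stage, _subseed(rng), f"decoy_{stage}", config)
        records.append(rec)
        truth_rows.append(
            {"id": rec.id, "kind": "decoy", "expected_stage": stage,
             "signal_end": pd.NA, "cationic_start": pd.NA, "cationic_end": pd.NA,
             "anionic_start": pd.NA, "anionic_end": pd.NA}
        )
    return records, pd.DataFrame(truth_rows)


def make_upstream_with_sites(
    pwm: PWM,
    n_sites: int,
    seed: int,
    length: int = 400,
    gene_id: str = "gene",
) -> tuple[UpstreamRecord, list[tuple[int, str]]]:
    """Random upstream DNA with planted consensus binding sites.

    The PWM's per-position argmax word (or its reverse complement, strand
    chosen at random) is embedded at non-overlapping random offsets. Returns
    the record and the truth list of (negative offset from ATG, strand).
    """
    rng = np.random.default_rng(seed)
    L = len(pwm)
    if length < n_sites * L:
        raise ValueError("sequence too short for the requested number of sites")
    seq = list(rng.choice(list("ACGT"), size=length))
    word = pwm.consensus
    placed: list[tuple[int, str]] = []
    occupied: set[int] = set()
    attempts = 0
    while len(placed) < n_sites and attempts < 1000:
        attempts += 1
        start = int(rng.integers(0, length - L + 1))
        if any(p in occupied for p in range(start, start + L)):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        site = word if strand == "+" else _revcomp(word)
        seq[start : start + L] = list(site)
        occupied.update(range(start, start + L))
        placed.append((start - length, strand))
    if len(placed) < n_sites:
        raise GenerationError("could not place all sites without overlap")
    record = UpstreamRecord(gene_id, "".join(seq))
    return record, sorted(placed)


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(seq))
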