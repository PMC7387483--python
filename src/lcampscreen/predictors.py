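"""Stage contracts for the three trained-predictor gates of the funnel.

The published funnel calls external servers for signal-peptide detection,
transmembrane-segment detection and subcellular localization. Those trained
models are not re-implemented here. Each stage instead has two
interchangeable backends:

* an *adapter* that ingests tabular result files exported from the real
  predictors (``load_external_predictions``), and
* an honest rule-based *heuristic* stand-in so the funnel runs end-to-end
  with no external calls; outputs carry a ``source`` field so downstream
  consumers can tell which backend produced a decision.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass

from .physchem import ResidueScale, builtin_scale, net_charge

log = logging.getLogger(__name__)

SMALL_RESIDUES = frozenset("AGSCT")  # admissible at the -3/-1 cleavage positions


@dataclass(frozen=True)
class SignalPrediction:
    is_secretory: bool
    cleavage_after: int | None  # 0-based index of the LAST signal-peptide residue
    source: str  # "external" | "heuristic"

    def __post_init__(self) -> None:
        if self.is_secretory != (self.cleavage_after is not None):
            raise ValueError("cleavage_after must be present iff is_secretory")


@dataclass(frozen=True)
class StageDecision:
    stage: str  # "secretory" | "transmembrane" | "localization"
    keep: bool
    detail: str = ""


# --- adapters ---------------------------------------------------------------

_REQUIRED_COLUMNS = {
    "signalp": {"id", "secretory"},
    "tm": {"id", "is_tm"},
    "localization": {"id", "localization"},
}

#: Localization classes counted as secreted (configurable; the published
#: screen's accepted-class set is not stated).
DEFAULT_SECRETED_CLASSES = frozenset({"extracellular", "secreted"})


def load_external_predictions(path, kind: str, known_ids=None) -> dict:
    """Parse an external-predictor result table into stage decisions.

    Dialects (TSV or CSV, header required):

    * ``kind="signalp"`` — columns ``id``, ``secretory`` (Y/N), optional
      ``cleavage``: either the 1-based position of the last signal residue
      (``22``) or the SignalP-style cut notation ``22|23``; both map to a
      0-based ``cleavage_after`` of 21.
    * ``kind="tm"`` — columns ``id``, ``is_tm`` (Y/N); Y means the protein is
      transmembrane and is dropped.
    * ``kind="localization"`` — columns ``id``, ``localization`` (class
      string, e.g. ``Extracellular``).

    Rows whose id is not in *known_ids* (when given) are warned about and
    skipped.
    """
    if kind not in _REQUIRED_COLUMNS:
        raise ValueError(f"unknown predictor kind {kind!r}")
    with open(path, newline="") as handle:
        sample = handle.read(4096)
        handle.seek(0)
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.DictReader(handle, delimiter=delim)
        if reader.fieldnames is None:
            return {}
        fields = {f.strip().lower() for f in reader.fieldnames}
        missing = _REQUIRED_COLUMNS[kind] - fields
        if missing:
            raise ValueError(
                f"{path}: missing required column(s) for kind {kind!r}: {sorted(missing)}"
            )
        out = {}
        for row in reader:
            row = {k.strip().lower(): (v or "").strip() for k, v in row.items() if k}
            rec_id = row["id"]
            if known_ids is not None and rec_id not in known_ids:
                warnings.warn(f"{path}: unknown id {rec_id!r} skipped", stacklevel=2)
                continue
            if kind == "signalp":
                secretory = row["secretory"].upper() in ("Y", "YES", "TRUE", "1")
                cleav = None
                if secretory:
                    raw = row.get("cleavage", "")
                    if not raw:
                        raise ValueError(
                            f"{path}: secretory row {rec_id!r} lacks a cleavage position"
                        )
                    pos_1based = int(raw.split("|")[0])
                    cleav = pos_1based - 1
                out[rec_id] = SignalPrediction(secretory, cleav, source="external")
            elif kind == "tm":
                is_tm = row["is_tm"].upper() in ("Y", "YES", "TRUE", "1")
                out[rec_id] = StageDecision(
                    "transmembrane", keep=not is_tm, detail="external"
                )
            else:
                loc = row["localization"]
                out[rec_id] = StageDecision("localization", keep=True, detail=loc)
        return out


# --- heuristic stand-ins ----------------------------------------------------


def heuristic_signal_peptide(
    seq: str,
    h_region_min_len: int = 7,
    h_region_mean_h: float = 1.0,
    scale: ResidueScale | None = None,
) -> SignalPrediction:
    """Rule-based signal-peptide stand-in (n/h/c-region test).

    A sequence is called secretory when all three classical regions are
    found:

    1. *n-region*: the first 5 residues have net charge >= 0;
    2. *h-region*: some run of >= *h_region_min_len* consecutive residues
       within positions 3–25 (1-based) has mean Fauchère–Pliska
       hydrophobicity >= *h_region_mean_h*;
    3. *c-region*: a candidate cleavage site exists at position 15–35 with
       small residues (A/G/S/C/T) at its −3 and −1 positions, downstream of
       the h-region.

    Among valid cleavage candidates the one maximising the hydrophobicity
    drop across the site (hydrophobic h-region side, polar mature side) is
    chosen. Sequences shorter than 20 residues are never called secretory.
    """
    scale = scale or builtin_scale("fauchere_pliska")
    if len(seq) < 20 or "X" in seq[:40]:
        return SignalPrediction(False, None, source="heuristic")
    # n-region
    if net_charge(seq[:5]) < 0:
        return SignalPrediction(False, None, source="heuristic")
    # h-region: best window of h_region_min_len within 1-based positions 3..25
    region = seq[2:25]
    h_end = None  # 0-based exclusive end of the first qualifying window
    for i in range(len(region) - h_region_min_len + 1):
        window = region[i : i + h_region_min_len]
        mean_h = sum(scale[r] for r in window) / len(window)
        if mean_h >= h_region_mean_h:
            h_end = 2 + i + h_region_min_len
            break
    if h_end is None:
        return SignalPrediction(False, None, source="heuristic")
    # c-region / cleavage: candidate "cleave after position p" (1-based p)
    best_p, best_score = None, None
    for p in range(max(15, h_end + 1), min(35, len(seq) - 1) + 1):
        if seq[p - 1] not in SMALL_RESIDUES or seq[p - 3] not in SMALL_RESIDUES:
            continue
        upstream = seq[max(0, p - 8) : p - 3]
        downstream = seq[p : p + 5]
        up_h = sum(scale[r] for r in upstream) / len(upstream) if upstream else 0.0
        down_h = (
            sum(scale[r] for r in downstream) / len(downstream) if downstream else 0.0
        )
        score = up_h - down_h
        if best_score is None or score > best_score:
            best_p, best_score = p, score
    if best_p is None:
        return SignalPrediction(False, None, source="heuristic")
    return SignalPrediction(True, best_p - 1, source="heuristic")


def heuristic_tm_filter(
    mature_seq: str,
    window: int = 19,
    threshold: float = 1.6,
    scale: ResidueScale | None = None,
) -> StageDecision:
    """Classic hydropathy transmembrane test on the mature sequence.

    Drops the record (``keep=False``) iff any *window*-residue stretch has a
    mean Kyte–Doolittle hydropathy >= *threshold* (inclusive) — the textbook
    signature of a membrane-spanning helix.
    """
    scale = scale or builtin_scale("kyte_doolittle")
    n = len(mature_seq)
    if n >= window:
        vals = [scale[r] if r != "X" else 0.0 for r in mature_seq]
        acc = sum(vals[:window])
        best = acc
        for i in range(window, n):
            acc += vals[i] - vals[i - window]
            best = max(best, acc)
        if best / window >= threshold:
            return StageDecision(
                "transmembrane",
                keep=False,
                detail=f"max {window}-mer hydropathy {best / window:.2f} >= {threshold}",
            )
    return StageDecision("transmembrane", keep=True, detail="no TM-like window")


def localization_gate(
    rec_id: str,
    external_map: dict | None = None,
    secreted_classes: frozenset = DEFAULT_SECRETED_CLASSES,
) -> StageDecision:
    """Keep records predicted extracellular/secreted.

    With no external prediction map the stage is a documented pass-through
    (there is no defensible sequence-only stand-in for a trained
    localization model); callers emit a once-per-run warning.
    """
    if external_map is None:
        return StageDecision("localization", keep=True, detail="pass-through")
    decision = external_map.get(rec_id)
    if decision is None:
        return StageDecision("localization", keep=False, detail="no prediction")
    keep = decision.detail.strip().lower() in secreted_classes
    return StageDecision("localization", keep=keep, detail=decision.detail)
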