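"""Orchestration of the LCAMP screening funnel.

The funnel applies, in fixed order, the eight stages used to mine a proteome
for linear cationic α-helical antimicrobial peptide (LCAMP) precursors:

1. ``length``       — keep 50–100-residue proteins (precursor-sized),
2. ``secretory``    — signal-peptide present; the signal is removed and all
   later stages see the *mature* sequence,
3. ``tm``           — drop transmembrane proteins,
4. ``cys``          — drop mature sequences containing cysteine (LCAMPs are
   linear: no disulfides),
5. ``amphipathic``  — >= 1 cationic amphipathic 18-residue window survives
   the threshold box,
6. ``helical``      — the candidate segment plausibly forms an α-helix,
7. ``aggregation``  — segment Na4vSS within the [−30, 30] gate,
8. ``localization`` — predicted extracellular (external predictions only;
   pass-through otherwise).

Survivors are ``candidate`` records. An anionic helical proregion is also
searched C-terminal of the cationic segment, and the canonical precursor
architecture (signal → cationic helix → anionic helix, in that order) is
flagged. The stage order is fixed; configuration can disable stages but not
reorder them.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import yaml

from . import aggregation as agg
from . import helixscan, predictors, seqio
from .helixscan import ANIONIC_BOX, CATIONIC_BOX, HelixSegment, ThresholdBox
from .physchem import DEFAULT_POLAR_SET, builtin_scale
from .predictors import SignalPrediction, StageDecision
from .seqio import PeptideRecord

log = logging.getLogger(__name__)

STAGES = [
    "length",
    "secretory",
    "tm",
    "cys",
    "amphipathic",
    "helical",
    "aggregation",
    "localization",
]


class ConfigError(ValueError):
    """Invalid screening configuration."""


@dataclass(frozen=True)
class HelicityConfig:
    method: str = "propensity"  # "propensity" | "external" | "off"
    min_helix_frac: float = 0.5
    min_mean_propensity: float = helixscan.MIN_MEAN_PROPENSITY


@dataclass(frozen=True)
class AggregationConfig:
    window: int | str = "auto"
    end_mode: str = "truncate"  # | "full_windows_only"
    gate_lo: float = -30.0
    gate_hi: float = 30.0
    target: str = "segment"  # score the merged segment | "window" (best 18-mer)


@dataclass(frozen=True)
class PredictorConfig:
    signal_mode: str = "heuristic"  # "heuristic" | "external" | "off"
    signal_path: str | None = None
    tm_mode: str = "heuristic"
    tm_path: str | None = None
    localization_mode: str = "passthrough"  # "external" | "passthrough" | "off"
    localization_path: str | None = None
    secreted_classes: tuple = tuple(sorted(predictors.DEFAULT_SECRETED_CLASSES))


@dataclass(frozen=True)
class ScreenConfig:
    """Every numeric screening parameter, with the published values as defaults."""

    min_len: int = 50
    max_len: int = 100
    cationic: ThresholdBox = field(default_factory=lambda: CATIONIC_BOX)
    anionic: ThresholdBox = field(default_factory=lambda: ANIONIC_BOX)
    helicity: HelicityConfig = field(default_factory=HelicityConfig)
    aggregation: AggregationConfig = field(default_factory=AggregationConfig)
    predictors: PredictorConfig = field(default_factory=PredictorConfig)
    pwm_core_cutoff: float = 0.75
    pwm_matrix_cutoff: float = 0.8
    polar_set: str = "".join(sorted(DEFAULT_POLAR_SET))
    hydrophobicity_scale: str = "fauchere_pliska"
    a3v_scale: str = "aggrescan_a3v"
    seed: int = 0

    # -- (de)serialisation ---------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "ScreenConfig":
        def build(klass, payload, where):
            if not isinstance(payload, dict):
                raise ConfigError(f"{where}: expected a mapping")
            allowed = {f.name for f in fields(klass)}
            unknown = set(payload) - allowed
            if unknown:
                raise ConfigError(f"{where}: unknown key(s) {sorted(unknown)}")
            return klass(**payload)

        allowed = {f.name for f in fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ConfigError(f"unknown config key(s) {sorted(unknown)}")
        kwargs = dict(data)
        for key, klass in (
            ("cationic", ThresholdBox),
            ("anionic", ThresholdBox),
            ("helicity", HelicityConfig),
            ("aggregation", AggregationConfig),
            ("predictors", PredictorConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = build(klass, kwargs[key], key)
        if "predictors" in kwargs and isinstance(
            kwargs["predictors"].secreted_classes, list
        ):
            kwargs["predictors"] = replace(
                kwargs["predictors"],
                secreted_classes=tuple(kwargs["predictors"].secreted_classes),
            )
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        data = self.to_dict()
        data["predictors"]["secreted_classes"] = list(
            data["predictors"]["secreted_classes"]
        )
        with open(path, "w") as handle:
            yaml.safe_dump(data, handle, sort_keys=False)


@dataclass
class CandidateReport:
    """Outcome of the funnel for one input record."""

    record: PeptideRecord
    stage_reached: str  # first failed stage, or "candidate"
    signal: SignalPrediction | None = None
    mature_start: int = 0  # 0-based precursor index where the mature region begins
    mature_seq: str = ""
    cationic_segments: list = field(default_factory=list)  # surviving HelixSegments
    segment_na4vss: dict = field(default_factory=dict)  # (start, end) -> Na4vSS
    anionic: HelixSegment | None = None  # coordinates on the mature sequence
    architecture_ok: bool = False

    @property
    def is_candidate(self) -> bool:
        return self.stage_reached == "candidate"

    @property
    def best_segment(self) -> HelixSegment | None:
        if not self.cationic_segments:
            return None
        return max(
            self.cationic_segments, key=lambda s: (s.best_window.profile.muH, -s.start)
        )

    def report_row(self) -> dict:
        """TSV row; coordinates 1-based inclusive on the full precursor."""
        row = {c: "" for c in seqio.REPORT_COLUMNS}
        row["id"] = self.record.id
        row["stage_reached"] = self.stage_reached
        row["verdict"] = "candidate" if self.is_candidate else "rejected"
        seg = self.best_segment
        if seg is not None:
            row["window_start"] = self.mature_start + seg.start + 1
            row["window_end"] = self.mature_start + seg.end
            row["window_seq"] = self.mature_seq[seg.start : seg.end]
            p = seg.best_window.profile
            row["H"] = round(p.H, 3)
            row["muH"] = round(p.muH, 3)
            row["z"] = p.z
            key = (seg.start, seg.end)
            if key in self.segment_na4vss:
                row["Na4vSS"] = round(self.segment_na4vss[key], 1)
        if self.anionic is not None:
            row["anionic_start"] = self.mature_start + self.anionic.start + 1
            row["anionic_end"] = self.mature_start + self.anionic.end
        return row


@dataclass(frozen=True)
class FunnelCounts:
    """Input size and survivor count after each stage (non-increasing)."""

    input_n: int
    after: dict  # stage name -> surviving count, in STAGES order

    def as_list(self) -> list[tuple[str, int]]:
        return [(s, self.after[s]) for s in STAGES]

    def is_monotone(self) -> bool:
        seq = [self.input_n] + [self.after[s] for s in STAGES]
        return all(a >= b for a, b in zip(seq, seq[1:]))


def _load_external(config: PredictorConfig, known_ids) -> dict:
    maps = {}
    for stage, mode, path, kind in (
        ("secretory", config.signal_mode, config.signal_path, "signalp"),
        ("tm", config.tm_mode, config.tm_path, "tm"),
        ("localization", config.localization_mode, config.localization_path, "localization"),
    ):
        if mode == "external":
            if not path:
                raise ConfigError(f"{stage}: external mode requires a file path")
            try:
                maps[stage] = predictors.load_external_predictions(path, kind, known_ids)
            except OSError as exc:
                raise ConfigError(f"{stage}: cannot read {path}: {exc}") from exc
    return maps


def run_funnel(
    records: Sequence[PeptideRecord], config: ScreenConfig | None = None
) -> tuple[list[CandidateReport], FunnelCounts]:
    """Run every record through the eight-stage funnel.

    Returns one :class:`CandidateReport` per input record (input order) and
    the per-stage survivor counts. Deterministic: a pure function of the
    records and the configuration.
    """
    config = config or ScreenConfig()
    for mode_name, mode in (
        ("signal_mode", config.predictors.signal_mode),
        ("tm_mode", config.predictors.tm_mode),
    ):
        if mode not in ("heuristic", "external", "off"):
            raise ConfigError(f"{mode_name}: unknown mode {mode!r}")
    if config.predictors.localization_mode not in ("external", "passthrough", "off"):
        raise ConfigError(
            f"localization_mode: unknown mode {config.predictors.localization_mode!r}"
        )
    external = _load_external(config.predictors, {r.id for r in records})
    if config.predictors.localization_mode == "passthrough":
        log.warning(
            "localization stage is a pass-through (no external predictions supplied)"
        )

    h_scale = builtin_scale(config.hydrophobicity_scale)
    a3v_scale = builtin_scale(config.a3v_scale)
    polar = frozenset(config.polar_set)
    secreted = frozenset(c.lower() for c in config.predictors.secreted_classes)

    reports = [_screen_one(r, config, external, h_scale, a3v_scale, polar, secreted)
               for r in records]

    tally = Counter(r.stage_reached for r in reports)
    after, surviving = {}, len(records)
    for stage in STAGES:
        surviving -= tally.get(stage, 0)
        after[stage] = surviving
    counts = FunnelCounts(input_n=len(records), after=after)
    for stage, n in counts.as_list():
        log.info("stage %-12s -> %d surviving", stage, n)
    return reports, counts


def _screen_one(
    record: PeptideRecord,
    config: ScreenConfig,
    external: dict,
    h_scale,
    a3v_scale,
    polar,
    secreted,
) -> CandidateReport:
    seq = record.sequence
    rep = CandidateReport(record=record, stage_reached="candidate")

    # 1. length
    if not (config.min_len <= record.length <= config.max_len):
        rep.stage_reached = "length"
        return rep

    # 2. signal peptide; later stages see the mature sequence
    pcfg = config.predictors
    if pcfg.signal_mode == "off":
        signal, mature_start = None, 0
    else:
        if pcfg.signal_mode == "external":
            signal = external["secretory"].get(record.id) or SignalPrediction(
                False, None, source="external"
            )
        else:
            signal = predictors.heuristic_signal_peptide(seq, scale=h_scale)
        if not signal.is_secretory:
            rep.stage_reached = "secretory"
            return rep
        mature_start = signal.cleavage_after + 1
    rep.signal = signal if pcfg.signal_mode != "off" else None
    mature = seq[mature_start:]
    if not mature:
        rep.stage_reached = "secretory"
        return rep
    rep.mature_start, rep.mature_seq = mature_start, mature

    # 3. transmembrane
    if pcfg.tm_mode != "off":
        if pcfg.tm_mode == "external":
            decision = external["tm"].get(record.id) or StageDecision(
                "transmembrane", keep=True, detail="no prediction"
            )
        else:
            decision = predictors.heuristic_tm_filter(mature)
        if not decision.keep:
            rep.stage_reached = "tm"
            return rep

    # 4. cysteine-free mature region
    if "C" in mature:
        rep.stage_reached = "cys"
        return rep

    # 5. cationic amphipathic windows
    windows = helixscan.scan_windows(
        mature, config.cationic, h_scale, polar, parent_id=record.id, klass="cationic"
    )
    segments = helixscan.merge_windows(windows)
    if not segments:
        rep.stage_reached = "amphipathic"
        return rep

    # 6. helicity
    if config.helicity.method != "off":
        kept = []
        for seg in segments:
            passed, _frac = helixscan.helicity_check(
                mature[seg.start : seg.end],
                method=config.helicity.method,
                min_helix_frac=config.helicity.min_helix_frac,
                min_mean_propensity=config.helicity.min_mean_propensity,
            )
            if passed:
                kept.append(seg)
        segments = kept
        if not segments:
            rep.stage_reached = "helical"
            return rep

    # 7. aggregation gate (on the merged segment by default)
    acfg = config.aggregation
    kept = []
    for seg in segments:
        target = (
            mature[seg.start : seg.end] if acfg.target == "segment" else seg.best_window.seq
        )
        prof = agg.aggregation_profile(
            target, a3v_scale, window=acfg.window, end_mode=acfg.end_mode
        )
        rep.segment_na4vss[(seg.start, seg.end)] = prof.Na4vSS
        if acfg.gate_lo <= prof.Na4vSS <= acfg.gate_hi:
            kept.append(seg)
    segments = kept
    if not segments:
        rep.stage_reached = "aggregation"
        return rep
    rep.cationic_segments = segments

    # 8. localization
    if pcfg.localization_mode == "external":
        decision = predictors.localization_gate(
            record.id, external["localization"], secreted
        )
        if not decision.keep:
            rep.stage_reached = "localization"
            return rep

    # annotation: anionic helical proregion + precursor architecture
    rep.anionic = helixscan.find_anionic_tail(
        mature, config.anionic, h_scale, parent_id=record.id
    )
    annotate_architecture(rep)
    return rep


def annotate_architecture(report: CandidateReport) -> CandidateReport:
    """Flag the canonical precursor layout: signal → cationic → anionic.

    True only when all three regions exist and, on precursor coordinates,
    the signal cleavage precedes the cationic segment start and the cationic
    segment ends at or before the anionic segment start.
    """
    report.architecture_ok = False
    seg = report.best_segment
    if report.signal is None or seg is None or report.anionic is None:
        return report
    cleave = report.signal.cleavage_after
    cat_start = report.mature_start + seg.start
    cat_end = report.mature_start + seg.end
    ani_start = report.mature_start + report.anionic.start
    report.architecture_ok = cleave < cat_start and cat_end <= ani_start
    return report


# --- consensus and assay helpers -------------------------------------------

GAP_CHARS = frozenset("-.")


def consensus_sequence(aligned: Sequence[str], threshold: float = 0.8) -> str:
    """Majority-rule consensus of equal-length gapped sequences.

    Per column: emit the residue whose frequency (over all sequences) is at
    least *threshold*, else ``X``; columns where gaps are the majority are
    dropped. An 80% threshold is the convention used to derive conserved
    signal-peptide consensi such as ``MDRKIVFALXLVXXLXVSXXXA``.
    """
    if not aligned:
        raise ValueError("no sequences")
    n = len(aligned)
    width = len(aligned[0])
    if any(len(s) != width for s in aligned):
        raise ValueError("aligned sequences must all have the same length")
    if not (0.5 < threshold <= 1.0):
        raise ValueError("threshold must be in (0.5, 1]")
    out = []
    for col in range(width):
        column = [s[col].upper() for s in aligned]
        gaps = sum(1 for c in column if c in GAP_CHARS)
        if gaps > n / 2:
            continue
        residue, count = Counter(c for c in column if c not in GAP_CHARS).most_common(1)[0]
        out.append(residue if count / n >= threshold else "X")
    return "".join(out)


def relative_activity(a_pc: float, a_nc: float, a_sa: float) -> float:
    """Relative activity of a liquid growth-inhibition assay.

    RA = ((A_PC − A_NC) − A_SA) / (A_PC − A_NC), with A_PC/A_NC/A_SA the
    absorbances of the positive control, negative control and sample.
    RA = 1 means complete inhibition (sample absorbance 0), RA = 0 means no
    inhibition beyond the negative control.
    """
    denom = a_pc - a_nc
    if denom == 0:
        raise ValueError("A_PC == A_NC: relative activity undefined")
    return (denom - a_sa) / denom
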