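"""Sliding-window detection of cationic-amphipathic and anionic helices.

An 18-residue window slides along the mature (signal-less) sequence with step
1; every window is profiled (hydrophobicity, hydrophobic moment, net charge,
composition) and kept when it falls inside a :class:`ThresholdBox`.
Overlapping passing windows merge into maximal :class:`HelixSegment` spans.

Two boxes matter for LCAMP screening: the *cationic* box that describes
mature antimicrobial helices (H in [0, 0.6], muH in [0.1, 1.0], z in
[3, 10], plus composition limits, cysteine forbidden) and the *anionic* box
that describes the acidic helical proregion found C-terminal of the active
peptide (H in [−0.7, 0.4], muH in [0, 0.5], z in [−10, −3]). All bounds are
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .physchem import (
    DEFAULT_POLAR_SET,
    PhyschemProfile,
    ResidueScale,
    ScaleError,
    builtin_scale,
    profile,
)

DEFAULT_WINDOW_LEN = 18


@dataclass(frozen=True)
class ThresholdBox:
    """Inclusive acceptance box for window profiles.

    Composition limits set to ``None`` are not applied; the anionic box
    applies none of them except the cysteine exclusion.
    """

    H_min: float
    H_max: float
    muH_min: float
    muH_max: float
    z_min: int
    z_max: int
    min_polar: int | None = None
    min_uncharged_STNQH: int | None = None
    min_gly: int | None = None
    max_charged: int | None = None
    forbid_cys: bool = True
    window_len: int = DEFAULT_WINDOW_LEN

    def __post_init__(self) -> None:
        if self.H_min > self.H_max or self.muH_min > self.muH_max or self.z_min > self.z_max:
            raise ValueError("threshold box has min > max")
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")

    def admits(self, p: PhyschemProfile) -> bool:
        """True when *p* satisfies every bound and composition rule."""
        if not (self.H_min <= p.H <= self.H_max):
            return False
        if not (self.muH_min <= p.muH <= self.muH_max):
            return False
        if not (self.z_min <= p.z <= self.z_max):
            return False
        if self.forbid_cys and p.n_cys > 0:
            return False
        if self.min_polar is not None and p.n_polar < self.min_polar:
            return False
        if (
            self.min_uncharged_STNQH is not None
            and p.n_uncharged_STNQH < self.min_uncharged_STNQH
        ):
            return False
        if self.min_gly is not None and p.n_gly < self.min_gly:
            return False
        if self.max_charged is not None and p.n_charged > self.max_charged:
            return False
        return True


#: Cationic amphipathic helix box (mature LCAMP), calibrated on known
#: antimicrobial peptides (cecropin-A, moricin, dermaseptin SI, PGLa, ...).
CATIONIC_BOX = ThresholdBox(
    H_min=0.0,
    H_max=0.6,
    muH_min=0.1,
    muH_max=1.0,
    z_min=3,
    z_max=10,
    min_polar=6,
    min_uncharged_STNQH=1,
    min_gly=0,
    max_charged=12,
    forbid_cys=True,
)

#: Anionic helical proregion box; only the H/muH/z limits and the cysteine
#: exclusion apply.
ANIONIC_BOX = ThresholdBox(
    H_min=-0.7,
    H_max=0.4,
    muH_min=0.0,
    muH_max=0.5,
    z_min=-10,
    z_max=-3,
    forbid_cys=True,
)


@dataclass(frozen=True)
class HelixWindow:
    parent_id: str
    start: int  # 0-based half-open on the scanned (mature) sequence
    end: int
    seq: str
    profile: PhyschemProfile
    klass: str  # "cationic" | "anionic"


@dataclass(frozen=True)
class HelixSegment:
    """Union of overlapping passing windows of one class."""

    parent_id: str
    start: int
    end: int
    klass: str
    best_window: HelixWindow  # maximal muH; ties broken by smaller start

    @property
    def seq(self) -> str:
        # best_window.seq is the scored 18-mer; the segment sequence is
        # reconstructed by the caller that holds the parent sequence.
        return self.best_window.seq


def scan_windows(
    seq: str,
    box: ThresholdBox,
    scale: ResidueScale | None = None,
    polar_set: Iterable[str] = DEFAULT_POLAR_SET,
    parent_id: str = "",
    klass: str = "cationic",
) -> list[HelixWindow]:
    """Return the windows of *seq* whose profile lies inside *box*.

    One window starts at every offset ``0 .. len(seq) - window_len``; a
    sequence shorter than the window is evaluated as a single whole-sequence
    window (whole-peptide values are what a wheel calculator reports for
    short synthetic peptides). Windows containing a residue with no scale
    value (``X``) fail closed.
    """
    if not seq:
        raise ValueError("empty sequence")
    scale = scale or builtin_scale("fauchere_pliska")
    w = box.window_len
    if len(seq) < w:
        spans = [(0, len(seq))]
    else:
        spans = [(i, i + w) for i in range(len(seq) - w + 1)]
    passing = []
    for start, end in spans:
        sub = seq[start:end]
        try:
            p = profile(sub, scale, polar_set)
        except ScaleError:
            continue  # unknown residue in window: fail closed
        if box.admits(p):
            passing.append(HelixWindow(parent_id, start, end, sub, p, klass))
    return passing


def merge_windows(windows: Sequence[HelixWindow]) -> list[HelixSegment]:
    """Merge overlapping/adjacent passing windows of the same class.

    Output segments (per parent and class) are disjoint and cover exactly
    the union of the window intervals. ``best_window`` is the member window
    with maximal muH, ties going to the smaller start.
    """
    groups: dict[tuple[str, str], list[HelixWindow]] = {}
    for win in windows:
        groups.setdefault((win.parent_id, win.klass), []).append(win)
    segments: list[HelixSegment] = []
    for (parent_id, klass), group in groups.items():
        group = sorted(group, key=lambda w: (w.start, w.end))
        current: list[HelixWindow] = []
        for win in group:
            if current and win.start <= current[-1].end:  # overlap or touch
                current.append(win)
            else:
                if current:
                    segments.append(_close_segment(parent_id, klass, current))
                current = [win]
        if current:
            segments.append(_close_segment(parent_id, klass, current))
    segments.sort(key=lambda s: (s.parent_id, s.start))
    return segments


def _close_segment(parent_id: str, klass: str, members: list[HelixWindow]) -> HelixSegment:
    best = max(members, key=lambda w: (w.profile.muH, -w.start))
    return HelixSegment(
        parent_id=parent_id,
        start=min(w.start for w in members),
        end=max(w.end for w in members),
        klass=klass,
        best_window=best,
    )


def find_anionic_tail(
    mature_seq: str,
    anionic_box: ThresholdBox = ANIONIC_BOX,
    scale: ResidueScale | None = None,
    parent_id: str = "",
) -> HelixSegment | None:
    """Locate the most C-terminal anionic helical segment, if any.

    LCAMP precursors typically end in an acidic helical proregion that is
    proteolytically removed; this reports the candidate span (or ``None``).
    """
    wins = scan_windows(
        mature_seq, anionic_box, scale, parent_id=parent_id, klass="anionic"
    )
    segments = merge_windows(wins)
    if not segments:
        return None
    return max(segments, key=lambda s: s.end)


# --- helicity stand-in ------------------------------------------------------

#: Minimum mean Chou–Fasman helix propensity for the propensity stand-in.
MIN_MEAN_PROPENSITY = 1.03


def helicity_check(
    segment_seq: str,
    method: str = "propensity",
    min_helix_frac: float = 0.5,
    external_ss: str | None = None,
    min_mean_propensity: float = MIN_MEAN_PROPENSITY,
) -> tuple[bool, float]:
    """Assess whether a segment can plausibly form an α-helix.

    ``method="propensity"`` is a built-in stand-in using Chou–Fasman helix
    propensities: pass when the mean propensity is at least
    *min_mean_propensity* AND the fraction of residues with propensity >= 1.0
    is at least *min_helix_frac*. ``method="external"`` instead takes a
    per-residue secondary-structure string (H/E/C) from a real predictor and
    passes on its helix fraction alone.

    Returns ``(passed, helix_fraction)``.
    """
    if not segment_seq:
        raise ValueError("empty segment")
    if method == "propensity":
        scale = builtin_scale("chou_fasman_helix")
        vals = [scale[r] for r in segment_seq]
        frac = sum(1 for v in vals if v >= 1.0) / len(vals)
        mean = sum(vals) / len(vals)
        return (mean >= min_mean_propensity and frac >= min_helix_frac), frac
    if method == "external":
        if external_ss is None:
            raise ValueError("method='external' requires a secondary-structure string")
        if len(external_ss) != len(segment_seq):
            raise ValueError("secondary-structure string length mismatch")
        frac = external_ss.upper().count("H") / len(external_ss)
        return frac >= min_helix_frac, frac
    raise ValueError(f"unknown helicity method {method!r}")


def relax(box: ThresholdBox, **bounds) -> ThresholdBox:
    """Return a copy of *box* with some bounds replaced (config plumbing)."""
    return replace(box, **bounds)
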