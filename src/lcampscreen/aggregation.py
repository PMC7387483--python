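"""AGGRESCAN-style aggregation-propensity scoring.

Each residue carries an intrinsic aggregation-propensity value (a3v, from an
in-vivo derived scale); a sliding window averages these into a smoothed
per-position profile (a4v). Two summary numbers follow:

* ``a4vSS`` — the sum of a4v over the profile,
* ``Na4vSS`` — a4vSS normalised per 100 residues (``100 * a4vSS / N``),
  which is length-comparable and is the screening gate used for LCAMP
  candidates: peptides with Na4vSS outside [−30, 30] are either too
  aggregation-prone or so aggregation-averse that they resemble the
  weakly/non-active ultra-cationic peptides.

Window length follows the AGGRESCAN convention when ``window="auto"``:
5 for sequences shorter than 75 residues, 7 up to 175, 9 up to 300, 11
beyond. Ends are handled by truncated (asymmetric) windows by default so the
profile keeps one value per residue; ``end_mode="full_windows_only"``
restricts a4v to positions with complete windows instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .physchem import ResidueScale, builtin_scale


@dataclass(frozen=True)
class AggregationProfile:
    sequence: str
    a3v: np.ndarray  # per-residue propensity
    a4v: np.ndarray  # window-averaged profile
    a4vSS: float
    Na4vSS: float
    window: int
    end_mode: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def auto_window(n: int) -> int:
    """AGGRESCAN length-dependent window: 5 / 7 / 9 / 11."""
    if n < 75:
        return 5
    if n <= 175:
        return 7
    if n <= 300:
        return 9
    return 11


def aggregation_profile(
    seq: str,
    scale: ResidueScale | None = None,
    window: int | str = "auto",
    end_mode: str = "truncate",
) -> AggregationProfile:
    """Compute the windowed aggregation profile and Na4vSS of *seq*.

    Parameters
    ----------
    seq:
        Amino-acid sequence, length >= 3 and >= the window.
    scale:
        a3v residue scale; defaults to the shipped AGGRESCAN scale.
    window:
        Odd window length, or ``"auto"`` for the length-dependent default.
    end_mode:
        ``"truncate"`` — asymmetric shorter windows at the termini, one a4v
        per residue (default); ``"full_windows_only"`` — a4v only where the
        full window fits. Na4vSS is normalised by the sequence length N in
        both modes.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than 3 residues")
    scale = scale or builtin_scale("aggrescan_a3v")
    n = len(seq)
    w = auto_window(n) if window == "auto" else int(window)
    if w < 1 or w % 2 == 0:
        # window 1 is the degenerate identity (a4v == a3v), kept for checks
        raise ValueError(f"window must be odd and >= 1, got {w}")
    if n < w:
        raise ValueError(f"sequence length {n} < window {w}")
    if end_mode not in ("truncate", "full_windows_only"):
        raise ValueError(f"unknown end_mode {end_mode!r}")

    a3v = np.array([scale[r] for r in seq], dtype=float)
    half = w // 2
    if end_mode == "truncate":
        a4v = np.array(
            [a3v[max(0, i - half) : min(n, i + half + 1)].mean() for i in range(n)]
        )
    else:
        a4v = np.convolve(a3v, np.ones(w) / w, mode="valid")
    a4vss = float(a4v.sum())
    return AggregationProfile(
        sequence=seq,
        a3v=a3v,
        a4v=a4v,
        a4vSS=a4vss,
        Na4vSS=100.0 * a4vss / n,
        window=w,
        end_mode=end_mode,
    )


def na4vss_gate(
    profile: AggregationProfile, lo: float = -30.0, hi: float = 30.0
) -> bool:
    """Inclusive gate on Na4vSS; the screening default is [−30, 30].

    A broader literature range for antimicrobial peptides, [−40, 60], is
    available as :data:`LITERATURE_GATE`.
    """
    return lo <= profile.Na4vSS <= hi


#: Default screening gate.
DEFAULT_GATE = (-30.0, 30.0)
#: Broader range reported for antimicrobial peptides in general.
LITERATURE_GATE = (-40.0, 60.0)
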