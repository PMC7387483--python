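"""Helical-wheel physicochemistry of amino-acid sequences.

The quantities computed here are the ones a helical-wheel calculator such as
HeliQuest reports for a peptide or sliding window:

* mean hydrophobicity ``<H>`` on the Fauchère–Pliska octanol/water scale,
* the Eisenberg hydrophobic moment ``muH`` per residue at an ideal α-helical
  periodicity of 100° per residue, which measures amphipathicity — the degree
  to which hydrophobic residues segregate onto one face of the helix,
* formal net charge ``z`` at neutral pH (K, R = +1; D, E = −1; H = 0),
* residue-composition counts used as additional screening statistics.

All residue scales are :class:`ResidueScale` objects loaded from two-column
text files; the defaults shipped with the package are accessible through
:func:`builtin_scale`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residues counted as "polar" for the minimum-polar screening statistic.
#: The choice of set is a configuration knob; this default covers charged
#: residues plus the classical polar uncharged ones.
DEFAULT_POLAR_SET = frozenset("DEKRHNQSTY")

_UNCHARGED_SET = frozenset("STNQH")
_POSITIVE = frozenset("KR")
_NEGATIVE = frozenset("DE")


class ScaleError(KeyError):
    """A residue has no value on the requested scale."""


@dataclass(frozen=True)
class ResidueScale:
    """A named per-residue numeric scale (hydrophobicity, propensity, ...).

    Lookup of a residue absent from the mapping raises :class:`ScaleError`
    rather than silently returning 0: a window containing an unknown residue
    (e.g. ``X``) must fail screening, not pass with a fabricated value.
    """

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [aa for aa in AMINO_ACIDS if aa not in self.values]
        if missing:
            raise ValueError(
                f"scale {self.name!r} is missing residues: {''.join(missing)}"
            )

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise ScaleError(
                f"residue {residue!r} has no value on scale {self.name!r}"
            ) from None

    def __contains__(self, residue: str) -> bool:
        return residue in self.values


def load_scale(path, name: str | None = None) -> ResidueScale:
    """Read a two-column (residue, value) scale file; ``#`` starts a comment."""
    values: dict[str, float] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'residue value', got {raw!r}")
            values[parts[0].upper()] = float(parts[1])
    return ResidueScale(name or str(path), values)


_BUILTIN_FILES = {
    "fauchere_pliska": "fauchere_pliska.tsv",
    "kyte_doolittle": "kyte_doolittle.tsv",
    "aggrescan_a3v": "aggrescan_a3v.tsv",
    "chou_fasman_helix": "chou_fasman_helix.tsv",
}
_SCALE_CACHE: dict[str, ResidueScale] = {}


def builtin_scale(name: str) -> ResidueScale:
    """Return one of the scales shipped with the package.

    Available names: ``fauchere_pliska``, ``kyte_doolittle``,
    ``aggrescan_a3v``, ``chou_fasman_helix``.
    """
    if name not in _BUILTIN_FILES:
        raise KeyError(f"unknown builtin scale {name!r}; choose from {sorted(_BUILTIN_FILES)}")
    if name not in _SCALE_CACHE:
        ref = resources.files("lcampscreen.data") / _BUILTIN_FILES[name]
        with resources.as_file(ref) as path:
            _SCALE_CACHE[name] = load_scale(path, name=name)
    return _SCALE_CACHE[name]


@dataclass(frozen=True)
class PhyschemProfile:
    """Physicochemical summary of one sequence or window."""

    H: float
    muH: float
    z: int
    n_polar: int
    n_uncharged_STNQH: int
    n_gly: int
    n_charged: int
    n_cys: int
    length: int


def _check_seq(seq: str) -> str:
    if not seq:
        raise ValueError("empty sequence")
    return seq


def net_charge(seq: str) -> int:
    """Formal net charge at neutral pH: #(K,R) − #(D,E); histidine counts 0."""
    _check_seq(seq)
    return sum(1 for r in seq if r in _POSITIVE) - sum(1 for r in seq if r in _NEGATIVE)


def mean_hydrophobicity(seq: str, scale: ResidueScale | None = None) -> float:
    """Arithmetic mean of the scale values over all residues."""
    _check_seq(seq)
    scale = scale or builtin_scale("fauchere_pliska")
    return sum(scale[r] for r in seq) / len(seq)


def hydrophobic_moment(
    seq: str, scale: ResidueScale | None = None, delta_deg: float = 100.0
) -> float:
    """Eisenberg per-residue hydrophobic moment.

    muH = (1/N) * | Σ_i H_i · e^(i·j·δ) |  with residue j at angle j·δ
    (j = 0 for the first residue), δ in degrees (100° = ideal α-helix).
    The result is phase-invariant, so the choice of starting angle is a pure
    convention.
    """
    _check_seq(seq)
    scale = scale or builtin_scale("fauchere_pliska")
    delta = math.radians(delta_deg)
    sx = sum(scale[r] * math.cos(j * delta) for j, r in enumerate(seq))
    sy = sum(scale[r] * math.sin(j * delta) for j, r in enumerate(seq))
    return math.hypot(sx, sy) / len(seq)


def composition_stats(
    seq: str, polar_set: Iterable[str] = DEFAULT_POLAR_SET
) -> dict[str, int]:
    """Residue-class counts used as screening statistics.

    Returns a dict with ``n_polar`` (membership in *polar_set*),
    ``n_uncharged_STNQH`` (S/T/N/Q/H), ``n_gly``, ``n_charged`` (D/E/K/R) and
    ``n_cys``.
    """
    _check_seq(seq)
    polar = frozenset(polar_set)
    return {
        "n_polar": sum(1 for r in seq if r in polar),
        "n_uncharged_STNQH": sum(1 for r in seq if r in _UNCHARGED_SET),
        "n_gly": seq.count("G"),
        "n_charged": sum(1 for r in seq if r in _POSITIVE or r in _NEGATIVE),
        "n_cys": seq.count("C"),
    }


def profile(
    seq: str,
    scale: ResidueScale | None = None,
    polar_set: Iterable[str] = DEFAULT_POLAR_SET,
    delta_deg: float = 100.0,
) -> PhyschemProfile:
    """Full physicochemical profile; equivalent to composing the parts."""
    scale = scale or builtin_scale("fauchere_pliska")
    counts = composition_stats(seq, polar_set)
    return PhyschemProfile(
        H=mean_hydrophobicity(seq, scale),
        muH=hydrophobic_moment(seq, scale, delta_deg),
        z=net_charge(seq),
        length=len(seq),
        **counts,
    )
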