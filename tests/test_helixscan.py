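"""Window scanning against a brute-force oracle, box algebra, merging."""

import numpy as np
import pytest

from lcampscreen.helixscan import (
    ANIONIC_BOX,
    CATIONIC_BOX,
    HelixWindow,
    ThresholdBox,
    find_anionic_tail,
    helicity_check,
    merge_windows,
    scan_windows,
)
from lcampscreen.physchem import PhyschemProfile, builtin_scale, profile

FP = builtin_scale("fauchere_pliska")


def brute_force_scan(seq, box):
    """Independent evaluator: test every offset separately."""
    w = box.window_len
    spans = [(0, len(seq))] if len(seq) < w else [
        (i, i + w) for i in range(len(seq) - w + 1)
    ]
    out = []
    for start, end in spans:
        sub = seq[start:end]
        if "X" in sub:
            continue
        p = profile(sub, FP)
        ok = (
            box.H_min <= p.H <= box.H_max
            and box.muH_min <= p.muH <= box.muH_max
            and box.z_min <= p.z <= box.z_max
            and not (box.forbid_cys and "C" in sub)
            and (box.min_polar is None or p.n_polar >= box.min_polar)
            and (box.min_uncharged_STNQH is None or p.n_uncharged_STNQH >= box.min_uncharged_STNQH)
            and (box.min_gly is None or p.n_gly >= box.min_gly)
            and (box.max_charged is None or p.n_charged <= box.max_charged)
        )
        if ok:
            out.append((start, end))
    return out


@pytest.mark.parametrize("box", [CATIONIC_BOX, ANIONIC_BOX], ids=["cationic", "anionic"])
def test_scan_matches_brute_force_on_random_sequences(box):
    rng = np.random.default_rng(2024)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(200):
        n = int(rng.integers(20, 121))
        seq = "".join(rng.choice(alphabet, size=n))
        got = [(w.start, w.end) for w in scan_windows(seq, box, FP)]
        assert got == brute_force_scan(seq, box)


def test_scan_charged_biased_sequences_against_oracle():
    # charge-enriched backgrounds actually exercise the passing branches
    rng = np.random.default_rng(7)
    alphabet = list("KKRRLLAAFFSSTTGGEE")
    hits = 0
    for _ in range(200):
        n = int(rng.integers(20, 90))
        seq = "".join(rng.choice(alphabet, size=n))
        got = [(w.start, w.end) for w in scan_windows(seq, CATIONIC_BOX, FP)]
        assert got == brute_force_scan(seq, CATIONIC_BOX)
        hits += len(got)
    assert hits > 0  # the comparison exercised passing windows


def test_window_profiles_reverify():
    rng = np.random.default_rng(5)
    seq = "".join(np.random.default_rng(5).choice(list("KRLAFST"), size=60))
    for win in scan_windows(seq, CATIONIC_BOX, FP, parent_id="p"):
        assert win.seq == seq[win.start : win.end]
        assert win.profile == profile(win.seq, FP)


def test_trivial_window_rejections():
    assert scan_windows("G" * 18, CATIONIC_BOX, FP) == []  # z = 0 < 3
    assert scan_windows("K" * 18, CATIONIC_BOX, FP) == []  # z = 18 > 10
    # a window containing X fails closed
    assert scan_windows("KLKLKLKLKXKLKLKLKL", CATIONIC_BOX, FP) == []


def test_box_boundary_inclusivity():
    box = CATIONIC_BOX
    base = dict(muH=0.5, z=5, n_polar=8, n_uncharged_STNQH=2, n_gly=0,
                n_charged=5, n_cys=0, length=18)
    assert box.admits(PhyschemProfile(H=0.6, **base))
    assert not box.admits(PhyschemProfile(H=0.6 + 1e-6, **base))
    assert box.admits(PhyschemProfile(H=0.0, **base))
    assert not box.admits(PhyschemProfile(H=-1e-9, **base))
    assert box.admits(PhyschemProfile(H=0.3, **{**base, "z": 3}))
    assert not box.admits(PhyschemProfile(H=0.3, **{**base, "z": 2}))
    with pytest.raises(ValueError):
        ThresholdBox(H_min=1.0, H_max=0.0, muH_min=0, muH_max=1, z_min=0, z_max=1)


def _win(start, muh=0.3, parent="p", klass="cationic", length=18):
    prof = PhyschemProfile(H=0.3, muH=muh, z=4, n_polar=8, n_uncharged_STNQH=2,
                           n_gly=0, n_charged=4, n_cys=0, length=length)
    return HelixWindow(parent, start, start + length, "A" * length, prof, klass)


def test_merge_overlapping_windows_into_one_segment():
    segs = merge_windows([_win(3), _win(4, muh=0.6), _win(5)])
    assert len(segs) == 1
    assert (segs[0].start, segs[0].end) == (3, 23)
    assert segs[0].best_window.start == 4  # maximal muH wins


def test_merge_disjoint_and_empty():
    segs = merge_windows([_win(0), _win(40)])
    assert [(s.start, s.end) for s in segs] == [(0, 18), (40, 58)]
    assert merge_windows([]) == []


def test_merge_tie_breaks_by_smaller_start():
    segs = merge_windows([_win(3, muh=0.5), _win(4, muh=0.5)])
    assert segs[0].best_window.start == 3


def test_merged_segments_cover_union_and_are_disjoint():
    rng = np.random.default_rng(11)
    for _ in range(50):
        starts = sorted(set(rng.integers(0, 80, size=rng.integers(1, 12))))
        wins = [_win(int(s)) for s in starts]
        segs = merge_windows(wins)
        union = set()
        for w in wins:
            union.update(range(w.start, w.end))
        covered = set()
        for s in segs:
            span = set(range(s.start, s.end))
            assert not span & covered  # disjoint
            covered |= span
        assert covered == union


def test_find_anionic_tail():
    assert find_anionic_tail("K" * 40, ANIONIC_BOX, FP) is None
    # short sequence inside the anionic box is a whole-sequence segment
    short = "EAEALSAELS"  # z = -4, weakly hydrophobic
    seg = find_anionic_tail(short, ANIONIC_BOX, FP)
    assert seg is not None and (seg.start, seg.end) == (0, len(short))
    # acid-rich C-terminal helix after a neutral region: most C-terminal segment
    seq = "SSQNTASQNTASQNTA" + "EALSEQALESSEAEEL"
    seg = find_anionic_tail(seq, ANIONIC_BOX, FP)
    assert seg is not None
    assert seg.end == len(seq)
    brute = brute_force_scan(seq, ANIONIC_BOX)
    assert seg.start == min(s for s, _ in brute)


def test_helicity_propensity_and_external():
    ok, frac = helicity_check("A" * 18)
    assert ok and frac == 1.0
    assert not helicity_check("G" * 18)[0]
    assert not helicity_check("P" * 18)[0]
    ok, frac = helicity_check("QQQQQQQQQQ", method="external", external_ss="HHHHHHHHCC")
    assert ok and frac == pytest.approx(0.8)
    with pytest.raises(ValueError):
        helicity_check("AAAA", method="external")
    with pytest.raises(ValueError):
        helicity_check("AAAA", method="nonsense")
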