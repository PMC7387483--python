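"""Helical-wheel physicochemistry: published values and algebraic laws."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcampscreen.peptides import TABLE_PEPTIDES, TABLE_VALUES
from lcampscreen.physchem import (
    ResidueScale,
    ScaleError,
    builtin_scale,
    composition_stats,
    hydrophobic_moment,
    mean_hydrophobicity,
    net_charge,
    profile,
)

FP = builtin_scale("fauchere_pliska")

aa_text = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60)


@pytest.mark.parametrize("gene_id", sorted(TABLE_PEPTIDES))
def test_published_peptide_values_reproduce(gene_id):
    """H (±5e-4), muH (±5e-4) and z (exact) match the published wheel values."""
    seq = TABLE_PEPTIDES[gene_id]
    h_exp, muh_exp, z_exp = TABLE_VALUES[gene_id]
    assert net_charge(seq) == z_exp
    assert mean_hydrophobicity(seq, FP) == pytest.approx(h_exp, abs=5e-4)
    assert hydrophobic_moment(seq, FP) == pytest.approx(muh_exp, abs=5e-4)


def test_moment_degenerate_cases():
    assert hydrophobic_moment("G" * 25, FP) == pytest.approx(0.0, abs=1e-12)
    assert mean_hydrophobicity("G" * 10, FP) == pytest.approx(0.0, abs=1e-12)
    # single residue: one-term vector sum, moment is |scale value|
    assert hydrophobic_moment("W", FP) == pytest.approx(abs(FP["W"]))


@settings(max_examples=60, derandomize=True)
@given(aa_text, aa_text)
def test_net_charge_additive_under_concatenation(a, b):
    assert net_charge(a + b) == net_charge(a) + net_charge(b)


@settings(max_examples=60, derandomize=True)
@given(aa_text)
def test_appending_charged_residue_shifts_charge_by_one(seq):
    assert net_charge(seq + "R") == net_charge(seq) + 1
    assert net_charge(seq + "E") == net_charge(seq) - 1


@settings(max_examples=60, derandomize=True)
@given(aa_text, st.randoms(use_true_random=False))
def test_mean_hydrophobicity_permutation_invariant(seq, rnd):
    shuffled = list(seq)
    rnd.shuffle(shuffled)
    assert mean_hydrophobicity("".join(shuffled), FP) == pytest.approx(
        mean_hydrophobicity(seq, FP)
    )


def test_moment_not_permutation_invariant_regression():
    # amphipathic arrangement vs blocked arrangement of the same residues
    assert hydrophobic_moment("KLKLKLKLKLKLKLKLKL", FP) != pytest.approx(
        hydrophobic_moment("KKKKKKKKKLLLLLLLLL", FP), abs=1e-3
    )


@settings(max_examples=60, derandomize=True)
@given(aa_text)
def test_moment_amplitude_bound(seq):
    bound = max(abs(FP[r]) for r in seq)
    assert hydrophobic_moment(seq, FP) <= bound + 1e-9


@settings(max_examples=60, derandomize=True)
@given(aa_text)
def test_moment_at_delta_zero_equals_abs_mean(seq):
    """δ=0 collapses the vector sum: muH = |Σ H_i| / N."""
    expected = abs(sum(FP[r] for r in seq)) / len(seq)
    assert hydrophobic_moment(seq, FP, delta_deg=0.0) == pytest.approx(expected)


def test_composition_stats_definitions():
    assert composition_stats("STNQH")["n_uncharged_STNQH"] == 5
    assert composition_stats("STNQH")["n_charged"] == 0
    assert composition_stats("KRDEKRDEKRDE")["n_charged"] == 12
    counts = composition_stats(TABLE_PEPTIDES["KH.S908.1"])
    assert counts["n_cys"] == 0
    assert counts["n_gly"] == 5


def test_profile_equals_composed_parts():
    seq = TABLE_PEPTIDES["KH.C1.100"]
    p = profile(seq, FP)
    assert p.H == pytest.approx(mean_hydrophobicity(seq, FP))
    assert p.muH == pytest.approx(hydrophobic_moment(seq, FP))
    assert p.z == net_charge(seq)
    assert p.length == len(seq)
    counts = composition_stats(seq)
    assert p.n_polar == counts["n_polar"]
    assert p.n_charged == counts["n_charged"]


def test_scale_contract():
    with pytest.raises(ScaleError):
        mean_hydrophobicity("AXA", FP)
    with pytest.raises(ValueError):
        ResidueScale("partial", {"A": 1.0})  # all 20 residues required
    with pytest.raises(ValueError):
        net_charge("")


def test_builtin_scale_roundtrip(tmp_path):
    path = tmp_path / "scale.tsv"
    path.write_text("# comment\n" + "\n".join(f"{r}\t{FP[r]}" for r in "ACDEFGHIKLMNPQRSTVWY"))
    from lcampscreen.physchem import load_scale

    loaded = load_scale(path)
    assert all(loaded[r] == FP[r] for r in "ACDEFGHIKLMNPQRSTVWY")
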