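"""Match-style PWM scoring against a brute-force oracle and score algebra."""

import math

import numpy as np
import pytest

from lcampscreen.motif import (
    BASES,
    PWM,
    PWMError,
    load_pwm,
    match_scan,
    scan_upstream_set,
    format_hits_table,
)
from lcampscreen.seqio import UpstreamRecord

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq):
    return "".join(COMP[b] for b in reversed(seq))


def toy_pwm(seed=0, length=6):
    rng = np.random.default_rng(seed)
    counts = rng.integers(1, 50, size=(length, 4)).astype(float)
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return PWM(f"toy{seed}", freqs)


def brute_score(word, pwm, positions):
    """Independent Match-similarity evaluator."""
    info = [
        sum(f * math.log(4 * f) for f in pwm.freqs[i] if f > 0) for i in positions
    ]
    cur = sum(
        inf * pwm.freqs[i][BASES.index(word[i])] for inf, i in zip(info, positions)
    )
    mn = sum(inf * min(pwm.freqs[i]) for inf, i in zip(info, positions))
    mx = sum(inf * max(pwm.freqs[i]) for inf, i in zip(info, positions))
    return (cur - mn) / (mx - mn)


def brute_scan(seq, pwm, core_cut, mat_cut):
    L = len(pwm)
    n = len(seq)
    hits = []
    for j in range(n - L + 1):
        window = seq[j : j + L]
        if "N" in window:
            continue
        for strand in "+-":
            word = window if strand == "+" else revcomp(window)
            mat = brute_score(word, pwm, range(L))
            core = brute_score(word, pwm, pwm.core_positions)
            if mat >= mat_cut and core >= core_cut:
                hits.append((j - n, strand, round(core, 10), round(mat, 10)))
    return sorted(hits)


def test_scan_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(123)
    for trial in range(200):
        pwm = toy_pwm(seed=trial, length=int(rng.integers(5, 9)))
        seq = "".join(rng.choice(list("ACGT"), size=50))
        rec = UpstreamRecord("g", seq)
        got = sorted(
            (h.position, h.strand, round(h.core_sim, 10), round(h.matrix_sim, 10))
            for h in match_scan(rec, pwm, core_cutoff=0.5, matrix_cutoff=0.5)
        )
        assert got == brute_scan(seq, pwm, 0.5, 0.5)


def test_consensus_word_scores_exactly_one(default_pwm):
    word = default_pwm.consensus
    n = 30
    seq = "A" * (n - len(word)) + word
    hits = match_scan(UpstreamRecord("g", seq), default_pwm)
    top = [h for h in hits if h.strand == "+" and h.position == -len(word)]
    assert len(top) == 1
    assert top[0].matrix_sim == pytest.approx(1.0)
    assert top[0].core_sim == pytest.approx(1.0)


def test_anticonsensus_word_scores_zero(default_pwm):
    word = default_pwm.anticonsensus
    rec = UpstreamRecord("g", word)
    assert all(
        h.strand == "-" for h in match_scan(rec, default_pwm)
    )  # + strand scores 0 and cannot pass


def test_scores_bounded_and_revcomp_symmetry():
    pwm = toy_pwm(seed=3)
    rng = np.random.default_rng(17)
    seq = "".join(rng.choice(list("ACGT"), size=80))
    fwd = match_scan(UpstreamRecord("g", seq), pwm, 0.0, 0.0)
    rev = match_scan(UpstreamRecord("g", revcomp(seq)), pwm, 0.0, 0.0)
    assert all(0 <= h.core_sim <= 1 and 0 <= h.matrix_sim <= 1 for h in fwd)
    n, L = len(seq), len(pwm)
    fwd_map = {(h.position + n, h.strand): h.matrix_sim for h in fwd}
    for h in rev:
        j = h.position + n
        mirror = (n - L - j, "+" if h.strand == "-" else "-")
        assert fwd_map[mirror] == pytest.approx(h.matrix_sim)


def test_cutoff_monotonicity():
    pwm = toy_pwm(seed=4)
    rng = np.random.default_rng(29)
    seq = "".join(rng.choice(list("ACGT"), size=200))
    rec = UpstreamRecord("g", seq)
    counts_mat = [
        len(match_scan(rec, pwm, core_cutoff=0.0, matrix_cutoff=c))
        for c in (0.0, 0.3, 0.6, 0.9)
    ]
    counts_core = [
        len(match_scan(rec, pwm, core_cutoff=c, matrix_cutoff=0.0))
        for c in (0.0, 0.3, 0.6, 0.9)
    ]
    assert counts_mat == sorted(counts_mat, reverse=True)
    assert counts_core == sorted(counts_core, reverse=True)


def test_windows_with_n_are_skipped():
    pwm = toy_pwm(seed=5)
    rec = UpstreamRecord("g", "N" * 40)
    assert match_scan(rec, pwm) == []


def test_degenerate_pwm_raises():
    uniform = PWM("u", np.full((6, 4), 0.25))
    with pytest.raises(PWMError, match="degenerate"):
        match_scan(UpstreamRecord("g", "ACGTACGTACGT"), uniform)


def test_load_pwm_jaspar_counts(tmp_path, default_pwm):
    assert np.allclose(default_pwm.freqs.sum(axis=1), 1.0)
    assert len(default_pwm.core_positions) == 5
    s, e = default_pwm.core_positions[0], default_pwm.core_positions[-1]
    assert e - s == 4  # contiguous


def test_load_pwm_plain_matrix(tmp_path):
    path = tmp_path / "plain.txt"
    path.write_text("A C G T\n10 0 0 0\n0 10 0 0\n0 0 10 0\n0 0 0 10\n5 5 0 0\n")
    pwm = load_pwm(path)
    assert len(pwm) == 5
    assert np.allclose(pwm.freqs.sum(axis=1), 1.0)
    assert pwm.consensus.startswith("ACGT")


def test_load_pwm_frequency_matrix_used_as_is(tmp_path):
    path = tmp_path / "freq.txt"
    path.write_text(
        "A C G T\n"
        + "\n".join("0.7 0.1 0.1 0.1" for _ in range(6))
    )
    pwm = load_pwm(path)
    assert np.allclose(pwm.freqs, [[0.7, 0.1, 0.1, 0.1]] * 6)


def test_uniform_rows_have_zero_information(tmp_path):
    path = tmp_path / "uni.txt"
    path.write_text("A C G T\n" + "\n".join("25 25 25 25" for _ in range(7)))
    pwm = load_pwm(path)
    assert np.allclose(pwm.info, 0.0, atol=1e-6)
    assert pwm.core_positions == (0, 1, 2, 3, 4)  # tie -> leftmost


def test_load_pwm_errors(tmp_path):
    zero = tmp_path / "zero.txt"
    zero.write_text("A C G T\n1 1 1 1\n0 0 0 0\n1 1 1 1\n1 1 1 1\n1 1 1 1\n")
    with pytest.raises(PWMError, match="all-zero"):
        load_pwm(zero)
    short = tmp_path / "short.txt"
    short.write_text("A C G T\n1 1 1 1\n1 1 1 1\n")
    with pytest.raises(PWMError, match="fewer than 5"):
        load_pwm(short)


def test_scan_upstream_set_ordering_and_nd(default_pwm):
    word = default_pwm.consensus
    with_site = UpstreamRecord("geneB", "ACGT" * 10 + word + "AC")
    without = UpstreamRecord("geneA", "AC" * 30)
    hits = scan_upstream_set([with_site, without], default_pwm)
    assert list(hits.gene_id.unique()) in ([["geneB"]], ["geneB"])
    assert hits.position.is_monotonic_increasing or len(hits) <= 1
    table = format_hits_table([with_site, without], hits)
    assert table.set_index("gene_id").loc["geneA", "sites"] == "N.D."
    assert "/" in table.set_index("gene_id").loc["geneB", "sites"]
    # position + L <= 0 invariant
    assert (hits.position + len(default_pwm) <= 0).all()
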