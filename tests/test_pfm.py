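import math

import numpy as np
import pytest

from dreamscreen.io_formats import PromoterRecord
from dreamscreen.pfm import (
    BASES,
    GappedPFM,
    PfmError,
    build_pfm,
    pvalue_table,
    scan_promoter,
    score_word,
)


def enumerate_distribution(table):
    """Independent oracle: full 4^k enumeration of background words."""
    iw = table.int_weights
    k = iw.shape[1]
    n_words = 4 ** k
    digits = (np.arange(n_words)[:, None] // (4 ** np.arange(k))) % 4
    scores = iw[digits, np.arange(k)].sum(axis=1)
    lo = scores.min()
    counts = np.bincount(scores - lo)
    return int(lo), counts / n_words


def random_pfm(rng, k):
    counts = rng.integers(0, 15, size=(4, k)).astype(float)
    counts[0] += 1  # keep columns non-degenerate
    # equalize column sums (sites are aligned, one base per site per column)
    target = counts.sum(axis=0).max()
    counts[3] += target - counts.sum(axis=0)
    return GappedPFM(counts=counts, spacer_start=2, spacer_len=0)


def test_build_counts_and_consensus():
    sites = ["TCCCGCACGTTTTGAA"] * 10
    pfm = build_pfm(sites)
    # raw tallies: every informative column concentrates the 10 sites
    assert pfm.site_count == 10
    np.testing.assert_allclose(pfm.counts.sum(axis=0), 10)
    # smoothed columns sum to site_count + alpha (pseudocount split by background)
    bg = np.asarray(pfm.background)[:, None]
    np.testing.assert_allclose((pfm.counts + pfm.alpha * bg).sum(axis=0), 11)
    assert pfm.consensus == "TCCCGCNNNNTTTGAA"
    # the consensus attains the column-wise maximum score
    assert score_word(pfm, sites[0]) == pytest.approx(pfm.max_score)


def test_build_rejects_bad_sites():
    with pytest.raises(PfmError):
        build_pfm(["TCCCGCACGTTTTGA"] * 3)  # length 15
    with pytest.raises(PfmError):
        build_pfm(["TCCCGCACGTTTTGAX"] * 3)  # bad base outside spacer... spacer ok
    build_pfm(["TCCCGCNNNNTTTGAA"] * 3)  # N at spacer allowed


def test_weights_match_hand_computed_log_odds():
    sites = ["ACCCGCACGTTTTGAA", "TCCCGCACGTTTTGAA",
             "TCCCGCACGTTTTGAA", "TGCCGCACGTTTTGAA"]
    pfm = build_pfm(sites, alpha=1.0)
    # column 1: A appears once, T three times; alpha spread 0.25 per base
    wA = math.log((1 + 0.25) / (5 * 0.25))
    wT = math.log((3 + 0.25) / (5 * 0.25))
    wG = math.log(0.25 / (5 * 0.25))
    assert pfm.weights[0, 0] == pytest.approx(wA)
    assert pfm.weights[3, 0] == pytest.approx(wT)
    assert pfm.weights[2, 0] == pytest.approx(wG)
    # independent per-position sum for an arbitrary word
    word = "AGCCGCTTTTTTTGAA"
    expected = sum(
        pfm.weights["ACGT".index(word[p - 1]), j]
        for j, p in enumerate(pfm.informative_positions)
    )
    assert score_word(pfm, word) == pytest.approx(expected)


def test_spacer_positions_never_contribute(matrix):
    a = "TCCCGCAAAATTTGAA"
    b = "TCCCGCGGGGTTTGAA"
    assert score_word(matrix, a) == score_word(matrix, b)


def test_consensus_is_maximal(matrix, rng):
    cmax = score_word(matrix, matrix.consensus.replace("N", "A"))
    for _ in range(200):
        word = "".join(np.asarray(list(BASES))[rng.integers(0, 4, size=16)])
        assert score_word(matrix, word) <= cmax + 1e-12


def test_dp_equals_enumeration_bitwise(rng):
    for _ in range(10):
        k = int(rng.integers(3, 9))
        pfm = random_pfm(rng, k)
        table = pvalue_table(pfm)
        lo_e, probs_e = enumerate_distribution(table)
        lo_d, probs_d = table.probabilities()
        assert lo_d == lo_e
        np.testing.assert_array_equal(probs_d, probs_e)  # exact, not approx


def test_pvalue_table_monotone_and_bounds(ptable):
    lo, hi = ptable.support
    assert ptable.pvalue_int(lo) == 1.0
    sf = [ptable.pvalue_int(s) for s in range(lo, hi + 1, (hi - lo) // 50 or 1)]
    assert all(a >= b for a, b in zip(sf, sf[1:]))
    assert ptable.pvalue_int(hi + 1) == 0.0


def test_single_column_law():
    counts = np.zeros((4, 1))
    counts[0, 0] = 3  # A-favoring column
    counts[1:, 0] = 1
    pfm = GappedPFM(counts=counts, spacer_start=2, spacer_len=0)
    table = pvalue_table(pfm)
    wA = table.int_weights[0, 0]
    assert table.pvalue_int(int(wA)) == pytest.approx(0.25)


def test_scan_recovers_planted_site_and_orientation(matrix, ptable):
    consensus = matrix.consensus.replace("N", "G")
    background = "A" * 400  # scores far below threshold everywhere
    idx = 300 - 120
    seq = background[:idx] + consensus + background[idx + 16:]
    rec = PromoterRecord("g", "mouse", "+", 300, seq)
    hits = scan_promoter(matrix, rec, table=ptable)
    assert [h.offset for h in hits] == [-120]
    assert hits[0].sequence == consensus
    assert hits[0].p_value <= 1e-3
    # the reverse complement of the site is invisible to the transcript-strand scan
    rc = consensus[::-1].translate(str.maketrans("ACGT", "TGCA"))
    seq_rc = background[:idx] + rc + background[idx + 16:]
    assert scan_promoter(matrix, PromoterRecord("g", "mouse", "+", 300, seq_rc),
                         table=ptable) == []


def test_scan_short_sequence_warns_and_returns_empty(matrix, ptable, caplog):
    rec = PromoterRecord("g", "mouse", "+", 0, "ACGTACGT")
    with caplog.at_level("WARNING"):
        assert scan_promoter(matrix, rec, table=ptable) == []
    assert "shorter" in caplog.text


def test_empirical_hit_rate_matches_nominal(matrix, ptable, rng):
    n = 120_000
    seq = "".join(np.asarray(list(BASES))[rng.integers(0, 4, size=n)])
    rec = PromoterRecord("bg", "mouse", "+", 0, seq)
    hits = scan_promoter(matrix, rec, p_max=1e-3, table=ptable)
    windows = n - 15
    nominal = windows * 1e-3
    sd = math.sqrt(windows * 1e-3 * (1 - 1e-3))
    assert abs(len(hits) - nominal) <= 3 * sd
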