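import numpy as np
import pandas as pd
import pytest

from dreamscreen.chip import (
    ChipError,
    GeneChipSummary,
    PeakEvidence,
    best_peak,
    candidate_filter,
    cobinding,
    total_chip_score,
)


def peaks_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def ev(score, start, end, chrom="chr1", distance=0.0):
    return PeakEvidence(score=score, distance=distance, start=start, end=end, chrom=chrom)


def test_best_peak_prefers_score_over_distance():
    tss = 10_000
    df = peaks_df([
        ("chr1", tss - 150, tss - 50, "near", 300, "+"),
        ("chr1", tss + 1900, tss + 2100, "far", 700, "+"),
    ])
    got = best_peak(tss, "+", df)
    assert got.score == 700 and got.distance == pytest.approx(2000)


def test_best_peak_distance_tie_break_and_strand_sign():
    tss = 10_000
    df = peaks_df([
        ("chr1", tss - 3050, tss - 2950, "far", 500, "+"),
        ("chr1", tss - 100, tss, "near", 500, "+"),
    ])
    got = best_peak(tss, "+", df)
    assert got.distance == pytest.approx(-50)  # upstream negative on + strand
    # on the minus strand the same genomic peak lies downstream
    assert best_peak(tss, "-", df).distance == pytest.approx(50)


def test_best_peak_window_and_errors():
    tss = 10_000
    df = peaks_df([("chr1", tss + 6000, tss + 6200, "out", 900, "+")])
    assert best_peak(tss, "+", df) is None
    with pytest.raises(ChipError):
        best_peak(tss, "+", df, search_window=0)


def test_best_peak_window_monotone():
    """Enlarging the search window never loses the best score."""
    rng = np.random.default_rng(11)
    tss = 50_000
    rows = [("chr1", int(p), int(p) + 200, f"p{i}", float(s), "+")
            for i, (p, s) in enumerate(zip(
                rng.integers(tss - 9000, tss + 9000, 40),
                rng.uniform(0, 1000, 40)))]
    df = peaks_df(rows)
    prev = -1.0
    for w in (1000, 2000, 5000, 10_000):
        got = best_peak(tss, "+", df, search_window=w)
        score = got.score if got else 0.0
        assert score >= prev
        prev = score


def test_cobinding_same_species_overlap_half_open():
    s = GeneChipSummary("g")
    s.evidence[("E2F4", "mouse")] = ev(500, 100, 300)
    s.evidence[("LIN9", "mouse")] = ev(400, 250, 400)
    assert cobinding(s) is True
    # touching intervals do not overlap (half-open semantics)
    s.evidence[("LIN9", "mouse")] = ev(400, 300, 400)
    assert cobinding(s) is False
    # overlap across species does not count
    s2 = GeneChipSummary("g2")
    s2.evidence[("E2F4", "mouse")] = ev(500, 100, 300)
    s2.evidence[("LIN9", "human")] = ev(400, 150, 250)
    assert cobinding(s2) is False


def test_total_score_arithmetic_clamp_and_permutation(rng):
    s = GeneChipSummary("g")
    slots = [("E2F4", "mouse"), ("LIN9", "mouse"), ("E2F4", "human"), ("LIN9", "human")]
    for slot, score in zip(slots, (1000, 1000, 1000, 1000)):
        s.evidence[slot] = ev(score, 0, 10)
    assert total_chip_score(s) == 4000  # the maximal value
    for slot, score in zip(slots, (200, 0, 300, 100)):
        s.evidence[slot] = ev(score, 0, 10)
    assert total_chip_score(s) == 600
    # permutation invariance and brute-force oracle on random summaries
    for _ in range(20):
        scores = rng.uniform(0, 1000, size=4)
        t = GeneChipSummary("t")
        for slot, sc in zip(slots, scores):
            t.evidence[slot] = ev(float(sc), 0, 10)
        assert total_chip_score(t) == pytest.approx(scores.sum())
        u = GeneChipSummary("u")
        for slot, sc in zip(slots, np.roll(scores, 1)):
            u.evidence[slot] = ev(float(sc), 0, 10)
        assert total_chip_score(u) == pytest.approx(total_chip_score(t))


def test_candidate_filter_cutoff_and_cobinding_conjunction():
    def summary(total_each, cobound):
        s = GeneChipSummary("x")
        s.evidence[("E2F4", "mouse")] = ev(total_each, 0, 100)
        s.evidence[("LIN9", "mouse")] = ev(total_each, 50 if cobound else 200, 300)
        return s

    summaries = {
        "at_cutoff": summary(489.5, True),       # total 979, cobound
        "below": summary(489.45, True),          # total 978.9
        "high_not_cobound": summary(1000, False),
    }
    assert candidate_filter(summaries, 979) == {"at_cutoff"}
    # output is always a subset of the cobound genes
    cobound = {g for g, s in summaries.items() if cobinding(s)}
    assert candidate_filter(summaries, 0) <= cobound
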