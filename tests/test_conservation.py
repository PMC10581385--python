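import pytest
from hypothesis import given, settings, strategies as st

from dreamscreen.conservation import (
    classify_rank,
    count_mismatches,
    pair_hits,
)
from dreamscreen.pfm import DbsHit

SITE = "TCCCGCACGTTTTGAA"


def make_hit(gene, species, offset, seq=SITE, score=2.0):
    return DbsHit(gene, species, offset, seq, score, 1e-4)


def test_count_mismatches_examples():
    assert count_mismatches(SITE, SITE) == (0, 0)
    # spacer-only differences are masked
    assert count_mismatches(SITE, "TCCCGCGGGGTTTGAA") == (0, 0)
    # position 1 is ignored too
    assert count_mismatches(SITE, "ACCCGCACGTTTTGAA") == (0, 0)
    # one CDE and two CHR mismatches
    other = "TACCGCACGTTTTGCC"
    assert count_mismatches(SITE, other) == (1, 2)
    with pytest.raises(ValueError):
        count_mismatches(SITE, SITE[:-1])


@given(
    a=st.text(alphabet="ACGT", min_size=16, max_size=16),
    b=st.text(alphabet="ACGT", min_size=16, max_size=16),
)
@settings(max_examples=50, deadline=None)
def test_count_mismatches_symmetric_and_bounded(a, b):
    m1 = count_mismatches(a, b)
    assert m1 == count_mismatches(b, a)
    assert 0 <= m1[0] <= 5 and 0 <= m1[1] <= 6
    # brute-force positional oracle
    assert m1[0] == sum(a[p] != b[p] for p in range(1, 6))
    assert m1[1] == sum(a[p] != b[p] for p in range(10, 16))


@pytest.mark.parametrize(
    "sm, sh, mc, mh, expected",
    [
        (2.1, 1.0, 0, 0, "A"),
        (2.1, 1.0, 1, 0, "A"),
        (1.0, -0.5, 1, 1, "B"),
        (1.0, 0.2, 2, 1, "B"),
        (0.5, 0.1, 2, 2, "C"),
        (0.5, 0.1, 0, 5, "C"),  # extended rule: CDE perfectly conserved
        (0.5, 0.1, 5, 0, "C"),  # extended rule: CHR perfectly conserved
        (0.5, 0.1, 2, 3, None),  # five mismatches split over both elements
        (-0.3, -0.4, 0, 1, "D"),
        (-0.3, -0.4, 2, 1, None),
        (0.0, -0.1, 0, 0, "D"),  # zero is not a positive score
    ],
)
def test_classify_rank(sm, sh, mc, mh, expected):
    assert classify_rank(sm, sh, mc, mh) == expected


def test_classify_rank_is_total_and_monotone():
    for s in (-1.0, 1.0):
        for mc in range(6):
            for mh in range(7):
                r = classify_rank(s, s, mc, mh)
                assert r in {"A", "B", "C", "D", None}
    # reducing mismatches never worsens the rank at fixed positive score
    order = {"A": 0, "B": 1, "C": 2, None: 3}
    for mh in range(6):
        r_more = classify_rank(1.0, 1.0, 0, mh + 1)
        r_less = classify_rank(1.0, 1.0, 0, mh)
        assert order.get(r_less, 3) <= order.get(r_more, 3)


def test_require_both_positive_mode():
    assert classify_rank(2.0, -1.0, 0, 0) == "A"
    assert classify_rank(2.0, -1.0, 0, 0, require_both_positive=True) == "D"


def test_pair_hits_selection_and_single_species():
    hm = {
        "g1": [make_hit("g1", "mouse", -120)],
        "g2": [make_hit("g2", "mouse", -200, score=1.0),
               make_hit("g2", "mouse", -50)],
        "g3": [make_hit("g3", "mouse", -10)],
    }
    hh = {
        "G1": [make_hit("G1", "human", -118)],
        "G2": [make_hit("G2", "human", -52)],
    }
    orth = {"g1": "G1", "g2": "G2", "g3": "G3"}
    pairs = {p.gene_id_m: p for p in pair_hits(hm, hh, orth)}
    # identical sequences with positive scores: rank A
    assert pairs["g1"].rank == "A"
    assert pairs["g1"].mismatch_cde == 0
    # two mouse candidates: the co-located one is retained
    assert pairs["g2"].hit_m.offset == -50
    # hits in one species only: retained but unranked
    assert pairs["g3"].rank is None and pairs["g3"].hit_h is None


def test_pair_hits_offset_tolerance_fallback():
    hm = {"g1": [make_hit("g1", "mouse", -300)]}
    hh = {"G1": [make_hit("G1", "human", -50)]}
    pairs = pair_hits(hm, hh, {"g1": "G1"}, max_offset_shift=20)
    # no co-located pair: falls back to the full cross-product
    assert pairs[0].rank == "A"
    assert pairs[0].hit_h is not None
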