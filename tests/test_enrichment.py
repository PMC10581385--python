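import math
from fractions import Fraction

import numpy as np
import pytest

from dreamscreen.enrichment import (
    EnrichmentError,
    curated_intersect,
    enrich,
    term_union,
)
from dreamscreen.io_formats import TermAnnotation


def ann(**terms):
    return {t: TermAnnotation(t, t.lower(), tuple(genes)) for t, genes in terms.items()}


def exact_upper_tail(N, B, n, b):
    """Exact-fraction hypergeometric upper tail by enumeration."""
    total = Fraction(0)
    for j in range(b, min(n, B) + 1):
        total += Fraction(math.comb(B, j) * math.comb(N - B, n - j), math.comb(N, n))
    return total


def test_worked_example_exact():
    genes = [f"g{i}" for i in range(10)]
    annotations = ann(T1=genes[:5])
    res = enrich(genes[:4], genes, annotations, p_threshold=1.0, universe="background")
    (r,) = [x for x in res if x.term_id == "T1"]
    # N=10, B=5, n=4, b=4 -> p = C(5,4)/C(10,4)
    assert (r.N, r.B, r.n, r.b) == (10, 5, 4, 4)
    assert r.p_value == pytest.approx(5 / 210, rel=1e-12)


def test_target_equals_background_gives_unit_enrichment():
    genes = [f"g{i}" for i in range(20)]
    annotations = ann(T1=genes[:7], T2=genes[5:12])
    res = enrich(genes, genes, annotations, p_threshold=1.0)
    assert all(r.enrichment == pytest.approx(1.0) for r in res)


def test_zero_overlap_gives_p_one():
    genes = [f"g{i}" for i in range(10)]
    annotations = ann(T1=genes[5:])
    res = enrich(genes[:3], genes, annotations, p_threshold=1.0, universe="background")
    (r,) = res
    assert r.b == 0 and r.p_value == 1.0


def test_target_outside_background_rejected():
    with pytest.raises(EnrichmentError, match="absent"):
        enrich({"x"}, {"a", "b"}, ann(T1=["a"]))


def test_agrees_with_exact_fraction_oracle_to_12_digits(rng):
    for _ in range(25):
        N = int(rng.integers(10, 61))
        genes = [f"g{i}" for i in range(N)]
        B = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        term_genes = list(rng.choice(genes, size=B, replace=False))
        target = list(rng.choice(genes, size=n, replace=False))
        res = enrich(target, genes, ann(T1=term_genes), p_threshold=1.0,
                     universe="background")
        (r,) = res
        expected = float(exact_upper_tail(N, B, n, r.b))
        if r.b > 0:
            assert r.p_value == pytest.approx(expected, rel=1e-12)


def test_p_monotone_nonincreasing_in_overlap():
    from scipy.stats import hypergeom

    N, B, n = 40, 12, 15
    ps = [float(hypergeom.sf(b - 1, N, B, n)) for b in range(0, min(B, n) + 1)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_annotated_universe_restriction():
    genes = [f"g{i}" for i in range(10)]
    annotations = ann(T1=genes[:4])  # only 4 genes carry any annotation
    res = enrich(genes[:4], genes, annotations, p_threshold=1.0)
    (r,) = res
    assert r.N == 4 and r.n == 4


def test_term_union_examples_and_oracle(rng):
    annotations = ann(T1=["a", "b", "c"], T2=["d", "e", "f", "g"], T3=["c", "d"])
    assert term_union(["T1", "T2"], annotations) == set("abcdefg")
    assert term_union(["T1", "T1"], annotations) == set("abc")  # idempotent
    with pytest.raises(EnrichmentError):
        term_union(["nope"], annotations)
    # random overlapping terms equal the brute-force union
    pool = [f"g{i}" for i in range(30)]
    terms = {
        f"T{i}": TermAnnotation(f"T{i}", "", tuple(rng.choice(pool, size=8, replace=False)))
        for i in range(5)
    }
    expected = set().union(*(t.genes for t in terms.values()))
    got = term_union(list(terms), terms)
    assert got == expected
    assert len(got) <= sum(len(t.genes) for t in terms.values())


def test_curated_intersect_case_and_aliases():
    genes = {"Rtel1", "Fanca", "Tsr2", "Actb"}
    curated = ["RTEL1", "FANCA", "WDR62"]
    assert curated_intersect(genes, curated) == {"Rtel1", "Fanca"}
    assert curated_intersect(genes, genes) == genes
    assert curated_intersect(genes, ["NPHP1"]) == set()
    aliases = {"CASC5": "KNL1"}
    assert curated_intersect({"Knl1"}, ["CASC5"], aliases=aliases) == {"Knl1"}
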