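import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dreamscreen.expression import (
    ExpressionError,
    ExpressionMatrix,
    gene_fold,
    gene_folds,
    p53_direction_filter,
    probe_ratio,
    probe_ratios,
    select_downregulated,
)

finite_log2 = st.floats(min_value=2.0, max_value=14.0)


def test_probe_ratio_examples():
    assert probe_ratio([8, 8, 8], [8, 8, 8]) == pytest.approx(1.0)
    assert probe_ratio([3, 3, 3], [2, 2, 2]) == pytest.approx(2.0)
    with pytest.raises(ExpressionError):
        probe_ratio([], [1.0])


@given(
    a=st.lists(finite_log2, min_size=3, max_size=3),
    b=st.lists(finite_log2, min_size=3, max_size=3),
)
@settings(max_examples=100, deadline=None)
def test_probe_ratio_against_brute_force_and_reciprocal(a, b):
    # independent recomputation: linearize, average, divide
    expected = (sum(2.0 ** x for x in a) / 3) / (sum(2.0 ** x for x in b) / 3)
    got = probe_ratio(a, b)
    assert got == pytest.approx(expected, rel=1e-12)
    assert got * probe_ratio(b, a) == pytest.approx(1.0, rel=1e-12)


def test_gene_fold_max_probe_and_ties():
    ratios = {"p1": 1.2, "p2": 1.8, "p3": 1.8, "q1": 0.7}
    pmap = {"p1": "g", "p2": "g", "p3": "g", "q1": "h"}
    gf = gene_fold("g", pmap, ratios)
    assert gf.repression_ratio == 1.8
    assert gf.best_probe_id == "p2"  # lexicographic tie-break
    assert gene_fold("h", pmap, ratios).repression_ratio == 0.7
    with pytest.raises(ExpressionError):
        gene_fold("absent", pmap, ratios)


def test_gene_folds_frame_matches_per_gene_calls():
    ratios = pd.Series({"p1": 1.2, "p2": 1.8, "q1": 0.7})
    pmap = pd.DataFrame({"probe_id": ["p1", "p2", "q1"], "gene_id": ["g", "g", "h"]})
    df = gene_folds(ratios, pmap)
    assert df.loc["g", "repression_ratio"] == 1.8
    assert df.loc["g", "best_probe_id"] == "p2"
    assert df.loc["h", "repression_ratio"] == 0.7


def test_select_downregulated_threshold_inclusive():
    folds = {"a": 1.5, "b": 1.49, "c": 3.0}
    assert select_downregulated(folds, 1.5) == {"a", "c"}
    with pytest.raises(ExpressionError):
        select_downregulated(folds, 1.0)


def test_filter_chain_monotone_in_threshold():
    rng = np.random.default_rng(5)
    folds = {f"g{i}": float(f) for i, f in enumerate(rng.uniform(0.5, 4.0, size=100))}
    prev = select_downregulated(folds, 1.2)
    for t in (1.5, 2.0, 3.0):
        cur = select_downregulated(folds, t)
        assert cur <= prev
        prev = cur


def test_p53_direction_filter_and_or_semantics():
    scores = pd.DataFrame(
        {
            "gene_id": ["a", "b", "c", "d"],
            "score_mouse": [-0.4, 0.2, np.nan, 0.1],
            "score_human": [0.1, 0.3, -0.2, np.nan],
        }
    ).set_index("gene_id")
    kept, missing = p53_direction_filter(["a", "b", "c", "d", "e"], scores)
    assert kept == {"a", "c"}  # negative in either species keeps the gene
    assert missing == ["e"]  # absent genes are dropped and reported


def test_matrix_validation():
    values = pd.DataFrame({"s1": [8.0], "s2": [8.0], "s3": [8.0], "s4": [8.0]},
                          index=["p1"])
    design = pd.DataFrame(
        {"sample": ["s1", "s2", "s3", "s4"], "condition": ["A", "A", "B", "B"],
         "replicate": [1, 2, 1, 2]}
    )
    m = ExpressionMatrix(values, design)
    assert probe_ratios(m)["p1"] == pytest.approx(1.0)
    bad = design.copy()
    bad.loc[3, "condition"] = "A"  # only one B replicate
    with pytest.raises(ExpressionError):
        ExpressionMatrix(values, bad)


def test_screen_recovers_planted_targets_noise_free(zero_noise_bundle):
    """On noise-free data the 1.5-fold screen has sensitivity = specificity = 1."""
    from dreamscreen import io_formats as iof

    b = zero_noise_bundle
    matrix = ExpressionMatrix(
        iof.read_expression_tsv(b.path("expression")),
        iof.read_table(b.path("expression_design"),
                       {"sample": str, "condition": str, "replicate": int}),
    )
    pmap = iof.read_table(b.path("probe_map"), {"probe_id": str, "gene_id": str})
    folds = gene_folds(probe_ratios(matrix), pmap)
    selected = select_downregulated(folds, 1.5)
    truth = b.truth
    planted = set(truth.loc[truth.is_true_target, "gene_id"])
    assert selected == planted
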