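"""Probe-level repression screen on a synthetic expression bundle.

Log2 intensities are linearized, averaged per condition, collapsed to the
best probe per gene, and genes repressed at least 1.5-fold in differentiated
cells are selected — then filtered to those with a negative p53 regulation
score in mouse and/or human.
"""

import tempfile

from dreamscreen import (
    ExpressionMatrix, SyntheticConfig, make_bundle,
    gene_folds, p53_direction_filter, select_downregulated,
)
from dreamscreen import io_formats as iof
from dreamscreen.expression import probe_ratios

with tempfile.TemporaryDirectory() as tmp:
    bundle = make_bundle(SyntheticConfig(seed=11, n_genes=120), tmp)
    matrix = ExpressionMatrix(
        iof.read_expression_tsv(bundle.path("expression")),
        iof.read_table(bundle.path("expression_design"),
                       {"sample": str, "condition": str, "replicate": int}),
    )
    probe_map = iof.read_table(bundle.path("probe_map"), {"probe_id": str, "gene_id": str})
    folds = gene_folds(probe_ratios(matrix), probe_map)
    selected = select_downregulated(folds, threshold=1.5)
    scores = iof.read_table(bundle.path("regulation_scores"),
                            {"gene_id": str, "score_mouse": float, "score_human": float},
                            index_col="gene_id")
    direction, missing = p53_direction_filter(selected, scores)
    truth = bundle.truth
    planted = set(truth.loc[truth.is_true_target, "gene_id"])
    print(f"{len(folds)} genes measured on {len(probe_map)} probes")
    print(f"{len(selected)} genes repressed >= 1.5-fold "
          f"(planted: {len(planted)}; recovered: {len(selected & planted)})")
    print(f"{len(direction)} of them also score as p53-repressed in the "
          f"regulation table")
    top = folds.loc[sorted(selected)].nlargest(3, "repression_ratio")
    print("strongest repression folds (gene, best probe, fold):")
    for gene, row in top.iterrows():
        print(f"  {gene}  {row.best_probe_id}  {row.repression_ratio:.2f}")
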