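import hashlib
import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from dreamscreen import io_formats as iof
from dreamscreen.expression import ExpressionMatrix, gene_folds, probe_ratios
from dreamscreen.pfm import pvalue_table
from dreamscreen.conservation import CDE_POSITIONS, CHR_POSITIONS
from dreamscreen.synthetic import (
    SyntheticConfig,
    SyntheticConfigError,
    default_pfm,
    make_bundle,
    plant_dbs,
    simulate_expression,
)


def sha_tree(root: Path) -> dict:
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(Path(root).iterdir())}


def test_same_seed_reproduces_identical_bytes(tmp_path):
    cfg = SyntheticConfig(seed=1, n_genes=60)
    b1 = make_bundle(cfg, tmp_path / "one")
    b2 = make_bundle(cfg, tmp_path / "two")
    assert sha_tree(b1.root) == sha_tree(b2.root)
    b3 = make_bundle(SyntheticConfig(seed=2, n_genes=60), tmp_path / "three")
    assert sha_tree(b3.root) != sha_tree(b1.root)


def test_zero_fraction_plants_nothing(tmp_path):
    b = make_bundle(SyntheticConfig(seed=3, n_genes=40, frac_true_targets=0.0),
                    tmp_path / "none")
    assert int(b.truth.is_true_target.sum()) == 0
    assert (b.truth.planted_rank == "").all()


def test_target_count_forced_by_fractions(zero_noise_bundle):
    truth = zero_noise_bundle.truth
    assert len(truth) == 200
    assert int(truth.is_true_target.sum()) == 60  # 200 x 0.3


def test_config_validation():
    with pytest.raises(SyntheticConfigError):
        SyntheticConfig(frac_true_targets=1.2)
    with pytest.raises(SyntheticConfigError):
        SyntheticConfig(peak_score_range=(500, 1500))
    with pytest.raises(SyntheticConfigError):
        SyntheticConfig(promoter_len=30)  # too short for motif plus flanks


def test_zero_noise_fold_is_exact(tmp_path):
    cfg = SyntheticConfig(seed=4, n_genes=50, noise_sd=0.0,
                          repression_log2fc=math.log2(1.5),
                          repression_log2fc_spread=0.0)
    b = make_bundle(cfg, tmp_path / "exact")
    truth = b.truth
    matrix = ExpressionMatrix(
        iof.read_expression_tsv(b.path("expression")),
        iof.read_table(b.path("expression_design"),
                       {"sample": str, "condition": str, "replicate": int}),
    )
    pmap = iof.read_table(b.path("probe_map"), {"probe_id": str, "gene_id": str})
    folds = gene_folds(probe_ratios(matrix), pmap)
    for row in truth.itertuples(index=False):
        expected = 1.5 if row.is_true_target else 1.0
        assert folds.loc[row.gene_id, "repression_ratio"] == pytest.approx(
            expected, rel=1e-5)


def test_probe_map_covers_every_gene(zero_noise_bundle):
    pmap = iof.read_table(zero_noise_bundle.path("probe_map"),
                          {"probe_id": str, "gene_id": str})
    assert set(pmap["gene_id"]) == set(zero_noise_bundle.truth["gene_id"])
    per_gene = pmap.groupby("gene_id").size()
    assert per_gene.between(1, 4).all()


@pytest.mark.parametrize("rank, n_mm", [("A", 1), ("B", 2), ("B", 3), ("C", 4), ("D", 0)])
def test_plant_dbs_mismatch_counts_by_rank(rank, n_mm):
    pfm = default_pfm()
    table = pvalue_table(pfm)
    rng = np.random.default_rng(9)
    prom = "A" * 400
    m, h, rec = plant_dbs(prom, prom, 300, 300, pfm, rank, n_mismatches=n_mm,
                          offset=-120, rng=rng, table=table)
    assert rec is not None and rec.rank == rank
    conserved = list(CDE_POSITIONS) + list(CHR_POSITIONS)
    mm = sum(1 for p in conserved if rec.site_m[p - 1] != rec.site_h[p - 1])
    assert mm == n_mm
    # mismatches are confined to conservation-relevant positions
    others = [p for p in range(1, 17) if p not in conserved
              and p not in pfm.spacer_positions]
    assert all(rec.site_m[p - 1] == rec.site_h[p - 1] for p in others)
    # both sites are embedded at the same TSS-relative offset
    assert m[300 - 120 : 300 - 120 + 16] == rec.site_m
    assert h[300 - 120 : 300 - 120 + 16] == rec.site_h
    # rank D means a negative score that still passes the scan threshold
    if rank == "D":
        thr = table.threshold_int(1e-3)
        from dreamscreen.synthetic import _int_score
        s = _int_score(table, rec.site_m)
        assert thr <= s < 0


def test_all_emitted_files_parse(zero_noise_bundle):
    b = zero_noise_bundle
    iof.read_expression_tsv(b.path("expression"))
    iof.read_table(b.path("expression_design"),
                   {"sample": str, "condition": str, "replicate": int})
    iof.read_table(b.path("probe_map"), {"probe_id": str, "gene_id": str})
    iof.read_table(b.path("regulation_scores"),
                   {"gene_id": str, "score_mouse": float, "score_human": float})
    iof.read_gmt(b.path("annotations"))
    iof.read_pfm(b.path("pfm"))
    iof.read_table(b.path("orthologs"), {"mouse_id": str, "human_id": str})
    for sp in ("mouse", "human"):
        recs = iof.read_promoter_fasta(b.path(f"promoters_{sp}"))
        assert len(recs) == len(b.truth)
        iof.read_table(b.path(f"tss_{sp}"),
                       {"gene_id": str, "chrom": str, "tss": int, "strand": str})
        for f in ("e2f4", "lin9"):
            bed = iof.read_bed(b.path(f"peaks_{f}_{sp}"))
            assert bed["score"].between(0, 1000).all()
    for ds in (1, 2):
        counts = iof.read_table(b.path(f"rnaseq_counts_{ds}"), {"gene_id": str},
                                index_col="gene_id").astype(float)
        assert (counts >= 0).all().all()
        iof.read_table(b.path(f"rnaseq_design_{ds}"), {"sample": str, "group": str})
    assert len(iof.read_gene_list(b.path("ta_genes"))) == 15


def test_planted_sites_recovered_by_scan(zero_noise_bundle):
    """Every planted site is reported by the scanner at its planted offset."""
    b = zero_noise_bundle
    pfm = iof.read_pfm(b.path("pfm"))
    table = pvalue_table(pfm)
    from dreamscreen.pfm import scan_promoter

    promoters = {r.gene_id: r for r in iof.read_promoter_fasta(b.path("promoters_mouse"))}
    planted = b.truth[b.truth.planted_rank != ""]
    for row in planted.itertuples(index=False):
        hits = scan_promoter(pfm, promoters[row.gene_id], table=table)
        assert any(h.offset == int(row.dbs_offset) and h.sequence == row.dbs_site_mouse
                   for h in hits)
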