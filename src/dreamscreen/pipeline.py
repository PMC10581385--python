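"""End-to-end orchestration of the p53-DREAM target screen.

Branches (e.g. blood-related and brain-related ontology terms) are analyzed
separately through the same cascade of shrinking filters — expression screen,
ontology/curated-list selection, p53 regulation direction, E2F4+LIN9
co-binding with the total-ChIP-score cutoff, RNA-seq consistency pruning —
and the surviving branch sets are merged by inclusion-exclusion. The merged
candidates are then scanned for gapped bipartite DREAM-binding sites within
their ChIP-bound promoter regions, orthologous site pairs are ranked A-D by
conservation, and sites are mapped to ChIP-peak centers and TSSs in 50-bp
windows with a fold-enrichment and log-space tail test over the
promoter-wide site frequency.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats as iof
from .expression import (
    ExpressionMatrix,
    probe_ratios,
    gene_folds,
    select_downregulated,
    p53_direction_filter,
)
from .enrichment import enrich, term_union, curated_intersect
from .chip import summarize_chip, cobinding, total_chip_score, candidate_filter
from .rnaseq import rnaseq_fold, combine_folds, control_check, prune_upregulated
from .pfm import scan_promoter, pvalue_table
from .conservation import pair_hits
from .mapping import (
    offset_histogram,
    genome_window_frequency,
    enrichment_fold,
    log_tail_test,
)

logger = logging.getLogger(__name__)

SPECIES = ("mouse", "human")
FACTORS = ("E2F4", "LIN9")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Input paths and thresholds of one screen run."""

    expression: Path
    expression_design: Path
    probe_map: Path
    regulation_scores: Path
    annotations: Path
    branches: dict  # name -> {"terms": path, "curated": path}
    peaks: dict  # (factor, species) -> path
    tss: dict  # species -> path
    promoters: dict  # species -> path
    orthologs: Path
    pfm: Path
    rnaseq: list  # [{"counts": path, "design": path}, ...]
    ta_genes: Path
    fold_threshold: float = 1.5
    enrich_p: float = 1e-3
    min_total: float = 979.0
    scan_p: float = 1e-3
    rnaseq_threshold: float = 1.5
    chip_window: int = 5000
    pair_offset_shift: int = 20
    peak_margin: int = 50
    bin_width: int = 50
    seed: int = 0

    @classmethod
    def from_bundle(cls, bundle, **overrides) -> "PipelineConfig":
        """Configuration pointing at a synthetic fixture bundle."""
        p = bundle.paths
        cfg = cls(
            expression=p["expression"],
            expression_design=p["expression_design"],
            probe_map=p["probe_map"],
            regulation_scores=p["regulation_scores"],
            annotations=p["annotations"],
            branches={
                b: {"terms": p[f"{b}_terms"], "curated": p[f"{b}_curated"]}
                for b in ("blood", "brain")
            },
            peaks={
                (f, sp): p[f"peaks_{f.lower()}_{sp}"] for f in FACTORS for sp in SPECIES
            },
            tss={sp: p[f"tss_{sp}"] for sp in SPECIES},
            promoters={sp: p[f"promoters_{sp}"] for sp in SPECIES},
            orthologs=p["orthologs"],
            pfm=p["pfm"],
            rnaseq=[
                {"counts": p[f"rnaseq_counts_{i}"], "design": p[f"rnaseq_design_{i}"]}
                for i in (1, 2)
            ],
            ta_genes=p["ta_genes"],
            seed=bundle.config.seed,
        )
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        def rp(x):
            q = Path(x)
            return q if q.is_absolute() else base / q
        peaks = {tuple(k.split("_", 1)): rp(v) for k, v in raw["peaks"].items()}
        peaks = {(f.upper(), sp): v for (f, sp), v in peaks.items()}
        return cls(
            expression=rp(raw["expression"]),
            expression_design=rp(raw["expression_design"]),
            probe_map=rp(raw["probe_map"]),
            regulation_scores=rp(raw["regulation_scores"]),
            annotations=rp(raw["annotations"]),
            branches={
                b: {"terms": rp(v["terms"]), "curated": rp(v["curated"])}
                for b, v in raw["branches"].items()
            },
            peaks=peaks,
            tss={sp: rp(v) for sp, v in raw["tss"].items()},
            promoters={sp: rp(v) for sp, v in raw["promoters"].items()},
            orthologs=rp(raw["orthologs"]),
            pfm=rp(raw["pfm"]),
            rnaseq=[{"counts": rp(d["counts"]), "design": rp(d["design"])} for d in raw["rnaseq"]],
            ta_genes=rp(raw["ta_genes"]),
            **{k: raw[k] for k in (
                "fold_threshold", "enrich_p", "min_total", "scan_p", "rnaseq_threshold",
                "chip_window", "pair_offset_shift", "peak_margin", "bin_width", "seed",
            ) if k in raw},
        )

    def config_hash(self) -> str:
        payload = repr(sorted(
            (k, str(v)) for k, v in dataclasses.asdict(self).items()
        )).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class PipelineResult:
    candidates: pd.DataFrame
    stage_counts: pd.DataFrame
    histograms: pd.DataFrame
    enrichment_stats: dict
    control_fraction: float
    report: str
    log_lines: list[str] = field(default_factory=list)

    @property
    def candidate_genes(self) -> set[str]:
        return set(self.candidates["gene_id"])


def union_counts(size_a: int, size_b: int, intersection: int) -> int:
    """Inclusion-exclusion union size |A| + |B| - |A n B| with validation."""
    if intersection > min(size_a, size_b) or min(size_a, size_b, intersection) < 0:
        raise PipelineError(
            f"inconsistent sizes: |A|={size_a}, |B|={size_b}, |AnB|={intersection}"
        )
    return size_a + size_b - intersection


def _log(lines: list[str], stage: str, genes, reason: str) -> None:
    for g in sorted(genes):
        lines.append(f"{stage}\t{g}\t{reason}")


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full screen; optionally write result tables under ``out_dir``."""
    log_lines: list[str] = []
    stage_rows: list[dict] = []

    # ---- expression screen ----------------------------------------------
    values = iof.read_expression_tsv(config.expression)
    design = iof.read_table(config.expression_design,
                            {"sample": str, "condition": str, "replicate": int})
    matrix = ExpressionMatrix(values, design)
    probe_map = iof.read_table(config.probe_map, {"probe_id": str, "gene_id": str})
    ratios = probe_ratios(matrix)
    folds = gene_folds(ratios, probe_map)
    all_genes = set(folds.index)
    screen_set = select_downregulated(folds, config.fold_threshold)
    _log(log_lines, "screen", all_genes - screen_set,
         f"repression ratio < {config.fold_threshold}")

    # ---- shared resources ------------------------------------------------
    scores = iof.read_table(
        config.regulation_scores,
        {"gene_id": str, "score_mouse": float, "score_human": float},
        index_col="gene_id",
    )
    annotations = iof.read_gmt(config.annotations)
    orth = iof.read_table(config.orthologs, {"mouse_id": str, "human_id": str})
    ortholog_map = dict(zip(orth["mouse_id"], orth["human_id"]))

    peaks = {key: iof.read_bed(path) for key, path in config.peaks.items()}
    tss_tables = {
        sp: iof.read_table(path, {"gene_id": str, "chrom": str, "tss": int, "strand": str})
        for sp, path in config.tss.items()
    }
    gene_map = {"human": ortholog_map, "mouse": {}}
    summaries = summarize_chip(peaks, tss_tables, gene_map=gene_map,
                               search_window=config.chip_window)

    # ---- RNA-seq validation folds ---------------------------------------
    ds_folds = []
    for ds in config.rnaseq:
        counts = iof.read_table(ds["counts"], {"gene_id": str}, index_col="gene_id").astype(float)
        ds_design = iof.read_table(ds["design"], {"sample": str, "group": str})
        ds_folds.append(rnaseq_fold(counts, ds_design))
    combined_folds = combine_folds(ds_folds)
    ta = iof.read_gene_list(config.ta_genes)
    control_frac = control_check(combined_folds, ta, config.rnaseq_threshold)

    # ---- per-branch cascade ----------------------------------------------
    branch_sets: dict[str, set[str]] = {}
    for branch, files in config.branches.items():
        branch_terms = set(iof.read_gene_list(files["terms"]))
        curated = iof.read_gene_list(files["curated"])
        enriched = enrich(screen_set, all_genes, annotations, p_threshold=config.enrich_p)
        enriched_branch = [r.term_id for r in enriched if r.term_id in branch_terms]
        pool = term_union(enriched_branch, annotations) if enriched_branch else set()
        pool |= curated_intersect(all_genes, curated)
        selected = screen_set & pool
        _log(log_lines, f"{branch}:select", screen_set - selected,
             "not in enriched branch terms or curated list")

        direction, missing = p53_direction_filter(selected, scores)
        _log(log_lines, f"{branch}:p53", selected - direction,
             "not repressed upon p53 activation (or no score)")

        chip_pass = {
            g for g in direction
            if g in summaries and cobinding(summaries[g])
            and total_chip_score(summaries[g]) >= config.min_total
        }
        _log(log_lines, f"{branch}:chip", direction - chip_pass,
             f"not cobound or total ChIP score < {config.min_total}")

        kept, removed, missing_rna = prune_upregulated(
            chip_pass, combined_folds, config.rnaseq_threshold
        )
        _log(log_lines, f"{branch}:rnaseq", removed,
             f"upregulated >= {config.rnaseq_threshold}-fold with p53 activity")

        branch_sets[branch] = kept
        stage_rows.append(
            {
                "branch": branch,
                "screen": len(screen_set),
                "selected": len(selected),
                "p53_direction": len(direction),
                "chip": len(chip_pass),
                "final": len(kept),
            }
        )

    names = sorted(branch_sets)
    union_set: set[str] = set().union(*branch_sets.values()) if branch_sets else set()
    if len(names) == 2:
        a, b = branch_sets[names[0]], branch_sets[names[1]]
        assert union_counts(len(a), len(b), len(a & b)) == len(union_set)
    stage_rows.append(
        {"branch": "union", "screen": len(screen_set), "selected": np.nan,
         "p53_direction": np.nan, "chip": np.nan, "final": len(union_set)}
    )

    # ---- DBS scan, conservation ranking ---------------------------------
    pfm = iof.read_pfm(config.pfm)
    table = pvalue_table(pfm)
    promoters = {
        sp: {r.gene_id: r for r in iof.read_promoter_fasta(path)}
        for sp, path in config.promoters.items()
    }
    tss_lookup = {
        sp: tss_tables[sp].drop_duplicates("gene_id").set_index("gene_id")
        for sp in SPECIES
    }

    def genomic_center(sp: str, gene: str, center_offset: float) -> float | None:
        if gene not in tss_lookup[sp].index:
            return None
        row = tss_lookup[sp].loc[gene]
        sign = 1 if row["strand"] == "+" else -1
        return float(row["tss"]) + sign * center_offset

    def near_peak(sp: str, ref_gene: str, gene: str, hit) -> bool:
        """Keep hits inside the ChIP-bound promoter region (peak +- margin)."""
        s = summaries.get(ref_gene)
        if s is None:
            return False
        g = genomic_center(sp, gene, hit.center_offset)
        if g is None:
            return False
        for (factor, species), ev in s.evidence.items():
            if species != sp or ev is None:
                continue
            if ev.start - config.peak_margin <= g < ev.end + config.peak_margin:
                return True
        return False

    hits_m: dict[str, list] = {}
    hits_h: dict[str, list] = {}
    for gene in sorted(union_set):
        rec_m = promoters["mouse"].get(gene)
        if rec_m is not None:
            hits = scan_promoter(pfm, rec_m, p_max=config.scan_p, table=table)
            hits = [h for h in hits if near_peak("mouse", gene, gene, h)]
            if hits:
                hits_m[gene] = hits
        hgene = ortholog_map.get(gene)
        rec_h = promoters["human"].get(hgene) if hgene else None
        if rec_h is not None:
            hits = scan_promoter(pfm, rec_h, p_max=config.scan_p, table=table)
            hits = [h for h in hits if near_peak("human", gene, hgene, h)]
            if hits:
                hits_h[hgene] = hits
    pairs = pair_hits(hits_m, hits_h, ortholog_map,
                      max_offset_shift=config.pair_offset_shift)
    pair_by_gene = {p.gene_id_m: p for p in pairs}

    # ---- mapping and enrichment statistics -------------------------------
    peak_offsets: list[float | None] = []
    tss_offsets: list[float] = []
    ranked_genes = []
    for gene in sorted(union_set):
        pr = pair_by_gene.get(gene)
        if pr is None or pr.hit_m is None:
            continue
        ranked_genes.append(gene)
        hit = pr.hit_m
        tss_offsets.append(hit.center_offset)
        s = summaries.get(gene)
        best_ev = None
        if s is not None:
            evs = [ev for (f, sp), ev in s.evidence.items() if sp == "mouse" and ev is not None]
            if evs:
                best_ev = max(evs, key=lambda e: e.score)
        if best_ev is None:
            peak_offsets.append(None)
        else:
            g = genomic_center("mouse", gene, hit.center_offset)
            peak_center = (best_ev.start + best_ev.end) / 2.0
            peak_offsets.append(g - peak_center)
    hist_peak = offset_histogram(peak_offsets, config.bin_width, anchor="peak_center")
    hist_tss = offset_histogram(tss_offsets, config.bin_width, anchor="TSS")

    n_examined = len(ranked_genes)
    half_window = config.bin_width / 2.0
    k_at_peak = sum(
        1 for off in peak_offsets if off is not None and abs(off) <= half_window
    )
    seqs = [
        (f"{sp}:{gid}", rec.seq)
        for sp in SPECIES
        for gid, rec in sorted(promoters[sp].items())
    ]
    f_bg, n_windows, n_hit_windows = genome_window_frequency(
        seqs, pfm, bin_width=config.bin_width, p_max=config.scan_p, table=table
    )
    enr_stats: dict = {
        "n": n_examined, "k": k_at_peak, "f": f_bg,
        "n_windows": n_windows, "n_hit_windows": n_hit_windows,
    }
    if n_examined > 0 and f_bg > 0:
        enr_stats["fold"] = enrichment_fold(k_at_peak, n_examined, f_bg)
        enr_stats["log10_p"] = log_tail_test(n_examined, k_at_peak, f_bg,
                                             population=n_windows)
    else:
        enr_stats["fold"] = float("nan")
        enr_stats["log10_p"] = float("nan")

    # ---- candidate table --------------------------------------------------
    rows = []
    for gene in sorted(union_set):
        pr = pair_by_gene.get(gene)
        s = summaries.get(gene)
        rows.append(
            {
                "gene_id": gene,
                "blood": gene in branch_sets.get("blood", set()),
                "brain": gene in branch_sets.get("brain", set()),
                "repression_ratio": float(folds.loc[gene, "repression_ratio"]),
                "total_chip_score": total_chip_score(s) if s else 0.0,
                "cobound": cobinding(s) if s else False,
                "rnaseq_fold": float(combined_folds.get(gene, np.nan)),
                "rank": (pr.rank or "") if pr else "",
                "dbs_offset_tss": pr.hit_m.offset if pr and pr.hit_m else np.nan,
                "dbs_site_mouse": pr.hit_m.sequence if pr and pr.hit_m else "",
                "dbs_site_human": pr.hit_h.sequence if pr and pr.hit_h else "",
                "dbs_score_mouse": pr.hit_m.score if pr and pr.hit_m else np.nan,
                "dbs_score_human": pr.hit_h.score if pr and pr.hit_h else np.nan,
            }
        )
    candidates = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "blood", "brain", "repression_ratio", "total_chip_score",
            "cobound", "rnaseq_fold", "rank", "dbs_offset_tss",
            "dbs_site_mouse", "dbs_site_human", "dbs_score_mouse", "dbs_score_human",
        ],
    )
    stage_counts = pd.DataFrame(stage_rows)

    hist_rows = []
    for hist in (hist_peak, hist_tss):
        for b in sorted(hist.counts):
            hist_rows.append(
                {"anchor": hist.anchor, "bin_start": b * hist.bin_width,
                 "bin_end": (b + 1) * hist.bin_width, "count": hist.counts[b]}
            )
    histograms = pd.DataFrame(hist_rows, columns=["anchor", "bin_start", "bin_end", "count"])

    report = _render_report(config, stage_counts, candidates, enr_stats, control_frac)
    result = PipelineResult(
        candidates=candidates,
        stage_counts=stage_counts,
        histograms=histograms,
        enrichment_stats=enr_stats,
        control_fraction=control_frac,
        report=report,
        log_lines=log_lines,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        h = config.config_hash()
        iof.write_table(candidates, out / "candidates.tsv", config_hash=h)
        iof.write_table(stage_counts, out / "stage_counts.tsv", config_hash=h)
        iof.write_table(histograms, out / "histograms.tsv", config_hash=h)
        (out / "report.md").write_text(report)
        (out / "run.log").write_text("\n".join(log_lines) + ("\n" if log_lines else ""))
    return result


def _render_report(config, stage_counts, candidates, enr, control_frac) -> str:
    lines = [
        "# p53-DREAM target screen report",
        "",
        "## Thresholds",
        f"- repression fold >= {config.fold_threshold} (inclusive)",
        f"- term enrichment p <= {config.enrich_p}",
        f"- total ChIP score >= {config.min_total} with E2F4/LIN9 co-binding",
        f"- validation RNA-seq pruning at fold >= {config.rnaseq_threshold}",
        f"- motif scan p <= {config.scan_p}, transcript strand only",
        f"- config hash {config.config_hash()}",
        "",
        "## Stage counts",
        stage_counts.to_string(index=False),
        "",
        "## Validation controls",
        f"- fraction of p53-transactivated controls responding: {control_frac:.3f}",
        "",
        "## DBS mapping",
        f"- genes with a ranked DBS: {enr['n']}",
        f"- sites within the central {int(2 * (50 // 2))}-bp window at ChIP peaks: {enr['k']}",
        f"- promoter-wide site-window frequency f = {enr['f']:.3g}",
        f"- fold enrichment at peaks: {enr['fold']:.1f}" if not math.isnan(enr["fold"]) else
        "- fold enrichment at peaks: undefined (no background hits)",
        f"- log10 tail probability: {enr['log10_p']:.1f}" if not math.isnan(enr["log10_p"]) else
        "- log10 tail probability: undefined",
        "- note: the fold enrichment is an underestimate whenever the foreground",
        "  sites were conservation-filtered but the background frequency was not.",
        "",
        "## Final candidates",
        f"- {len(candidates)} genes ({int(candidates['rank'].ne('').sum())} with a ranked DBS)",
        "",
    ]
    return "\n".join(lines)
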