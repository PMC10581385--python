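"""Per-gene ChIP evidence integration across factors and species.

For every gene and every (factor, species) slot — E2F4/LIN9 in mouse and
human — the best peak within a window around the TSS is selected: highest
score first, then minimal distance to the TSS, then smallest start. A gene
is called cobound when, in at least one species, its best E2F4 and best LIN9
intervals overlap by at least one base (half-open semantics: touching
intervals do not overlap). The total ChIP score sums the up-to-four best
scores (absent evidence contributes 0, scores clamped to [0, 1000], maximum
4000), and the candidate filter keeps cobound genes whose total reaches the
configured cutoff (default 979, inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FACTORS = ("E2F4", "LIN9")
SPECIES = ("mouse", "human")
DEFAULT_WINDOW = 5000
DEFAULT_MIN_TOTAL = 979.0


class ChipError(ValueError):
    pass


@dataclass(frozen=True)
class PeakEvidence:
    """Best peak for one (factor, species) slot of a gene."""

    score: float
    distance: float  # signed bp, upstream negative on the gene strand
    start: int
    end: int
    chrom: str


@dataclass
class GeneChipSummary:
    gene_id: str
    evidence: dict = field(default_factory=dict)  # (factor, species) -> PeakEvidence

    @property
    def cobound(self) -> bool:
        return cobinding(self)

    @property
    def total_score(self) -> float:
        return total_chip_score(self)


def best_peak(
    tss: int,
    strand: str,
    peaks: pd.DataFrame,
    chrom: str | None = None,
    search_window: int = DEFAULT_WINDOW,
) -> PeakEvidence | None:
    """Best-evidence peak near one TSS, or None if no peak enters the window.

    Among peaks intersecting [tss - w, tss + w): maximum score wins; ties
    break by minimal |center - tss|, then by smallest start. The reported
    distance is signed on the gene strand (upstream negative).
    """
    if search_window <= 0:
        raise ChipError("search window must be positive")
    if tss is None:
        raise ChipError("TSS unknown")
    df = peaks
    if chrom is not None and "chrom" in df.columns:
        df = df[df["chrom"] == chrom]
    lo, hi = tss - search_window, tss + search_window
    df = df[(df["start"] < hi) & (df["end"] > lo)]
    if df.empty:
        return None
    center = (df["start"] + df["end"]) / 2.0
    order = pd.DataFrame(
        {
            "score": df["score"],
            "absdist": (center - tss).abs(),
            "start": df["start"],
        },
        index=df.index,
    ).sort_values(["score", "absdist", "start"], ascending=[False, True, True])
    idx = order.index[0]
    row = df.loc[idx]
    c = (row["start"] + row["end"]) / 2.0
    distance = c - tss if strand == "+" else tss - c
    return PeakEvidence(
        score=float(row["score"]),
        distance=float(distance),
        start=int(row["start"]),
        end=int(row["end"]),
        chrom=str(row["chrom"]) if "chrom" in row else "",
    )


def cobinding(summary: GeneChipSummary) -> bool:
    """True iff best E2F4 and best LIN9 intervals overlap in >= 1 species."""
    for sp in SPECIES:
        e = summary.evidence.get(("E2F4", sp))
        l = summary.evidence.get(("LIN9", sp))
        if e is None or l is None:
            continue
        if e.chrom == l.chrom and e.start < l.end and l.start < e.end:
            return True
    return False


def total_chip_score(summary: GeneChipSummary) -> float:
    """Sum of the up-to-four best slot scores, each clamped to [0, 1000]."""
    total = 0.0
    for ev in summary.evidence.values():
        if ev is not None:
            total += float(np.clip(ev.score, 0.0, 1000.0))
    return total


def candidate_filter(
    summaries: dict[str, GeneChipSummary],
    min_total: float = DEFAULT_MIN_TOTAL,
) -> set[str]:
    """Cobound genes with total ChIP score >= min_total (inclusive)."""
    return {
        g for g, s in summaries.items() if cobinding(s) and total_chip_score(s) >= min_total
    }


def summarize_chip(
    peaks: dict[tuple[str, str], pd.DataFrame],
    tss_tables: dict[str, pd.DataFrame],
    gene_map: dict[str, dict[str, str]] | None = None,
    search_window: int = DEFAULT_WINDOW,
) -> dict[str, GeneChipSummary]:
    """Best-evidence summaries for every gene in the mouse TSS table.

    ``peaks`` maps (factor, species) to a BED frame; ``tss_tables`` maps
    species to a TSS frame (gene_id, chrom, tss, strand) that may carry
    several TSS rows per gene. ``gene_map`` translates the reference (mouse)
    gene id to each species' id (identity by default). For a multi-TSS gene
    the TSS whose best peak scores highest — then lies closest — is used, and
    the choice is logged.
    """
    gene_map = gene_map or {}
    ref_tss = tss_tables["mouse"]
    summaries: dict[str, GeneChipSummary] = {}
    for gene in sorted(ref_tss["gene_id"].unique()):
        summary = GeneChipSummary(gene_id=gene)
        for sp in SPECIES:
            sp_gene = gene_map.get(sp, {}).get(gene, gene)
            tdf = tss_tables.get(sp)
            if tdf is None:
                continue
            rows = tdf[tdf["gene_id"] == sp_gene]
            if rows.empty:
                continue
            for factor in FACTORS:
                pdf = peaks.get((factor, sp))
                if pdf is None or pdf.empty:
                    continue
                candidates = []
                for _, r in rows.iterrows():
                    ev = best_peak(int(r["tss"]), str(r["strand"]), pdf,
                                   chrom=str(r["chrom"]), search_window=search_window)
                    if ev is not None:
                        candidates.append(ev)
                if not candidates:
                    continue
                candidates.sort(key=lambda e: (-e.score, abs(e.distance), e.start))
                if len(rows) > 1:
                    logger.info("gene %s (%s/%s): %d TSSs, kept the one nearest the top peak",
                                gene, factor, sp, len(rows))
                summary.evidence[(factor, sp)] = candidates[0]
        summaries[gene] = summary
    return summaries


def summaries_frame(summaries: dict[str, GeneChipSummary]) -> pd.DataFrame:
    """Flatten summaries for TSV output."""
    rows = []
    for gene in sorted(summaries):
        s = summaries[gene]
        row: dict = {"gene_id": gene, "cobound": cobinding(s),
                     "total_score": total_chip_score(s)}
        for factor in FACTORS:
            for sp in SPECIES:
                ev = s.evidence.get((factor, sp))
                key = f"{factor.lower()}_{sp}"
                row[f"{key}_score"] = ev.score if ev else np.nan
                row[f"{key}_distance"] = ev.distance if ev else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
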