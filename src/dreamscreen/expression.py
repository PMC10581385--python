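"""Probe-level fold-change screen and p53 regulation-direction filter.

The screen works on RMA-like log2 intensities from a two-condition design
(condition A: proliferating, tamoxifen-maintained cells; condition B:
differentiated cells after withdrawal). Values are linearized before
averaging, the per-probe repression ratio is mean(A)/mean(B) on the linear
scale, genes collapse to their best (highest-ratio) probe, and the screen
keeps genes repressed at least 1.5-fold. A second filter keeps only genes
with a negative p53 regulation score (i.e. repressed upon p53 activation) in
mouse and/or human.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITION_A = "A"  # +OHT-like (proliferating)
CONDITION_B = "B"  # -OHT-like (differentiated)


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Probe x sample log2 intensities plus the condition/replicate design.

    ``design`` maps each sample column to a condition label in {A, B} and a
    replicate index; both conditions need at least two replicates and no
    value may be missing.
    """

    values: pd.DataFrame
    design: pd.DataFrame  # columns: sample, condition, replicate

    def __post_init__(self):
        required = {"sample", "condition", "replicate"}
        if not required.issubset(self.design.columns):
            raise ExpressionError(f"design needs columns {sorted(required)}")
        unknown = set(self.design["condition"]) - {CONDITION_A, CONDITION_B}
        if unknown:
            raise ExpressionError(f"unknown condition labels {sorted(unknown)}")
        missing = set(self.design["sample"]) - set(self.values.columns)
        if missing:
            raise ExpressionError(f"design samples absent from matrix: {sorted(missing)}")
        counts = self.design["condition"].value_counts()
        for cond in (CONDITION_A, CONDITION_B):
            if counts.get(cond, 0) < 2:
                raise ExpressionError(f"condition {cond} needs at least 2 replicates")
        if self.values[self.samples(CONDITION_A) + self.samples(CONDITION_B)].isna().any().any():
            raise ExpressionError("expression matrix contains missing values")

    def samples(self, condition: str) -> list[str]:
        return self.design.loc[self.design["condition"] == condition, "sample"].tolist()


@dataclass(frozen=True)
class GeneFold:
    gene_id: str
    repression_ratio: float
    best_probe_id: str


def probe_ratio(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Repression ratio mean(2^a)/mean(2^b) of one probe (linear-scale means)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ExpressionError("both conditions need at least one value")
    return float(np.mean(2.0 ** a) / np.mean(2.0 ** b))


def probe_ratios(matrix: ExpressionMatrix) -> pd.Series:
    """Vectorized per-probe repression ratios for the whole matrix."""
    lin = 2.0 ** matrix.values
    mean_a = lin[matrix.samples(CONDITION_A)].mean(axis=1)
    mean_b = lin[matrix.samples(CONDITION_B)].mean(axis=1)
    out = mean_a / mean_b
    out.name = "repression_ratio"
    return out


def gene_fold(gene_id: str, probe_map: Mapping[str, str], ratios: Mapping[str, float]) -> GeneFold:
    """Collapse a gene to its best probe: the one with the highest ratio.

    Ties break toward the lexicographically smallest probe id.
    """
    probes = sorted(p for p, g in probe_map.items() if g == gene_id)
    if not probes:
        raise ExpressionError(f"gene {gene_id!r} has no probes in the map")
    best = max(probes, key=lambda p: (ratios[p], ))  # max keeps first of equals: sorted => smallest id
    return GeneFold(gene_id, float(ratios[best]), best)


def gene_folds(ratios: pd.Series, probe_map: pd.DataFrame) -> pd.DataFrame:
    """Best-probe repression ratio per gene.

    ``probe_map`` has columns ``probe_id`` and ``gene_id``; ties on the ratio
    break toward the smallest probe id. Returns a frame indexed by gene with
    ``repression_ratio`` and ``best_probe_id``.
    """
    df = probe_map[["probe_id", "gene_id"]].copy()
    unknown = set(df["probe_id"]) - set(ratios.index)
    if unknown:
        raise ExpressionError(f"probes missing from the ratio table: {sorted(unknown)[:5]}")
    df["repression_ratio"] = df["probe_id"].map(ratios)
    df = df.sort_values(["gene_id", "repression_ratio", "probe_id"],
                        ascending=[True, False, True])
    best = df.groupby("gene_id", sort=True).first()
    best = best.rename(columns={"probe_id": "best_probe_id"})
    return best[["repression_ratio", "best_probe_id"]]


def select_downregulated(folds: pd.DataFrame | Mapping[str, float], threshold: float = 1.5) -> set[str]:
    """Genes repressed at least ``threshold``-fold (inclusive)."""
    if threshold <= 1:
        raise ExpressionError("threshold must exceed 1")
    if isinstance(folds, pd.DataFrame):
        ratios = folds["repression_ratio"]
        return set(ratios.index[ratios >= threshold])
    return {g for g, r in folds.items() if r >= threshold}


def p53_direction_filter(
    genes: Iterable[str],
    scores: pd.DataFrame,
) -> tuple[set[str], list[str]]:
    """Keep genes with a negative p53 regulation score in mouse and/or human.

    ``scores`` is indexed by gene with optional columns ``score_mouse`` and
    ``score_human`` (NaN = no data for that species). Genes absent from the
    table are dropped and returned separately for audit.
    """
    kept: set[str] = set()
    missing: list[str] = []
    for gene in genes:
        if gene not in scores.index:
            missing.append(gene)
            continue
        row = scores.loc[gene]
        vals = [row.get("score_mouse"), row.get("score_human")]
        vals = [v for v in vals if v is not None and not pd.isna(v)]
        if not vals:
            missing.append(gene)
            continue
        if any(v < 0 for v in vals):
            kept.add(gene)
    if missing:
        logger.warning("%d genes lacked a p53 regulation score and were dropped", len(missing))
    return kept, sorted(missing)
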