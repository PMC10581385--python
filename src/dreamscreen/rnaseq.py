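"""RNA-seq consistency pruning of candidate repression targets.

A gene proposed as a p53-DREAM repression target should not look upregulated
when p53 activity increases in independent validation RNA-seq. Counts are
normalized to counts-per-million, the per-gene fold is the ratio of group
means (p53-active over control) with a 0.5-CPM pseudocount added to each
mean, folds are combined across datasets by geometric mean, and candidates
with a combined fold >= 1.5 are pruned. A panel of known p53-transactivated
genes serves as a positive control: the pipeline warns when fewer than half
of them reach the fold threshold.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_ACTIVE = "p53_active"
GROUP_CONTROL = "control"
PSEUDOCOUNT_CPM = 0.5


class RnaseqError(ValueError):
    pass


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per sample; library sizes must be positive."""
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        bad = libsize.index[libsize <= 0].tolist()
        raise RnaseqError(f"non-positive library sizes for samples {bad}")
    return counts / libsize * 1e6


def rnaseq_fold(counts: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-gene expression fold (p53-active over control) for one dataset.

    ``design`` has columns ``sample`` and ``group`` with labels
    ``p53_active`` / ``control``. Returns a frame indexed by gene with
    columns ``fold`` and ``all_zero`` (flag for genes with zero counts in
    both groups, reported with fold 1.0).
    """
    required = {"sample", "group"}
    if not required.issubset(design.columns):
        raise RnaseqError(f"design needs columns {sorted(required)}")
    groups = set(design["group"])
    if not {GROUP_ACTIVE, GROUP_CONTROL}.issubset(groups):
        raise RnaseqError(f"design needs groups {GROUP_ACTIVE!r} and {GROUP_CONTROL!r}")
    if (counts < 0).any().any():
        raise RnaseqError("counts must be non-negative")
    active = design.loc[design["group"] == GROUP_ACTIVE, "sample"].tolist()
    control = design.loc[design["group"] == GROUP_CONTROL, "sample"].tolist()
    missing = (set(active) | set(control)) - set(counts.columns)
    if missing:
        raise RnaseqError(f"design samples absent from count table: {sorted(missing)}")
    norm = cpm(counts)
    mean_active = norm[active].mean(axis=1)
    mean_control = norm[control].mean(axis=1)
    fold = (mean_active + PSEUDOCOUNT_CPM) / (mean_control + PSEUDOCOUNT_CPM)
    all_zero = (counts[active + control].sum(axis=1) == 0)
    fold[all_zero] = 1.0
    return pd.DataFrame({"fold": fold, "all_zero": all_zero})


def combine_folds(folds: Sequence[pd.Series | pd.DataFrame]) -> pd.Series:
    """Geometric-mean aggregation of per-dataset folds.

    Genes absent from some datasets are averaged over the datasets where
    they appear.
    """
    if not folds:
        raise RnaseqError("no fold tables to combine")
    series = [f["fold"] if isinstance(f, pd.DataFrame) else f for f in folds]
    logs = pd.concat([np.log(s) for s in series], axis=1)
    return np.exp(logs.mean(axis=1, skipna=True)).rename("fold")


def control_check(
    folds: pd.Series | pd.DataFrame,
    ta_genes: Sequence[str],
    threshold: float = 1.5,
) -> float:
    """Fraction of p53-transactivated control genes with fold >= threshold.

    A fraction below 0.5 triggers a warning: the validation dataset then
    shows no convincing p53 response and pruning decisions are doubtful.
    """
    if len(ta_genes) == 0:
        raise RnaseqError("the transactivated-control panel is empty")
    if isinstance(folds, pd.DataFrame):
        folds = folds["fold"]
    present = [g for g in ta_genes if g in folds.index]
    if len(present) < len(ta_genes):
        logger.warning("%d control genes missing from the fold table",
                       len(ta_genes) - len(present))
    up = sum(1 for g in present if folds[g] >= threshold)
    frac = up / len(ta_genes)
    if frac < 0.5:
        logger.warning(
            "only %.0f%% of p53-transactivated controls responded (threshold %.2f): "
            "weak p53 activation in the validation data", 100 * frac, threshold)
    return frac


def prune_upregulated(
    candidates: Iterable[str],
    folds: pd.Series | pd.DataFrame,
    threshold: float = 1.5,
) -> tuple[set[str], set[str], list[str]]:
    """Remove candidates whose validation fold is >= threshold (inclusive).

    Genes absent from the fold table are retained and listed for audit.
    Returns (kept, removed, missing).
    """
    if isinstance(folds, pd.DataFrame):
        folds = folds["fold"]
    kept: set[str] = set()
    removed: set[str] = set()
    missing: list[str] = []
    for gene in candidates:
        if gene not in folds.index:
            missing.append(gene)
            kept.add(gene)
        elif folds[gene] >= threshold:
            removed.add(gene)
        else:
            kept.add(gene)
    if missing:
        logger.warning("%d candidates absent from RNA-seq, retained unpruned", len(missing))
    return kept, removed, sorted(missing)
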