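"""Unranked target-vs-background ontology enrichment and curated-list tools.

Enrichment follows the GOrilla-style unranked two-list mode: for each term,
the overlap b between the target list (size n) and the term's genes in the
background (B of N) is tested with the hypergeometric upper tail
P(X >= b), and terms with p <= 1e-3 (the tool's default cutoff) are
reported sorted by p. No multiple-testing correction enters the headline
filter; a Benjamini-Hochberg q-value column is emitted for transparency.

The universe N defaults to the genes carrying at least one annotation, the
convention that reproduces published annotated-background counts; pass
``universe="background"`` to use the full background instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .io_formats import TermAnnotation


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    description: str
    N: int
    B: int
    n: int
    b: int
    enrichment: float
    p_value: float
    q_value: float


def _hypergeom_upper_tail(N: int, B: int, n: int, b: int) -> float:
    """P(X >= b) for X ~ Hypergeometric(N, B, n)."""
    return float(stats.hypergeom.sf(b - 1, N, B, n))


def enrich(
    target: Iterable[str],
    background: Iterable[str],
    annotations: Mapping[str, TermAnnotation],
    p_threshold: float = 1e-3,
    universe: str = "annotated",
) -> list[EnrichmentResult]:
    """Hypergeometric term enrichment of ``target`` against ``background``.

    Returns the terms with p <= ``p_threshold`` sorted ascending by p (ties
    by term id). Raises if the target is not contained in the background.
    """
    target = set(target)
    background = set(background)
    if not background:
        raise EnrichmentError("background is empty")
    offenders = sorted(target - background)
    if offenders:
        raise EnrichmentError(f"target genes absent from background: {offenders[:10]}")
    if universe == "annotated":
        annotated = set()
        for t in annotations.values():
            annotated.update(t.genes)
        pool = background & annotated
    elif universe == "background":
        pool = background
    else:
        raise EnrichmentError(f"unknown universe mode {universe!r}")
    tgt = target & pool
    N, n = len(pool), len(tgt)
    rows = []
    for term_id in sorted(annotations):
        ann = annotations[term_id]
        term_genes = set(ann.genes) & pool
        B = len(term_genes)
        if B == 0:
            continue
        b = len(term_genes & tgt)
        p = _hypergeom_upper_tail(N, B, n, b) if b > 0 else 1.0
        enr = (b / n) / (B / N) if n > 0 else 0.0
        rows.append((term_id, ann.description, N, B, n, b, enr, p))
    if not rows:
        return []
    df = pd.DataFrame(rows, columns=["term_id", "description", "N", "B", "n", "b",
                                     "enrichment", "p_value"])
    df["q_value"] = stats.false_discovery_control(df["p_value"], method="bh")
    df = df[df["p_value"] <= p_threshold].sort_values(["p_value", "term_id"])
    return [EnrichmentResult(**row) for row in df.to_dict("records")]


def results_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def term_union(
    terms: Iterable[str],
    annotations: Mapping[str, TermAnnotation],
) -> set[str]:
    """Deduplicated union of the gene sets of the given terms."""
    out: set[str] = set()
    for term in terms:
        if term not in annotations:
            raise EnrichmentError(f"unknown term {term!r}")
        out.update(annotations[term].genes)
    return out


def curated_intersect(
    genes: Iterable[str],
    curated: Iterable[str],
    aliases: Mapping[str, str] | None = None,
) -> set[str]:
    """Intersect a gene set with a curated disease list.

    Symbols are matched case-insensitively after optional alias resolution
    (mouse and human symbol case conventions differ); the returned symbols
    come from ``genes``.
    """
    def norm(symbol: str) -> str:
        if aliases:
            symbol = aliases.get(symbol, aliases.get(symbol.upper(), symbol))
        return symbol.upper()

    curated_norm = {norm(g) for g in curated}
    return {g for g in genes if norm(g) in curated_norm}
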