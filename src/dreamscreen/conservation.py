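"""Cross-species conservation ranking of DREAM-binding sites.

A candidate site found in both a mouse promoter and its human ortholog is
classified into ranks A-D by combining the best PFM score across the two
species with the number of base mismatches at conservation-relevant
positions: 2-6 of the CDE (E2F) element and 11-16 of the CHR (CLE) element.
Position 1 and the 4-bp spacer (positions 7-10) are ignored. The extended
rank-C rule also admits sites with more than four mismatches when they are
confined to a single element, i.e. the other element is perfectly conserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .pfm import DbsHit, MOTIF_LENGTH

logger = logging.getLogger(__name__)

CDE_POSITIONS = tuple(range(2, 7))  # 1-based positions 2-6
CHR_POSITIONS = tuple(range(11, 17))  # 1-based positions 11-16

RANKS = ("A", "B", "C", "D")
_RANK_ORDER = {"A": 0, "B": 1, "C": 2, "D": 3, None: 4}


def count_mismatches(site_m: str, site_h: str) -> tuple[int, int]:
    """Per-position mismatch counts restricted to the CDE and CHR elements.

    The comparison is ungapped; spacer positions and position 1 are ignored.
    """
    if len(site_m) != MOTIF_LENGTH or len(site_h) != MOTIF_LENGTH:
        raise ValueError(
            f"sites must both have length {MOTIF_LENGTH}, got {len(site_m)} and {len(site_h)}"
        )
    a, b = site_m.upper(), site_h.upper()
    m_cde = sum(1 for p in CDE_POSITIONS if a[p - 1] != b[p - 1])
    m_chr = sum(1 for p in CHR_POSITIONS if a[p - 1] != b[p - 1])
    return m_cde, m_chr


def classify_rank(
    score_m: float,
    score_h: float,
    mismatch_cde: int,
    mismatch_chr: int,
    require_both_positive: bool = False,
) -> str | None:
    """Rank a mouse/human site pair; returns 'A'..'D' or None.

    With a positive score (by default the maximum over the two species):
    0-1 total mismatches -> A, 2-3 -> B, exactly 4 -> C; more than 4 is still
    C when the mismatches affect only one element. With a non-positive score,
    0-1 mismatches -> D. Everything else is unranked.
    """
    if not 0 <= mismatch_cde <= len(CDE_POSITIONS):
        raise ValueError(f"mismatch_cde out of range: {mismatch_cde}")
    if not 0 <= mismatch_chr <= len(CHR_POSITIONS):
        raise ValueError(f"mismatch_chr out of range: {mismatch_chr}")
    if require_both_positive:
        positive = score_m > 0 and score_h > 0
    else:
        positive = max(score_m, score_h) > 0
    m = mismatch_cde + mismatch_chr
    if positive:
        if m <= 1:
            return "A"
        if m in (2, 3):
            return "B"
        if m == 4 or (m > 4 and (mismatch_cde == 0 or mismatch_chr == 0)):
            return "C"
        return None
    if m <= 1:
        return "D"
    return None


@dataclass(frozen=True)
class ConservedDbsPair:
    """A ranked orthologous pair of candidate sites (one may be absent)."""

    gene_id_m: str
    gene_id_h: str | None
    hit_m: DbsHit | None
    hit_h: DbsHit | None
    mismatch_cde: int | None
    mismatch_chr: int | None
    best_score: float
    rank: str | None

    @property
    def rank_order(self) -> int:
        return _RANK_ORDER[self.rank]


def _pair(gene_m: str, gene_h: str, hm: DbsHit, hh: DbsHit,
          require_both_positive: bool) -> ConservedDbsPair:
    m_cde, m_chr = count_mismatches(hm.sequence, hh.sequence)
    rank = classify_rank(hm.score, hh.score, m_cde, m_chr,
                         require_both_positive=require_both_positive)
    return ConservedDbsPair(
        gene_id_m=gene_m,
        gene_id_h=gene_h,
        hit_m=hm,
        hit_h=hh,
        mismatch_cde=m_cde,
        mismatch_chr=m_chr,
        best_score=max(hm.score, hh.score),
        rank=rank,
    )


DEFAULT_OFFSET_SHIFT = 20


def pair_hits(
    hits_m: dict[str, list[DbsHit]],
    hits_h: dict[str, list[DbsHit]],
    ortholog_map: dict[str, str],
    require_both_positive: bool = False,
    max_offset_shift: int | None = DEFAULT_OFFSET_SHIFT,
) -> list[ConservedDbsPair]:
    """Rank cross-products of hits within each orthologous promoter pair.

    Orthologous sites occupy approximately conserved promoter positions, so
    by default only pairs whose TSS-relative offsets agree within
    ``max_offset_shift`` bp compete; when no co-located pair exists the rule
    falls back to all cross-products (pass ``None`` to disable entirely).
    Per mouse gene the pair with the best rank (A < B < C < D < none) is
    retained, ties broken by highest best score, then by smallest offsets for
    determinism. Genes with hits in only one species, or without an ortholog,
    yield an unranked single-species record.
    """
    results: list[ConservedDbsPair] = []
    for gene_m in sorted(set(hits_m) | {g for g in ortholog_map if g in hits_m}):
        mouse_hits = hits_m.get(gene_m, [])
        if not mouse_hits:
            continue
        gene_h = ortholog_map.get(gene_m)
        human_hits = hits_h.get(gene_h, []) if gene_h is not None else []
        if gene_h is None:
            logger.warning("gene %s has no ortholog: retained unranked", gene_m)
        if not human_hits:
            best_m = max(mouse_hits, key=lambda h: (h.score, -h.offset))
            results.append(
                ConservedDbsPair(gene_m, gene_h, best_m, None, None, None, best_m.score, None)
            )
            continue
        pairs = [(hm, hh) for hm in mouse_hits for hh in human_hits]
        if max_offset_shift is not None:
            colocated = [
                (hm, hh) for hm, hh in pairs
                if abs(hm.offset - hh.offset) <= max_offset_shift
            ]
            if colocated:
                pairs = colocated
        candidates = [
            _pair(gene_m, gene_h, hm, hh, require_both_positive) for hm, hh in pairs
        ]
        candidates.sort(
            key=lambda p: (p.rank_order, -p.best_score, p.hit_m.offset, p.hit_h.offset)
        )
        results.append(candidates[0])
    # human-only hits: report unranked so nothing silently disappears
    human_to_mouse = {h: m for m, h in ortholog_map.items()}
    covered_h = {p.gene_id_h for p in results if p.gene_id_h is not None}
    for gene_h in sorted(set(hits_h) - covered_h):
        human_hits = hits_h.get(gene_h, [])
        if not human_hits:
            continue
        gene_m = human_to_mouse.get(gene_h)
        if gene_m is not None and hits_m.get(gene_m):
            continue  # already handled above
        best_h = max(human_hits, key=lambda h: (h.score, -h.offset))
        results.append(
            ConservedDbsPair(gene_m or gene_h, gene_h, None, best_h, None, None,
                             best_h.score, None)
        )
    return results
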