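"""Gapped bipartite position frequency matrices and exact-p-value scanning.

The DREAM-binding site (DBS) model is a 16-bp bipartite element: a GC-rich
CDE (E2F) half at positions 1-6, a 4-bp spacer at positions 7-10 that carries
no information, and an AT-rich CHR (CLE) half at positions 11-16. A matrix is
built from a set of validated 16-mer sites; spacer bases are excluded, so the
count matrix has 12 informative columns. Scoring uses additive log-odds
weights against a background base composition, and p-values are exact tail
probabilities of the score of an i.i.d. background word, computed by
dynamic-programming convolution over integer-discretized weights.

Scanning is restricted to the transcript strand: promoter sequences are
stored 5'->3' in gene orientation and a site on the opposite strand is, by
design, never reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np

from .io_formats import PromoterRecord

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DEFAULT_SPACER_START = 7  # 1-based position of the first spacer column
DEFAULT_SPACER_LEN = 4
MOTIF_LENGTH = 16
DEFAULT_SCALE = 10_000  # integer discretization: one unit = 1e-4 log-odds


class PfmError(ValueError):
    pass


@dataclass(frozen=True)
class GappedPFM:
    """A gapped count matrix over the informative (non-spacer) columns.

    ``counts`` has shape (4, n_informative) in base order A, C, G, T; the
    spacer occupies 1-based positions ``spacer_start .. spacer_start +
    spacer_len - 1`` of the full motif and contributes exactly zero to every
    score.
    """

    counts: np.ndarray
    spacer_start: int = DEFAULT_SPACER_START
    spacer_len: int = DEFAULT_SPACER_LEN
    alpha: float = 1.0
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    name: str = "custom"

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise PfmError("counts must have shape (4, n_informative)")
        if np.any(counts < 0):
            raise PfmError("counts must be non-negative")
        colsums = counts.sum(axis=0)
        if not np.allclose(colsums, colsums[0]):
            raise PfmError("every informative column must have the same total count")
        bg = np.asarray(self.background, dtype=float)
        if np.any(bg <= 0) or not np.isclose(bg.sum(), 1.0):
            raise PfmError("background must be strictly positive and sum to 1")
        if self.alpha < 0:
            raise PfmError("pseudocount must be non-negative")
        if self.spacer_start < 2 or self.spacer_len < 0:
            raise PfmError("spacer must sit strictly inside the motif")

    # -- geometry ----------------------------------------------------------

    @property
    def n_informative(self) -> int:
        return self.counts.shape[1]

    @property
    def length(self) -> int:
        return self.n_informative + self.spacer_len

    @property
    def informative_positions(self) -> tuple[int, ...]:
        """1-based motif positions carrying weight, in column order."""
        before = list(range(1, self.spacer_start))
        after = list(range(self.spacer_start + self.spacer_len, self.length + 1))
        return tuple(before + after)

    @property
    def spacer_positions(self) -> tuple[int, ...]:
        return tuple(range(self.spacer_start, self.spacer_start + self.spacer_len))

    @property
    def site_count(self) -> float:
        return float(self.counts.sum(axis=0)[0])

    # -- scoring -----------------------------------------------------------

    @cached_property
    def weights(self) -> np.ndarray:
        """Log-odds weights, shape (4, n_informative).

        w[b, j] = ln( (count[b, j] + alpha * bg[b]) / ((site_count + alpha) * bg[b]) )

        The pseudocount ``alpha`` is distributed over bases proportionally to
        the background, so a column of the consensus-only matrix keeps a
        finite penalty for unseen bases.
        """
        bg = np.asarray(self.background, dtype=float)[:, None]
        num = self.counts + self.alpha * bg
        den = (self.site_count + self.alpha) * bg
        w = np.log(num / den)
        w.setflags(write=False)
        return w

    @cached_property
    def consensus(self) -> str:
        cons = ["N"] * self.length
        inf = self.informative_positions
        best = np.argmax(self.counts, axis=0)
        for j, pos in enumerate(inf):
            cons[pos - 1] = BASES[best[j]]
        return "".join(cons)

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.weights.min(axis=0).sum())


def build_pfm(
    sites: Sequence[str],
    spacer_start: int = DEFAULT_SPACER_START,
    spacer_len: int = DEFAULT_SPACER_LEN,
    alpha: float = 1.0,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    name: str = "custom",
) -> GappedPFM:
    """Tally a gapped PFM from aligned 16-mer sites; spacer bases are ignored.

    Sites must all have the motif length; informative positions must be
    A/C/G/T while spacer positions may be any base or N.
    """
    if len(sites) < 2:
        raise PfmError("need at least two sites to build a matrix")
    length = MOTIF_LENGTH
    spacer = set(range(spacer_start, spacer_start + spacer_len))
    inf_positions = [p for p in range(1, length + 1) if p not in spacer]
    counts = np.zeros((4, len(inf_positions)), dtype=float)
    for si, site in enumerate(sites):
        site = site.upper()
        if len(site) != length:
            raise PfmError(f"site {si} has length {len(site)}, expected {length}")
        for j, pos in enumerate(inf_positions):
            base = site[pos - 1]
            if base not in BASE_INDEX:
                raise PfmError(
                    f"site {si}: non-ACGT base {base!r} at informative position {pos}"
                )
            counts[BASE_INDEX[base], j] += 1
        for pos in spacer:
            if site[pos - 1] not in "ACGTN":
                raise PfmError(f"site {si}: invalid base {site[pos - 1]!r} at spacer position {pos}")
    return GappedPFM(
        counts=counts,
        spacer_start=spacer_start,
        spacer_len=spacer_len,
        alpha=alpha,
        background=tuple(float(b) for b in background),
        name=name,
    )


def score_word(pfm: GappedPFM, word: str) -> float:
    """Sum of log-odds weights over the informative positions of ``word``.

    Spacer bases never contribute. An ambiguous base at an informative
    position is scored with the worst-case (minimum-weight) base and logged.
    """
    word = word.upper()
    if len(word) != pfm.length:
        raise PfmError(f"word has length {len(word)}, expected {pfm.length}")
    total = 0.0
    w = pfm.weights
    for j, pos in enumerate(pfm.informative_positions):
        base = word[pos - 1]
        bi = BASE_INDEX.get(base)
        if bi is None:
            logger.warning("ambiguous base %r at position %d scored worst-case", base, pos)
            total += float(w[:, j].min())
        else:
            total += float(w[bi, j])
    return total


# ---------------------------------------------------------------------------
# Exact score -> p-value table
# ---------------------------------------------------------------------------


def _exact_distribution(int_weights: np.ndarray, background: np.ndarray):
    """Exact distribution of the integer score of an i.i.d. background word.

    Returns ``(lo, probs)`` where ``probs[i]`` is P(score == lo + i). With a
    uniform background every probability is an exact multiple of 4**-k, so
    the convolution is bit-for-bit identical to full enumeration.
    """
    lo, probs = 0, np.array([1.0])
    for col in range(int_weights.shape[1]):
        w = int_weights[:, col]
        new_lo = lo + int(w.min())
        new_hi = lo + len(probs) - 1 + int(w.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            start = lo + int(w[b]) - new_lo
            new[start : start + len(probs)] += background[b] * probs
        lo, probs = new_lo, new
    return lo, probs


class ScorePValueTable:
    """Monotone map from motif score to P(score >= s) under the background.

    Scores are discretized to integers on a fixed grid (``scale`` units per
    natural-log unit); both the table and the scanner quantize identically,
    so lookups are exact on the grid.
    """

    def __init__(self, pfm: GappedPFM, background: Sequence[float] | None = None,
                 scale: int = DEFAULT_SCALE):
        self.pfm = pfm
        self.scale = int(scale)
        bg = np.asarray(background if background is not None else pfm.background, dtype=float)
        if np.any(bg <= 0) or not np.isclose(bg.sum(), 1.0):
            raise PfmError("background must be strictly positive and sum to 1")
        self.background = bg
        self.int_weights = np.rint(pfm.weights * self.scale).astype(np.int64)
        lo, probs = _exact_distribution(self.int_weights, bg)
        self._lo = lo
        self._probs = probs
        # survival function over the integer grid: sf[i] = P(score >= lo+i)
        sf = np.cumsum(probs[::-1])[::-1]
        self._sf = np.minimum(sf, 1.0)

    # -- lookups -----------------------------------------------------------

    @property
    def support(self) -> tuple[int, int]:
        return self._lo, self._lo + len(self._probs) - 1

    def probabilities(self) -> tuple[int, np.ndarray]:
        return self._lo, self._probs.copy()

    def pvalue_int(self, s: int) -> float:
        lo, hi = self.support
        if s <= lo:
            return 1.0
        if s > hi:
            return 0.0
        return float(self._sf[s - lo])

    def quantize(self, score: float) -> int:
        return int(np.rint(score * self.scale))

    def pvalue(self, score: float) -> float:
        return self.pvalue_int(self.quantize(score))

    def threshold_int(self, p_max: float) -> int:
        """Smallest integer score s with P(score >= s) <= p_max."""
        idx = np.searchsorted(-self._sf, -p_max, side="left")
        lo, hi = self.support
        if idx >= len(self._sf):
            return hi + 1  # nothing passes
        return lo + int(idx)

    def threshold_score(self, p_max: float) -> float:
        return self.threshold_int(p_max) / self.scale

    def hit_probability(self, p_max: float) -> float:
        """Attained per-window hit probability at the p_max cutoff."""
        return self.pvalue_int(self.threshold_int(p_max))


def pvalue_table(
    pfm: GappedPFM,
    background: Sequence[float] | None = None,
    scale: int = DEFAULT_SCALE,
) -> ScorePValueTable:
    """Build the exact score->p-value table for ``pfm``."""
    return ScorePValueTable(pfm, background=background, scale=scale)


# ---------------------------------------------------------------------------
# Promoter scanning (transcript strand only)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DbsHit:
    """One candidate DREAM-binding site on the transcript strand.

    ``offset`` is the TSS-relative, gene-strand coordinate of the first base
    of the 16-mer (upstream negative, 0 = TSS base).
    """

    gene_id: str
    species: str
    offset: int
    sequence: str
    score: float
    p_value: float
    orientation: str = "transcript"

    @property
    def center_offset(self) -> float:
        return self.offset + (len(self.sequence) - 1) / 2.0


def _encode(seq: str) -> np.ndarray:
    """Map sequence to 0..3 codes; any non-ACGT base becomes code 4."""
    codes = np.full(len(seq), 4, dtype=np.int8)
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    for base, idx in BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def window_scores(table: ScorePValueTable, seq: str) -> np.ndarray:
    """Integer scores of every length-16 window of ``seq`` (worst-case for N)."""
    pfm = table.pfm
    codes = _encode(seq)
    if len(codes) < pfm.length:
        return np.zeros(0, dtype=np.int64)
    # extend weights with a worst-case row for ambiguous bases
    iw = table.int_weights
    ext = np.vstack([iw, iw.min(axis=0)])  # row 4 = worst case
    win = np.lib.stride_tricks.sliding_window_view(codes, pfm.length)
    cols = np.array([p - 1 for p in pfm.informative_positions])
    sub = win[:, cols]  # (n_windows, n_informative)
    return ext[sub, np.arange(len(cols))].sum(axis=1)


def scan_promoter(
    pfm: GappedPFM,
    promoter: PromoterRecord,
    p_max: float = 1e-3,
    table: ScorePValueTable | None = None,
) -> list[DbsHit]:
    """Scan a promoter on the transcript strand and report hits with p <= p_max.

    Offsets are reported TSS-relative in gene-strand coordinates; overlapping
    hits are all reported. A sequence shorter than the motif yields an empty
    result with a warning.
    """
    if table is None:
        table = pvalue_table(pfm)
    if len(promoter.seq) < pfm.length:
        logger.warning(
            "promoter %s (%s) shorter than the motif (%d < %d): no scan",
            promoter.gene_id, promoter.species, len(promoter.seq), pfm.length,
        )
        return []
    scores = window_scores(table, promoter.seq)
    thr = table.threshold_int(p_max)
    hits: list[DbsHit] = []
    for i in np.nonzero(scores >= thr)[0]:
        s = int(scores[i])
        hits.append(
            DbsHit(
                gene_id=promoter.gene_id,
                species=promoter.species,
                offset=int(i) - promoter.tss_offset,
                sequence=promoter.seq[i : i + pfm.length],
                score=s / table.scale,
                p_value=table.pvalue_int(s),
            )
        )
    return hits
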