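"""Mapping of candidate sites to ChIP-peak centers and TSSs, with enrichment
statistics.

Sites are binned by the signed offset of their center from an anchor (peak
center or TSS) in fixed-width windows (50 bp by default, floor convention).
The genome-wide frequency f of site-containing windows calibrates a fold
enrichment (k/n)/f, and the upper-tail probability of observing k or more
site-containing windows among n is computed entirely in log space — as a
binomial tail in the infinite-population limit, or as a hypergeometric tail
when a finite window population is supplied. The reported enrichment is, if
anything, an underestimate whenever the foreground sites were additionally
filtered for cross-species conservation while the genome-wide frequency was
not.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .pfm import GappedPFM, ScorePValueTable, pvalue_table, window_scores

logger = logging.getLogger(__name__)

DEFAULT_BIN = 50


class MappingError(ValueError):
    pass


@dataclass
class WindowHistogram:
    """Counts of site centers in fixed-width offset windows around an anchor."""

    bin_width: int
    anchor: str  # "peak_center" or "TSS"
    counts: dict[int, int] = field(default_factory=dict)
    n_unanchored: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def offset_histogram(
    offsets: Iterable[float | None],
    bin_width: int = DEFAULT_BIN,
    anchor: str = "peak_center",
) -> WindowHistogram:
    """Bin signed site-center offsets as floor(offset / bin_width).

    ``None`` offsets (site without an anchor) are counted separately with a
    warning rather than dropped.
    """
    if bin_width <= 0:
        raise MappingError("bin width must be positive")
    hist = WindowHistogram(bin_width=bin_width, anchor=anchor)
    for off in offsets:
        if off is None or (isinstance(off, float) and math.isnan(off)):
            hist.n_unanchored += 1
            continue
        b = math.floor(off / bin_width)
        hist.counts[b] = hist.counts.get(b, 0) + 1
    if hist.n_unanchored:
        logger.warning("%d sites had no anchor and were bucketed separately",
                       hist.n_unanchored)
    return hist


def genome_window_frequency(
    sequences: Iterable[tuple[str, str]] | Iterable[str],
    pfm: GappedPFM,
    bin_width: int = DEFAULT_BIN,
    p_max: float = 1e-3,
    table: ScorePValueTable | None = None,
) -> tuple[float, int, int]:
    """Fraction of genome windows containing at least one site center.

    ``sequences`` are (name, seq) pairs or bare sequences; only the given
    (forward) strand is scanned. Returns (f, n_windows, n_hit_windows).
    """
    if table is None:
        table = pvalue_table(pfm)
    thr = table.threshold_int(p_max)
    half = (pfm.length - 1) / 2.0
    n_windows = 0
    n_hit = 0
    seen_any = False
    for item in sequences:
        name, seq = item if isinstance(item, tuple) else ("seq", item)
        seen_any = True
        nbins = len(seq) // bin_width
        if nbins == 0:
            continue
        n_windows += nbins
        scores = window_scores(table, seq)
        starts = np.nonzero(scores >= thr)[0]
        if len(starts) == 0:
            continue
        centers = starts + half
        bins = np.unique((centers // bin_width).astype(int))
        n_hit += int((bins < nbins).sum())
    if not seen_any or n_windows == 0:
        raise MappingError("empty genome: no windows to scan")
    f = n_hit / n_windows
    if f == 0.0:
        logger.warning("no site-containing windows found: frequency is 0, "
                       "fold enrichment will be undefined")
    return f, n_windows, n_hit


def enrichment_fold(k: int, n: int, f: float) -> float:
    """Fold enrichment (k/n) / f of site-containing windows over background."""
    if n <= 0:
        raise MappingError("n must be positive")
    if f <= 0:
        raise MappingError("background frequency is 0: enrichment undefined")
    return (k / n) / f


def log_tail_test(
    n: int,
    k: int,
    f: float,
    population: int | None = None,
) -> float:
    """log10 of the upper-tail probability P(X >= k) of the window test.

    With ``population`` (total number of genome windows N_w) the test is
    hypergeometric with K_w = round(f * N_w) marked windows; without it the
    binomial(n, f) limit is used. Everything is computed in log space via
    log-gamma so astronomically small tails keep full precision.
    """
    if not 0 <= k <= n:
        raise MappingError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0 < f < 1:
        raise MappingError(f"need 0 < f < 1, got f={f}")
    if k == 0:
        return 0.0
    if population is None:
        js = np.arange(k, n + 1)
        log_terms = (
            gammaln(n + 1) - gammaln(js + 1) - gammaln(n - js + 1)
            + js * math.log(f) + (n - js) * math.log1p(-f)
        )
    else:
        N = int(population)
        K = int(round(f * N))
        if K < k:
            return float("-inf") if K == 0 else _hyper_tail(N, K, n, k)
        return _hyper_tail(N, K, n, k)
    return float(logsumexp(log_terms) / math.log(10))


def _hyper_tail(N: int, K: int, n: int, k: int) -> float:
    """log10 P(X >= k) for X ~ Hypergeometric(N, K, n), in log space."""
    hi = min(n, K)
    if k > hi:
        return float("-inf")
    js = np.arange(k, hi + 1)
    js = js[(n - js) <= (N - K)]
    if len(js) == 0:
        return float("-inf")

    def logC(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    log_terms = logC(K, js) + logC(N - K, n - js) - logC(N, n)
    return float(logsumexp(log_terms) / math.log(10))
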