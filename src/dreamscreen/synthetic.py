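"""Seeded synthetic fixture bundles with planted, machine-readable ground truth.

The generator emulates the study conditions of the screen end to end:
triplicate log2 expression with true targets repressed at least 1.5-fold,
p53 regulation scores negative for true targets, E2F4/LIN9 ChIP peaks
centered on the planted binding sites near the TSS in both species,
orthologous mouse/human promoter pairs carrying planted 16-bp gapped
DREAM-binding sites with controlled mismatch counts, blood/brain ontology
annotations linking the planted targets to branch terms, and validation
RNA-seq counts in which true repression targets do not respond while a
panel of known p53-transactivated controls does (13 of 15 at >=1.5-fold).

Every file is written deterministically: the same config and seed reproduce
a byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats as iof
from .io_formats import PromoterRecord, TermAnnotation
from .pfm import (
    BASES,
    BASE_INDEX,
    GappedPFM,
    ScorePValueTable,
    build_pfm,
    pvalue_table,
)
from .conservation import CDE_POSITIONS, CHR_POSITIONS, classify_rank

logger = logging.getLogger(__name__)


class SyntheticConfigError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# The default "validated site" collection and its matrix
# ---------------------------------------------------------------------------
#
# A fixed panel of 22 aligned 16-mer sites standing in for an experimentally
# validated DBS collection: CDE (GC-rich) consensus TCCCGC, 4-bp spacer,
# CHR (AT-rich) consensus TTTGAA. Ten of the twelve informative columns are
# strongly conserved; positions 5 and 13 carry controlled diversity
# (20/1/1/0 and 19/2/1/0 base counts). This column architecture gives the
# matrix the two properties the screen's scan needs: the p<=1e-3 threshold
# score is negative (so weakly conserved, negative-score sites remain
# detectable, which is what makes rank D non-empty) and the score lattice is
# dense enough that the attained hit rate sits close to the nominal p.
# Spacer bases vary freely across sites and are never counted.

CONSENSUS_CDE = "TCCCGC"
CONSENSUS_CHR = "TTTGAA"
_SPACERS = [
    "ACAT", "GGTC", "TACG", "CTTA", "AGCA", "TCGT", "CATG", "GTAC",
    "TTCA", "CGAT", "ATGC", "GACT", "TGCA", "CAGT", "ACTG", "TCAG",
    "GATC", "AGTC", "CTGA", "TAGC", "GCTA", "ATCG",
]


def _site(cde: str, spacer: str, chr_: str) -> str:
    return cde + spacer + chr_


DEFAULT_VALIDATED_SITES: tuple[str, ...] = tuple(
    _site(cde, sp, chr_)
    for (cde, chr_), sp in zip(
        [
            ("TCCCAC", CONSENSUS_CHR),  # position 5 G->A
            ("TCCCTC", CONSENSUS_CHR),  # position 5 G->T
            ("TCCCGC", "TTAGAA"),       # position 13 T->A
            ("TCCCGC", "TTAGAA"),       # position 13 T->A
            ("TCCCGC", "TTCGAA"),       # position 13 T->C
        ]
        + [("TCCCGC", CONSENSUS_CHR)] * 17,
        _SPACERS,
    )
)


def default_pfm(alpha: float = 1.0) -> GappedPFM:
    """The matrix tallied from the default validated-site panel."""
    return build_pfm(DEFAULT_VALIDATED_SITES, alpha=alpha, name="PFM22-synthetic")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

RANKS_DEFAULT = {"A": 1, "B": 2, "C": 4, "D": 0}

MOUSE, HUMAN = "mouse", "human"
FACTORS = ("E2F4", "LIN9")
N_TA_GENES = 15
N_TA_RESPONDING = 13
LOCUS_SPACING = 10_000
PEAK_HALF_WIDTH = 150


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic study.

    Defaults mirror the screen's conditions: triplicates, a 1.5-fold
    repression floor with per-gene spread above it, ChIP scores high enough
    that every true target clears the 979 total-score cutoff, a 4-bp spacer
    and 1-kb promoters with the TSS 800 bp in.
    """

    n_genes: int = 200
    frac_true_targets: float = 0.3
    repression_log2fc: float = math.log2(1.5)
    repression_log2fc_spread: float = 2.0
    noise_sd: float = 0.1
    n_replicates: int = 3
    promoter_len: int = 1000
    promoter_upstream: int = 800
    peak_score_range: tuple[float, float] = (600.0, 1000.0)
    divergence_per_rank: dict = field(default_factory=lambda: dict(RANKS_DEFAULT))
    spacer_len: int = 4
    frac_poor_candidates: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.frac_true_targets <= 1.0:
            raise SyntheticConfigError("frac_true_targets must lie in [0, 1]")
        if not 0.0 <= self.frac_poor_candidates <= 1.0:
            raise SyntheticConfigError("frac_poor_candidates must lie in [0, 1]")
        lo, hi = self.peak_score_range
        if not (0 <= lo <= hi <= 1000):
            raise SyntheticConfigError("peak_score_range must be within [0, 1000]")
        if self.n_replicates < 2:
            raise SyntheticConfigError("need at least two replicates per condition")
        motif_len = 12 + self.spacer_len
        if self.promoter_len < motif_len + 40:
            raise SyntheticConfigError(
                f"promoter_len {self.promoter_len} too short to host the {motif_len}-bp "
                "motif plus flanks"
            )
        if not 0 < self.promoter_upstream < self.promoter_len:
            raise SyntheticConfigError("promoter_upstream must split the promoter")
        if self.noise_sd < 0:
            raise SyntheticConfigError("noise_sd must be non-negative")

    @property
    def n_true_targets(self) -> int:
        return int(round(self.n_genes * self.frac_true_targets))

    @property
    def n_poor_candidates(self) -> int:
        return int(round(self.n_genes * self.frac_poor_candidates))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["peak_score_range"] = list(self.peak_score_range)
        return d


@dataclass(frozen=True)
class PlantedDbs:
    rank: str
    n_mismatches: int
    offset: int  # TSS-relative gene-strand offset of the site start
    site_m: str
    site_h: str


@dataclass
class FixtureBundle:
    """Paths of every emitted file plus the in-memory truth table."""

    root: Path
    config: SyntheticConfig
    truth: pd.DataFrame
    paths: dict[str, Path]

    def path(self, key: str) -> Path:
        return self.paths[key]


# ---------------------------------------------------------------------------
# DBS planting
# ---------------------------------------------------------------------------


def _informative_losses(pfm: GappedPFM) -> list[tuple[float, int, str]]:
    """Cheapest mismatch (loss, 1-based position, alt base) per conservation-
    relevant informative position, sorted cheapest first."""
    conserved = set(CDE_POSITIONS) | set(CHR_POSITIONS)
    w = pfm.weights
    out = []
    for j, pos in enumerate(pfm.informative_positions):
        if pos not in conserved:
            continue
        order = np.argsort(-w[:, j])
        cons_b = int(order[0])
        alt_b = int(order[1])
        loss = float(w[cons_b, j] - w[alt_b, j])
        out.append((loss, pos, BASES[alt_b]))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def _negative_variant(table: ScorePValueTable, p_max: float) -> str | None:
    """A 12-informative-base word with negative score still passing the scan.

    Dynamic programming over achievable integer score sums with
    backpointers; returns the informative-letter word whose score is the
    largest achievable value in [threshold, 0), or None when the matrix
    admits no such word (then rank D cannot be planted).
    """
    thr = table.threshold_int(p_max)
    if thr >= 0:
        return None
    iw = table.int_weights
    k = iw.shape[1]
    achievable: dict[int, tuple] = {0: ()}
    for col in range(k):
        nxt: dict[int, tuple] = {}
        for s, path in achievable.items():
            for b in range(4):
                s2 = s + int(iw[b, col])
                if s2 not in nxt:
                    nxt[s2] = path + (b,)
        achievable = nxt
    negatives = [s for s in achievable if thr <= s < 0]
    if not negatives:
        return None
    best = max(negatives)
    return "".join(BASES[b] for b in achievable[best])


def _expand_word(informative: str, pfm: GappedPFM, spacer: str) -> str:
    site = ["N"] * pfm.length
    for letter, pos in zip(informative, pfm.informative_positions):
        site[pos - 1] = letter
    for i, pos in enumerate(pfm.spacer_positions):
        site[pos - 1] = spacer[i]
    return "".join(site)


def _site_informative(site: str, pfm: GappedPFM) -> str:
    return "".join(site[p - 1] for p in pfm.informative_positions)


def _int_score(table: ScorePValueTable, site: str) -> int:
    iw = table.int_weights
    total = 0
    for j, pos in enumerate(table.pfm.informative_positions):
        total += int(iw[BASE_INDEX[site[pos - 1]], j])
    return total


def plant_dbs(
    promoter_m: str,
    promoter_h: str,
    tss_index_m: int,
    tss_index_h: int,
    pfm: GappedPFM,
    target_rank: str,
    n_mismatches: int | None = None,
    offset: int = -120,
    rng: np.random.Generator | None = None,
    table: ScorePValueTable | None = None,
    p_max: float = 1e-3,
) -> tuple[str, str, PlantedDbs | None]:
    """Plant an orthologous site pair of the requested conservation rank.

    The mouse promoter receives the matrix consensus (ranks A-C) or a
    score-degraded variant that still passes the scan (rank D); the human
    promoter receives the same site carrying exactly ``n_mismatches``
    substitutions confined to the conservation-relevant positions (2-6 and
    11-16), placed cheapest-loss-first so the orthologous site remains a
    scan hit. Both sites sit at the same TSS-relative ``offset``. Returns
    the modified promoters and the planted record, or ``(.., .., None)``
    when the requested rank cannot be realized with this matrix (reported
    and skipped; only rank D can be infeasible).
    """
    if target_rank not in "ABCD":
        raise SyntheticConfigError(f"unknown rank {target_rank!r}")
    if rng is None:
        rng = np.random.default_rng(0)
    if table is None:
        table = pvalue_table(pfm)
    if n_mismatches is None:
        n_mismatches = RANKS_DEFAULT[target_rank]
    thr = table.threshold_int(p_max)
    spacer_m = "".join(rng.choice(list(BASES), size=pfm.spacer_len))
    spacer_h = "".join(rng.choice(list(BASES), size=pfm.spacer_len))

    if target_rank == "D":
        informative = _negative_variant(table, p_max)
        if informative is None:
            logger.warning("rank D not plantable: no negative score passes p <= %g", p_max)
            return promoter_m, promoter_h, None
        site_m = _expand_word(informative, pfm, spacer_m)
    else:
        site_m = _expand_word(
            _site_informative(pfm.consensus, pfm), pfm, spacer_m
        )

    # mutate cheapest conservation-relevant positions first
    losses = _informative_losses(pfm)
    site_h = list(site_m)
    applied = 0
    for loss, pos, alt in losses:
        if applied >= n_mismatches:
            break
        if site_h[pos - 1] == alt:
            continue
        candidate = list(site_h)
        candidate[pos - 1] = alt
        cand_site = "".join(candidate)
        score_int = _int_score(table, cand_site)
        if score_int < thr:
            continue
        if target_rank == "D" and score_int >= 0:
            continue
        site_h = candidate
        applied += 1
    site_h = "".join(site_h)
    # spacer differs freely between species without affecting anything
    site_h = _expand_word(_site_informative(site_h, pfm), pfm, spacer_h)

    if applied < n_mismatches:
        logger.warning(
            "rank %s: only %d of %d requested mismatches plantable without "
            "losing the scan hit", target_rank, applied, n_mismatches,
        )
    # sanity: the planted pair must classify as the requested rank
    m_cde = sum(1 for p in CDE_POSITIONS if site_m[p - 1] != site_h[p - 1])
    m_chr = sum(1 for p in CHR_POSITIONS if site_m[p - 1] != site_h[p - 1])
    score_m = _int_score(table, site_m) / table.scale
    score_h = _int_score(table, site_h) / table.scale
    got = classify_rank(score_m, score_h, m_cde, m_chr)
    if got != target_rank:
        raise GenerationError(
            f"planted pair classifies as {got!r}, requested {target_rank!r}"
        )

    def embed(seq: str, tss_index: int, site: str) -> str:
        idx = tss_index + offset
        if idx < 0 or idx + len(site) > len(seq):
            raise SyntheticConfigError(
                f"promoter too short to host the motif at offset {offset}"
            )
        return seq[:idx] + site + seq[idx + len(site):]

    return (
        embed(promoter_m, tss_index_m, site_m),
        embed(promoter_h, tss_index_h, site_h),
        PlantedDbs(target_rank, applied, offset, site_m, site_h),
    )


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------


def simulate_expression(
    truth: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Probe-level log2 matrix, design and probe map for the truth table.

    Each gene carries 1-4 probes with baselines ~ Uniform(6, 12); condition-B
    samples of repressed genes are shifted down by the planted log2 fold and
    i.i.d. Normal(0, noise_sd) noise is added everywhere.
    """
    samples_a = [f"HSC{i + 1}" for i in range(config.n_replicates)]
    samples_b = [f"Diff{i + 1}" for i in range(config.n_replicates)]
    design = pd.DataFrame(
        {
            "sample": samples_a + samples_b,
            "condition": ["A"] * config.n_replicates + ["B"] * config.n_replicates,
            "replicate": list(range(1, config.n_replicates + 1)) * 2,
        }
    )
    probe_rows = []
    value_rows = []
    probe_ids = []
    for row in truth.itertuples(index=False):
        n_probes = int(rng.integers(1, 5))
        l2fc = float(row.planted_log2fc)
        for p in range(n_probes):
            probe_id = f"{row.gene_id}_p{p + 1}"
            probe_ids.append(probe_id)
            probe_rows.append((probe_id, row.gene_id))
            baseline = rng.uniform(6.0, 12.0)
            vals_a = baseline + rng.normal(0.0, config.noise_sd, size=config.n_replicates) \
                if config.noise_sd > 0 else np.full(config.n_replicates, baseline)
            vals_b = baseline - l2fc + (
                rng.normal(0.0, config.noise_sd, size=config.n_replicates)
                if config.noise_sd > 0 else 0.0
            )
            vals_b = np.asarray(vals_b) + np.zeros(config.n_replicates)
            value_rows.append(np.concatenate([vals_a, vals_b]))
    values = pd.DataFrame(value_rows, index=probe_ids, columns=samples_a + samples_b)
    values.index.name = "probe_id"
    probe_map = pd.DataFrame(probe_rows, columns=["probe_id", "gene_id"])
    return values, design, probe_map


# ---------------------------------------------------------------------------
# Bundle assembly
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.asarray(list(BASES))[rng.integers(0, 4, size=length)])


def _gene_ids(n: int) -> list[str]:
    return [f"Gene{i + 1:04d}" for i in range(n)]


def _build_truth(config: SyntheticConfig, rng: np.random.Generator,
                 rank_cycle: list[str]) -> pd.DataFrame:
    genes = _gene_ids(config.n_genes)
    n_true = config.n_true_targets
    n_poor = config.n_poor_candidates
    idx = rng.permutation(config.n_genes)
    true_idx = set(idx[:n_true].tolist())
    poor_idx = set(idx[n_true : n_true + n_poor].tolist())
    rows = []
    k_true = 0
    for i, gene in enumerate(genes):
        is_true = i in true_idx
        is_poor = i in poor_idx
        planted = is_true or is_poor
        if planted:
            l2fc = config.repression_log2fc + rng.uniform(0.0, config.repression_log2fc_spread)
        else:
            l2fc = 0.0
        if is_true:
            rank = rank_cycle[k_true % len(rank_cycle)]
            k_true += 1
        elif is_poor:
            rank = rank_cycle[int(rng.integers(0, len(rank_cycle)))]
        else:
            rank = ""
        u = rng.uniform()
        if planted:
            branch = "blood" if u < 0.4 else ("brain" if u < 0.8 else "both")
        else:
            branch = ""
        rows.append(
            {
                "gene_id": gene,
                "human_id": gene.upper(),
                "is_true_target": is_true,
                "is_poor_candidate": is_poor,
                "branch": branch,
                "planted_log2fc": l2fc,
                "planted_fold": 2.0 ** l2fc,
                "requested_rank": rank,
                "rnaseq_fold": 3.0 if is_poor else 1.0,
            }
        )
    return pd.DataFrame(rows)


def make_bundle(config: SyntheticConfig, out_dir: str | os.PathLike) -> FixtureBundle:
    """Generate and write a complete fixture bundle; returns paths and truth.

    Re-running with the same config and seed reproduces every file byte for
    byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    pfm = default_pfm()
    table = pvalue_table(pfm)
    if pfm.length != 12 + config.spacer_len:
        raise SyntheticConfigError(
            f"spacer_len {config.spacer_len} incompatible with the default matrix"
        )

    rank_cycle = sorted(config.divergence_per_rank)
    truth = _build_truth(config, rng, rank_cycle)

    # ---- promoters, TSS tables, planted sites and peaks -----------------
    upstream = config.promoter_upstream
    downstream = config.promoter_len - upstream
    lo_off = -min(250, upstream - 20)
    hi_off = min(150, downstream - pfm.length - 4)
    promoters: dict[str, list[PromoterRecord]] = {MOUSE: [], HUMAN: []}
    tss_rows: dict[str, list] = {MOUSE: [], HUMAN: []}
    peak_rows: dict[tuple[str, str], list] = {(f, sp): [] for f in FACTORS for sp in (MOUSE, HUMAN)}
    planted_records: list[PlantedDbs | None] = []
    peak_offsets: list[float] = []

    n_peak = {sp: 0 for sp in (MOUSE, HUMAN)}
    for i, row in enumerate(truth.itertuples(index=False)):
        seq_m = _random_seq(rng, config.promoter_len)
        seq_h = _random_seq(rng, config.promoter_len)
        strand = {MOUSE: "+" if rng.uniform() < 0.5 else "-",
                  HUMAN: "+" if rng.uniform() < 0.5 else "-"}
        tss_genomic = {sp: i * LOCUS_SPACING + LOCUS_SPACING // 2 for sp in (MOUSE, HUMAN)}
        planted: PlantedDbs | None = None
        site_offset = None
        if row.requested_rank:
            offset = int(rng.integers(lo_off, hi_off + 1))
            seq_m, seq_h, planted = plant_dbs(
                seq_m, seq_h, upstream, upstream, pfm, row.requested_rank,
                n_mismatches=config.divergence_per_rank[row.requested_rank],
                offset=offset, rng=rng, table=table,
            )
            if planted is not None:
                site_offset = offset + pfm.length // 2  # site center, gene strand
        planted_records.append(planted)

        for sp, seq, gid in ((MOUSE, seq_m, row.gene_id), (HUMAN, seq_h, row.human_id)):
            promoters[sp].append(PromoterRecord(gid, sp, strand[sp], upstream, seq))
            tss_rows[sp].append((gid, "chr1", tss_genomic[sp], strand[sp], sp))

        # peaks: planted candidates get all four slots centered on the site
        if planted is not None:
            peak_offsets.append(float(site_offset))
            for sp, gid in ((MOUSE, row.gene_id), (HUMAN, row.human_id)):
                sign = 1 if strand[sp] == "+" else -1
                center = tss_genomic[sp] + sign * site_offset
                start, end = center - PEAK_HALF_WIDTH, center + PEAK_HALF_WIDTH + 1
                for f in FACTORS:
                    score = rng.uniform(*config.peak_score_range)
                    n_peak[sp] += 1
                    peak_rows[(f, sp)].append(
                        ("chr1", start, end, f"peak{n_peak[sp]:05d}", round(score, 1), strand[sp])
                    )
        else:
            peak_offsets.append(float("nan"))
            # decoys: sparse low-score peaks anywhere in the locus
            for sp, gid in ((MOUSE, row.gene_id), (HUMAN, row.human_id)):
                for f in FACTORS:
                    if rng.uniform() < 0.4:
                        center = tss_genomic[sp] + int(rng.integers(-4000, 4001))
                        score = rng.uniform(0.0, 300.0)
                        n_peak[sp] += 1
                        peak_rows[(f, sp)].append(
                            ("chr1", center - PEAK_HALF_WIDTH, center + PEAK_HALF_WIDTH + 1,
                             f"peak{n_peak[sp]:05d}", round(score, 1), strand[sp])
                        )

    truth["planted_rank"] = [p.rank if p else "" for p in planted_records]
    truth["dbs_offset"] = [p.offset if p else np.nan for p in planted_records]
    truth["dbs_site_mouse"] = [p.site_m if p else "" for p in planted_records]
    truth["dbs_site_human"] = [p.site_h if p else "" for p in planted_records]
    truth["dbs_mismatches"] = [p.n_mismatches if p else np.nan for p in planted_records]
    truth["peak_center_offset"] = peak_offsets

    # ---- expression ------------------------------------------------------
    values, design, probe_map = simulate_expression(truth, config, rng)

    # ---- regulation scores ----------------------------------------------
    reg_rows = []
    for row in truth.itertuples(index=False):
        planted = bool(row.is_true_target or row.is_poor_candidate)
        if planted:
            sm = -round(rng.uniform(0.1, 1.0), 3)
            sh = -round(rng.uniform(0.1, 1.0), 3) if rng.uniform() < 0.7 else round(
                rng.uniform(0.0, 0.5), 3)
        else:
            sm = round(rng.uniform(-1.0, 1.0), 3)
            sh = round(rng.uniform(-1.0, 1.0), 3)
        reg_rows.append((row.gene_id, sm, sh))
    scores = pd.DataFrame(reg_rows, columns=["gene_id", "score_mouse", "score_human"])

    # ---- annotations ----------------------------------------------------
    branch_terms = {
        "blood": [f"BLOOD_T{i + 1}" for i in range(3)],
        "brain": [f"BRAIN_T{i + 1}" for i in range(3)],
    }
    term_desc = {t: f"{b}-related process {t[-1]}" for b, ts in branch_terms.items() for t in ts}
    misc_terms = [f"MISC_T{i + 1}" for i in range(5)]
    term_desc.update({t: f"unrelated process {t[-1]}" for t in misc_terms})
    term_genes: dict[str, list[str]] = {t: [] for t in list(term_desc)}
    terms_per_gene = []
    for row in truth.itertuples(index=False):
        assigned: list[str] = []
        branches = []
        if row.branch == "both":
            branches = ["blood", "brain"]
        elif row.branch:
            branches = [row.branch]
        for b in branches:
            k = 1 + int(rng.uniform() < 0.5)
            assigned.extend(rng.choice(branch_terms[b], size=k, replace=False).tolist())
        if not branches:
            k = 1 + int(rng.uniform() < 0.5)
            assigned.extend(rng.choice(misc_terms, size=k, replace=False).tolist())
            if rng.uniform() < 0.1:  # decoys sprinkle into branch terms
                b = "blood" if rng.uniform() < 0.5 else "brain"
                assigned.append(str(rng.choice(branch_terms[b])))
        assigned = sorted(set(assigned))
        for t in assigned:
            term_genes[t].append(row.gene_id)
        terms_per_gene.append(";".join(assigned))
    truth["terms"] = terms_per_gene
    annotations = {
        t: TermAnnotation(t, term_desc[t], tuple(term_genes[t]))
        for t in term_genes
        if term_genes[t]
    }
    # curated disease lists in human symbol convention (case-insensitive match)
    curated = {}
    for b in ("blood", "brain"):
        members = sorted(
            {g for t in branch_terms[b] for g in term_genes.get(t, [])}
        )
        curated[b] = [g.upper() for g in members]

    # ---- RNA-seq ---------------------------------------------------------
    ta_genes = [f"TAgene{i + 1:02d}" for i in range(N_TA_GENES)]
    rnaseq = {}
    n_per_group = 3
    for ds in (1, 2):
        sample_names = [f"ds{ds}_act{i + 1}" for i in range(n_per_group)] + [
            f"ds{ds}_ctl{i + 1}" for i in range(n_per_group)
        ]
        design_ds = pd.DataFrame(
            {
                "sample": sample_names,
                "group": ["p53_active"] * n_per_group + ["control"] * n_per_group,
            }
        )
        gene_list = truth["gene_id"].tolist() + ta_genes
        lam = rng.uniform(50.0, 500.0, size=len(gene_list))
        folds = np.ones(len(gene_list))
        folds[: config.n_genes] = truth["rnaseq_fold"].to_numpy()
        for j in range(N_TA_GENES):
            gi = config.n_genes + j
            folds[gi] = rng.uniform(1.6, 4.0) if j < N_TA_RESPONDING else 1.0
        libfac = (
            rng.uniform(0.7, 1.3, size=2 * n_per_group)
            if config.noise_sd > 0
            else np.ones(2 * n_per_group)
        )
        mat = np.zeros((len(gene_list), 2 * n_per_group))
        for s in range(2 * n_per_group):
            mean = lam * (folds if s < n_per_group else 1.0) * libfac[s]
            mat[:, s] = rng.poisson(mean) if config.noise_sd > 0 else np.round(mean)
        counts = pd.DataFrame(mat.astype(np.int64), index=gene_list, columns=sample_names)
        counts.index.name = "gene_id"
        rnaseq[ds] = (counts, design_ds)

    # ---- write everything -----------------------------------------------
    paths: dict[str, Path] = {}

    def p(key: str, name: str) -> Path:
        paths[key] = out / name
        return paths[key]

    for sp in (MOUSE, HUMAN):
        iof.write_promoter_fasta(promoters[sp], p(f"promoters_{sp}", f"promoters_{sp}.fa"))
        tss_df = pd.DataFrame(tss_rows[sp], columns=["gene_id", "chrom", "tss", "strand", "species"])
        iof.write_table(tss_df, p(f"tss_{sp}", f"tss_{sp}.tsv"))
        for f in FACTORS:
            bed = pd.DataFrame(
                peak_rows[(f, sp)], columns=["chrom", "start", "end", "name", "score", "strand"]
            )
            iof.write_bed(bed, p(f"peaks_{f.lower()}_{sp}", f"peaks_{f.lower()}_{sp}.bed"))
    orth = truth[["gene_id", "human_id"]].rename(columns={"gene_id": "mouse_id"})
    iof.write_table(orth, p("orthologs", "orthologs.tsv"))
    iof.write_expression_tsv(values, p("expression", "expression.tsv"))
    iof.write_table(design, p("expression_design", "expression_design.tsv"))
    iof.write_table(probe_map, p("probe_map", "probe_map.tsv"))
    iof.write_table(scores, p("regulation_scores", "regulation_scores.tsv"))
    iof.write_gmt(annotations, p("annotations", "annotations.gmt"))
    for b in ("blood", "brain"):
        iof.write_gene_list(branch_terms[b], p(f"{b}_terms", f"{b}_terms.txt"))
        iof.write_gene_list(curated[b], p(f"{b}_curated", f"{b}_curated.txt"))
    for ds in (1, 2):
        counts, design_ds = rnaseq[ds]
        iof.write_table(counts.reset_index(), p(f"rnaseq_counts_{ds}", f"rnaseq_counts_{ds}.tsv"))
        iof.write_table(design_ds, p(f"rnaseq_design_{ds}", f"rnaseq_design_{ds}.tsv"))
    iof.write_gene_list(ta_genes, p("ta_genes", "ta_genes.txt"))
    iof.write_pfm(pfm, p("pfm", "pfm.txt"))
    iof.write_table(truth, p("truth", "truth.tsv"))
    with open(p("config", "config.yaml"), "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    return FixtureBundle(root=out, config=config, truth=truth, paths=paths)
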