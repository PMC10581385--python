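"""Readers and writers for the external file formats used across the package.

All genomic intervals are 0-based, half-open. TSS-relative offsets are signed
with 0 at the TSS base and upstream negative on the gene strand. Every writer
emits a deterministic comment header (tool version plus an optional config
hash) so that repeated runs of the generator produce byte-identical bundles.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__

_COMMENT = "#"

VALID_STRANDS = {"+", "-"}


class FormatError(ValueError):
    """Raised for malformed input files; the message carries the line number."""


def _header(config_hash: str | None = None) -> str:
    tag = f"{_COMMENT} dreamscreen {__version__}"
    if config_hash:
        tag += f" config_hash={config_hash}"
    return tag + "\n"


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED6 file of scored peaks into a DataFrame.

    Scores must lie in [0, 1000] (ChIP-Atlas convention); intervals must be
    non-empty with non-negative coordinates.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(_COMMENT) or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(
                    f"{path}:{lineno}: expected 6 tab-separated BED fields, got {len(fields)}"
                )
            chrom, start_s, end_s, name, score_s, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
                score = float(score_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinate or score") from exc
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start coordinate {start}")
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: empty or inverted interval [{start}, {end})"
                )
            if not 0.0 <= score <= 1000.0:
                raise FormatError(f"{path}:{lineno}: score {score} outside [0, 1000]")
            if strand not in VALID_STRANDS | {"."}:
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            rows.append((chrom, start, end, name, score, strand))
    df = pd.DataFrame(rows, columns=BED_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bed(df: pd.DataFrame, path: str | os.PathLike, config_hash: str | None = None) -> None:
    missing = [c for c in BED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"BED frame missing columns: {missing}")
    if ((df["score"] < 0) | (df["score"] > 1000)).any():
        raise FormatError("BED scores must lie in [0, 1000]")
    if (df["start"] >= df["end"]).any():
        raise FormatError("BED intervals must be non-empty")
    with open(path, "w") as fh:
        fh.write(_header(config_hash))
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t{_fmt_num(row.score)}\t{row.strand}\n"
            )


def _fmt_num(x: float) -> str:
    """Format a score compactly and reproducibly (integers without decimals)."""
    if float(x) == int(x):
        return str(int(x))
    return f"{x:.6g}"


# ---------------------------------------------------------------------------
# Promoter FASTA with structured headers  >geneID|species|strand|tss_offset
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PromoterRecord:
    """One promoter sequence, written 5'->3' on the transcript strand.

    ``tss_offset`` is the index of the TSS base within ``seq``; position i of
    the sequence therefore sits at gene-strand offset ``i - tss_offset``.
    """

    gene_id: str
    species: str
    strand: str
    tss_offset: int
    seq: str

    def offset_of_index(self, i: int) -> int:
        return i - self.tss_offset


def read_promoter_fasta(path: str | os.PathLike) -> list[PromoterRecord]:
    records: list[PromoterRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 4:
            raise FormatError(
                f"{path}: promoter header must be geneID|species|strand|tss_offset, "
                f"got {rec.id!r}"
            )
        gene_id, species, strand, tss_s = parts
        if strand not in VALID_STRANDS:
            raise FormatError(f"{path}: bad strand {strand!r} for {gene_id}")
        try:
            tss_offset = int(tss_s)
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer tss_offset for {gene_id}") from exc
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence for {gene_id}")
        records.append(PromoterRecord(gene_id, species, strand, tss_offset, seq))
    return records


def write_promoter_fasta(records: Iterable[PromoterRecord], path: str | os.PathLike) -> None:
    seq_records = [
        SeqRecord(
            Seq(rec.seq),
            id=f"{rec.gene_id}|{rec.species}|{rec.strand}|{rec.tss_offset}",
            description="",
        )
        for rec in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Schema-checked TSV tables
# ---------------------------------------------------------------------------


def read_table(
    path: str | os.PathLike,
    schema: Mapping[str, type] | None = None,
    index_col: str | None = None,
) -> pd.DataFrame:
    """Read a TSV table, checking that every schema column is present.

    ``schema`` maps column name -> dtype (``str``, ``int``, ``float``).
    Extra columns are preserved untouched.
    """
    df = pd.read_csv(path, sep="\t", comment=_COMMENT, dtype=str)
    if schema:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required columns {missing}")
        for col, typ in schema.items():
            if typ is int:
                try:
                    df[col] = df[col].astype(np.int64)
                except (TypeError, ValueError) as exc:
                    raise FormatError(f"{path}: column {col!r} is not integer") from exc
            elif typ is float:
                try:
                    df[col] = df[col].astype(float)
                except (TypeError, ValueError) as exc:
                    raise FormatError(f"{path}: column {col!r} is not numeric") from exc
    if index_col is not None:
        if df[index_col].duplicated().any():
            dupes = df[index_col][df[index_col].duplicated()].unique()[:5]
            raise FormatError(f"{path}: duplicate {index_col} values, e.g. {list(dupes)}")
        df = df.set_index(index_col)
    return df


def write_table(
    df: pd.DataFrame,
    path: str | os.PathLike,
    config_hash: str | None = None,
    float_format: str = "%.6g",
    index: bool = False,
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config_hash))
        df.to_csv(fh, sep="\t", float_format=float_format, index=index, lineterminator="\n")


# ---------------------------------------------------------------------------
# Expression matrix TSV (probe x sample, log2 values)
# ---------------------------------------------------------------------------


def read_expression_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment=_COMMENT, index_col=0)
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate probe ids")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise FormatError(f"{path}: missing expression values in columns {bad}")
    return df.astype(float)


def write_expression_tsv(
    df: pd.DataFrame, path: str | os.PathLike, config_hash: str | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config_hash))
        df.to_csv(fh, sep="\t", float_format="%.6f", index_label="probe_id", lineterminator="\n")


# ---------------------------------------------------------------------------
# GMT-like annotations:  term_id <TAB> description <TAB> gene1,gene2,...
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TermAnnotation:
    term_id: str
    description: str
    genes: tuple[str, ...]


def read_gmt(path: str | os.PathLike) -> dict[str, TermAnnotation]:
    terms: dict[str, TermAnnotation] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(_COMMENT):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected term, description, gene list (3 fields)"
                )
            term_id, description, genes_s = fields
            genes = tuple(g for g in genes_s.split(",") if g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: term {term_id!r} has an empty gene set")
            if term_id in terms:
                raise FormatError(f"{path}:{lineno}: duplicate term {term_id!r}")
            terms[term_id] = TermAnnotation(term_id, description, genes)
    return terms


def write_gmt(
    terms: Mapping[str, TermAnnotation] | Iterable[TermAnnotation],
    path: str | os.PathLike,
    config_hash: str | None = None,
) -> None:
    if isinstance(terms, Mapping):
        terms = terms.values()
    with open(path, "w") as fh:
        fh.write(_header(config_hash))
        for t in terms:
            fh.write(f"{t.term_id}\t{t.description}\t{','.join(t.genes)}\n")


# ---------------------------------------------------------------------------
# Plain gene lists (one symbol per line)
# ---------------------------------------------------------------------------


def read_gene_list(path: str | os.PathLike) -> list[str]:
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith(_COMMENT):
                genes.append(line)
    return genes


def write_gene_list(genes: Sequence[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# PFM dialect: 4 base rows x L columns of counts, plus a spacer mask line
# ---------------------------------------------------------------------------


def read_pfm(path: str | os.PathLike):
    """Read a gapped count matrix (JASPAR-like rows ``A | counts...`` plus a
    ``spacer: 7-10`` mask line) into a :class:`~dreamscreen.pfm.GappedPFM`."""
    from .pfm import GappedPFM, BASES

    rows: dict[str, list[float]] = {}
    spacer: tuple[int, int] | None = None
    name = "custom"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(_COMMENT):
                continue
            if line.startswith(">"):
                name = line[1:].strip() or name
                continue
            if line.lower().startswith("spacer:"):
                rng = line.split(":", 1)[1].strip()
                try:
                    lo_s, hi_s = rng.split("-")
                    spacer = (int(lo_s), int(hi_s))
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad spacer mask {rng!r}") from exc
                continue
            parts = line.replace("|", " ").split()
            base = parts[0].upper()
            if base not in "ACGT":
                raise FormatError(f"{path}:{lineno}: unknown base row {parts[0]!r}")
            try:
                rows[base] = [float(x) for x in parts[1:]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric count") from exc
    if set(rows) != set("ACGT"):
        raise FormatError(f"{path}: need exactly one row per base A/C/G/T, got {sorted(rows)}")
    if spacer is None:
        raise FormatError(f"{path}: missing 'spacer: lo-hi' mask line")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise FormatError(f"{path}: base rows have unequal lengths {sorted(lengths)}")
    (ncols,) = lengths
    spacer_start, spacer_end = spacer
    spacer_len = spacer_end - spacer_start + 1
    expected = 16
    if ncols != expected:
        raise FormatError(f"{path}: expected {expected} matrix columns, got {ncols}")
    full = np.array([rows[b] for b in BASES], dtype=float)
    keep = [i for i in range(ncols) if not (spacer_start - 1 <= i <= spacer_end - 1)]
    if np.any(full[:, [i for i in range(ncols) if i not in keep]] != 0):
        raise FormatError(f"{path}: spacer columns must carry zero counts")
    counts = full[:, keep]
    return GappedPFM(counts=counts, spacer_start=spacer_start, spacer_len=spacer_len, name=name)


def write_pfm(pfm, path: str | os.PathLike, config_hash: str | None = None) -> None:
    from .pfm import BASES

    full = np.zeros((4, pfm.length))
    inf = [p - 1 for p in pfm.informative_positions]
    full[:, inf] = pfm.counts
    with open(path, "w") as fh:
        fh.write(_header(config_hash))
        fh.write(f">{pfm.name}\n")
        for bi, base in enumerate(BASES):
            vals = " ".join(_fmt_num(v) for v in full[bi])
            fh.write(f"{base} | {vals}\n")
        fh.write(f"spacer: {pfm.spacer_start}-{pfm.spacer_start + pfm.spacer_len - 1}\n")
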