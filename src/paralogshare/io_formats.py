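"""Readers and writers for the pipeline's interchange formats.

The canonical interchange format is TSV.  A restricted GTF dialect
(``five_prime_utr`` / ``CDS`` / ``three_prime_utr`` features carrying
``gene_id`` and ``transcript_id`` attributes) is accepted for annotation.
Coverage arrives as bedGraph.  All internal coordinates are 0-based
half-open; GTF's 1-based inclusive coordinates are converted at the file
boundary and nowhere else.  Coverage vectors are stored in transcript
(5'->3') orientation, so minus-strand tracks are reversed on read.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("paralogshare")


class ParseError(ValueError):
    """Malformed input file (names the offending line where possible)."""


class ValidationError(ValueError):
    """Well-formed input that violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: UTR/CDS lengths plus the genomic 3'-UTR interval.

    ``utr3_start``/``utr3_end`` are 0-based half-open genomic coordinates;
    ``l_3utr`` must equal their difference.  CDS length includes start and
    stop codons and must be a positive multiple of 3.
    """

    gene_id: str
    transcript_id: str
    l_5utr: int
    l_cds: int
    l_3utr: int
    chrom: str = "chr1"
    utr3_start: int = 0
    utr3_end: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.l_cds <= 0 or self.l_cds % 3 != 0:
            raise ValidationError(
                f"{self.transcript_id}: CDS length {self.l_cds} must be a "
                "positive multiple of 3"
            )
        if self.l_5utr < 0:
            raise ValidationError(f"{self.transcript_id}: negative 5'-UTR length")
        if self.utr3_end <= self.utr3_start:
            raise ValidationError(
                f"{self.transcript_id}: empty or inverted 3'-UTR interval "
                f"[{self.utr3_start}, {self.utr3_end})"
            )
        if self.l_3utr != self.utr3_end - self.utr3_start:
            raise ValidationError(
                f"{self.transcript_id}: l_3utr={self.l_3utr} does not match "
                f"interval [{self.utr3_start}, {self.utr3_end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.transcript_id}: bad strand {self.strand!r}")

    @property
    def total_length(self) -> int:
        return self.l_5utr + self.l_cds + self.l_3utr


@dataclass
class CountMatrix:
    """Non-negative gene x sample counts tagged with the assay they came from."""

    genes: list[str]
    samples: list[str]
    counts: np.ndarray  # shape (n_genes, n_samples)
    assay: str  # "rna" | "ribo"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValidationError("count matrix shape does not match labels")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene ids")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids")
        if np.any(self.counts < 0):
            raise ValidationError("negative counts")
        if self.assay not in ("rna", "ribo"):
            raise ValidationError(f"unknown assay {self.assay!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.samples)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, assay: str) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), assay)


@dataclass
class CoverageTrack:
    """Per-base read depth along one 3'-UTR for one sample, 5'->3'."""

    gene_id: str
    sample_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1:
            raise ValidationError("depth must be one-dimensional")
        if np.any(self.depth < 0):
            raise ValidationError("negative depth")


@dataclass
class CohortTable:
    """Carriers with/without a cardiac event per gene (registry-style r x 2)."""

    table: pd.DataFrame  # columns: gene_id, with_event, without_event
    phenotype_label: str = "all"

    def __post_init__(self) -> None:
        required = {"gene_id", "with_event", "without_event"}
        if not required.issubset(self.table.columns):
            raise ValidationError(f"cohort table needs columns {sorted(required)}")
        if (self.table[["with_event", "without_event"]] < 0).any().any():
            raise ValidationError("negative cohort counts")
        if len(self.table) < 2:
            raise ValidationError("cohort table needs at least 2 genes for testing")

    def as_array(self) -> np.ndarray:
        return self.table[["with_event", "without_event"]].to_numpy(dtype=int)

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene_id"])


@dataclass(frozen=True)
class ConstraintRecord:
    """Observed and expected variant counts for one gene and variant class."""

    gene_id: str
    variant_class: str  # "missense" | "plof"
    observed: int
    expected: float

    def __post_init__(self) -> None:
        if self.observed < 0:
            raise ValidationError("observed count must be >= 0")
        if self.expected <= 0:
            raise ValidationError("expected count must be strictly positive")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_TSV_ANNOT_COLS = [
    "gene_id", "transcript_id", "l_5utr", "l_cds", "l_3utr",
    "chrom", "utr3_start", "utr3_end", "strand",
]


def read_annotation(path: str | Path, format: str = "tsv") -> list[TranscriptModel]:
    """Read transcript models from TSV (0-based half-open) or restricted GTF.

    The GTF dialect uses 1-based inclusive coordinates; they are converted
    to the internal 0-based half-open convention here.  Minus-strand models
    keep their genomic interval; downstream coverage readers reverse depth
    into transcript orientation using ``strand``.
    """
    path = Path(path)
    if format == "tsv":
        return _read_annotation_tsv(path)
    if format == "gtf":
        return _read_annotation_gtf(path)
    raise ValueError(f"unknown annotation format {format!r}")


def _read_annotation_tsv(path: Path) -> list[TranscriptModel]:
    models: list[TranscriptModel] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            logger.warning("empty annotation file %s", path)
            return []
        missing = set(_TSV_ANNOT_COLS) - set(reader.fieldnames)
        if missing:
            raise ParseError(f"{path}: missing annotation columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                models.append(TranscriptModel(
                    gene_id=row["gene_id"],
                    transcript_id=row["transcript_id"],
                    l_5utr=int(row["l_5utr"]),
                    l_cds=int(row["l_cds"]),
                    l_3utr=int(row["l_3utr"]),
                    chrom=row["chrom"],
                    utr3_start=int(row["utr3_start"]),
                    utr3_end=int(row["utr3_end"]),
                    strand=row["strand"],
                ))
            except (KeyError, TypeError) as exc:
                raise ParseError(f"{path} line {i}: missing field ({exc})") from exc
            except ValueError as exc:
                if isinstance(exc, ValidationError):
                    raise
                raise ParseError(f"{path} line {i}: {exc}") from exc
    if not models:
        logger.warning("annotation file %s contained no transcripts", path)
    return models


def _read_annotation_gtf(path: Path) -> list[TranscriptModel]:
    # restricted dialect: feature types five_prime_utr / CDS / three_prime_utr,
    # attributes gene_id and transcript_id
    per_tx: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path} line {lineno}: expected 9 GTF columns")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = parts
            if feature not in ("five_prime_utr", "CDS", "three_prime_utr"):
                continue
            attr = _parse_gtf_attributes(attrs, path, lineno)
            try:
                gene_id, tx_id = attr["gene_id"], attr["transcript_id"]
            except KeyError as exc:
                raise ParseError(
                    f"{path} line {lineno}: missing mandatory attribute {exc}"
                ) from exc
            # GTF is 1-based inclusive -> 0-based half-open
            start, end = int(start_s) - 1, int(end_s)
            rec = per_tx.setdefault(tx_id, {
                "gene_id": gene_id, "chrom": chrom, "strand": strand,
                "l_5utr": 0, "l_cds": 0, "utr3_intervals": [],
            })
            if feature == "five_prime_utr":
                rec["l_5utr"] += end - start
            elif feature == "CDS":
                rec["l_cds"] += end - start
            else:
                rec["utr3_intervals"].append((start, end))
    models = []
    for tx_id, rec in per_tx.items():
        ivs = rec["utr3_intervals"]
        if not ivs:
            raise ValidationError(f"{tx_id}: no 3'-UTR feature (l_3utr <= 0)")
        utr3_start = min(s for s, _ in ivs)
        utr3_end = max(e for _, e in ivs)
        l_3utr = sum(e - s for s, e in ivs)
        if l_3utr != utr3_end - utr3_start:
            raise ValidationError(f"{tx_id}: 3'-UTR features are not contiguous")
        models.append(TranscriptModel(
            gene_id=rec["gene_id"], transcript_id=tx_id,
            l_5utr=rec["l_5utr"], l_cds=rec["l_cds"], l_3utr=l_3utr,
            chrom=rec["chrom"], utr3_start=utr3_start, utr3_end=utr3_end,
            strand=rec["strand"],
        ))
    if not models:
        logger.warning("annotation file %s contained no transcripts", path)
    return models


def _parse_gtf_attributes(attrs: str, path: Path, lineno: int) -> dict[str, str]:
    out = {}
    for chunk in attrs.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            key, value = chunk.split(" ", 1)
        except ValueError:
            raise ParseError(f"{path} line {lineno}: bad attribute {chunk!r}")
        out[key] = value.strip().strip('"')
    return out


def write_annotation(models: Sequence[TranscriptModel], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_TSV_ANNOT_COLS)
        for m in models:
            writer.writerow([m.gene_id, m.transcript_id, m.l_5utr, m.l_cds,
                             m.l_3utr, m.chrom, m.utr3_start, m.utr3_end, m.strand])


def write_annotation_gtf(models: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write the restricted GTF dialect (1-based inclusive on disk).

    The 5'-UTR and CDS features are placed immediately upstream of the
    3'-UTR interval; only their lengths are meaningful to the readers.
    """
    def line(m, feature, start0, end0):
        attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
        return "\t".join([m.chrom, "paralogshare", feature, str(start0 + 1),
                          str(end0), ".", m.strand, ".", attrs]) + "\n"

    with open(path, "w") as fh:
        for m in models:
            cds_start = m.utr3_start - m.l_cds
            utr5_start = cds_start - m.l_5utr
            if m.l_5utr > 0:
                fh.write(line(m, "five_prime_utr", utr5_start, cds_start))
            fh.write(line(m, "CDS", cds_start, m.utr3_start))
            fh.write(line(m, "three_prime_utr", m.utr3_start, m.utr3_end))


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path, assay: str) -> CountMatrix:
    """Read a gene x sample TSV (first column gene id, header = sample ids)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene ids {dupes}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any():
            row = df.index[bad.isna()][0]
            raise ParseError(f"{path}: non-numeric cell at gene {row!r}, sample {col!r}")
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValidationError(f"{path}: negative count entries")
    return CountMatrix(list(df.index.astype(str)), list(df.columns.astype(str)),
                       values, assay)


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    # integer-valued matrices round-trip bit-exactly as integers
    if np.allclose(df.to_numpy() % 1, 0):
        df = df.astype(int)
    df.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# bedGraph coverage
# ---------------------------------------------------------------------------

def read_bedgraph_coverage(
    path: str | Path,
    models: Sequence[TranscriptModel],
    sample_id: str,
) -> list[CoverageTrack]:
    """Clip bedGraph depth to each model's 3'-UTR, in transcript orientation.

    bedGraph intervals are 0-based half-open.  Bases not covered by any
    interval get depth 0.  Intervals that overlap with conflicting values
    raise; a model whose chromosome never appears yields an all-zero track
    with a warning.
    """
    path = Path(path)
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"{path} line {lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if value < 0:
                raise ValidationError(f"{path} line {lineno}: negative depth")
            intervals.setdefault(chrom, []).append((start, end, value))

    tracks = []
    for m in models:
        depth = np.zeros(m.l_3utr, dtype=float)
        chrom_ivs = intervals.get(m.chrom)
        if chrom_ivs is None:
            logger.warning("no coverage for chrom %s (gene %s) in %s; track of zeros",
                           m.chrom, m.gene_id, path)
        else:
            assigned = np.zeros(m.l_3utr, dtype=bool)
            for start, end, value in chrom_ivs:
                lo = max(start, m.utr3_start) - m.utr3_start
                hi = min(end, m.utr3_end) - m.utr3_start
                if hi <= lo:
                    continue
                clash = assigned[lo:hi] & (depth[lo:hi] != value)
                if clash.any():
                    raise ValidationError(
                        f"{path}: overlapping conflicting intervals on {m.chrom} "
                        f"within 3'-UTR of {m.gene_id}"
                    )
                depth[lo:hi] = value
                assigned[lo:hi] = True
        if m.strand == "-":
            depth = depth[::-1].copy()
        tracks.append(CoverageTrack(m.gene_id, sample_id, depth))
    return tracks


def write_bedgraph_coverage(
    tracks: Iterable[CoverageTrack],
    models: Sequence[TranscriptModel],
    path: str | Path,
) -> None:
    """Run-length encode tracks back to bedGraph in genomic orientation."""
    by_gene = {m.gene_id: m for m in models}
    with open(path, "w") as fh:
        for t in tracks:
            m = by_gene[t.gene_id]
            depth = t.depth[::-1] if m.strand == "-" else t.depth
            boundaries = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [len(depth)]])
            for s, e in zip(starts, ends):
                v = depth[s]
                if v != 0:
                    fh.write(f"{m.chrom}\t{m.utr3_start + s}\t{m.utr3_start + e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# cohort / constraint tables, config
# ---------------------------------------------------------------------------

def read_cohort_table(path: str | Path, phenotype_label: str = "all") -> CohortTable:
    df = pd.read_csv(path, sep="\t")
    return CohortTable(df, phenotype_label=phenotype_label)


def write_cohort_table(table: CohortTable, path: str | Path) -> None:
    table.table.to_csv(path, sep="\t", index=False)


def read_constraint_table(path: str | Path) -> list[ConstraintRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        ConstraintRecord(str(r.gene_id), str(r.variant_class),
                         int(r.observed), float(r.expected))
        for r in df.itertuples()
    ]


def write_constraint_table(records: Sequence[ConstraintRecord], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, sep="\t", index=False)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
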