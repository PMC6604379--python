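"""Genomic text formats and the core domain types of the pipeline.

All internal coordinates are 0-based half-open; conversion to and from
1-based closed coordinates happens only at the GFF3 parse/serialize
boundary.  Mapped reads are deduplicated on (chrom, start, strand), the
single-end duplicate-removal convention; read length is retained so that
fractional-overlap counting downstream conserves mass.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

MARKS = ("H3K4me1", "H3K4me2", "H3K4me3", "H3K36me3")
INPUT_LABEL = "input"
WT = "wild_type"
MUT = "mutant"


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line number."""


class ValidationError(ValueError):
    """An input violates a domain invariant (coordinates, duplicate IDs...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene as its TSS-TTS genomic span with strand.

    The TSS is ``start`` on the + strand and ``end`` on the - strand; all
    per-gene statistics in the pipeline are computed on this span.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    is_te: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass
class ReadSet:
    """Deduplicated mapped-read intervals for one (sample, genotype) pair.

    ``reads`` is a DataFrame with columns chrom/start/end/strand, sorted by
    (chrom, start); ``total_reads`` is the post-deduplication count and is
    the denominator of all depth normalization.
    """

    sample_label: str
    genotype: str
    reads: pd.DataFrame
    total_reads: int = 0

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, sample_label: str, genotype: str) -> "ReadSet":
        df = deduplicate_reads(df)
        return cls(sample_label=sample_label, genotype=genotype, reads=df,
                   total_reads=len(df))

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) int arrays for one chromosome, sorted by start."""
        sub = self.reads[self.reads["chrom"] == chrom]
        return (sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64))


def deduplicate_reads(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse reads sharing (chrom, start, strand) to a single read.

    Idempotent by construction; the surviving row is the first occurrence.
    """
    df = df.drop_duplicates(subset=["chrom", "start", "strand"], keep="first")
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return df


@dataclass
class PipelineConfig:
    """All thresholds and sizes of the pipeline in one place.

    Defaults are the study's published parameters: 200-bp windows with a
    200-bp gap for the broad marks (H3K4me1/me2) and a 600-bp gap for the
    punctate ones (H3K4me3/H3K36me3); island discovery at FDR < 1e-2,
    significant islands at FDR < 1e-3 with >= 2-fold IP/input enrichment;
    differential islands at FDR < 1e-4 with >= 1.5-fold change; read depth
    normalized to 10 million; 300 gene-body bins flanked by 50 bins over
    1 kb on each side; FPKM class bounds (1, 2, 10); DE at > 1.5-fold and
    adjusted p < 0.05; K-means with k = 5.
    """

    window_W: int = 200
    gap_G: dict = field(default_factory=lambda: {
        "H3K4me1": 200, "H3K4me2": 200, "H3K4me3": 600, "H3K36me3": 600})
    island_fdr_call: float = 1e-2
    island_fdr_sig: float = 1e-3
    island_fold_sig: float = 2.0
    diff_fdr: float = 1e-4
    diff_fold: float = 1.5
    norm_depth: int = 10_000_000
    body_bins: int = 300
    flank_bins: int = 50
    flank_len: int = 1000
    fpkm_class_bounds: tuple = (1.0, 2.0, 10.0)
    de_fold: float = 1.5
    de_alpha: float = 0.05
    kmeans_k: int = 5
    seed: int = 1
    # knobs of the island caller the source study leaves implicit
    eligibility_p0: float = 0.2
    effective_fraction: float = 0.74

    def validate(self) -> None:
        if self.window_W <= 0:
            raise ValidationError("window_W must be positive")
        if self.body_bins <= 0 or self.flank_bins <= 0 or self.flank_len <= 0:
            raise ValidationError("bin counts and flank length must be positive")
        if not all(g >= 0 for g in self.gap_G.values()):
            raise ValidationError("gap_G values must be non-negative")
        if len(self.fpkm_class_bounds) != 3 or list(self.fpkm_class_bounds) != sorted(
                self.fpkm_class_bounds):
            raise ValidationError("fpkm_class_bounds must be three ascending floats")
        for name in ("island_fdr_call", "island_fdr_sig", "diff_fdr", "de_alpha",
                     "eligibility_p0"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"{name} must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fpkm_class_bounds"] = list(self.fpkm_class_bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        d = dict(d)
        if "fpkm_class_bounds" in d:
            d["fpkm_class_bounds"] = tuple(d["fpkm_class_bounds"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def _parse_gff3_attributes(text: str) -> dict:
    out = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_annotation(path: str | Path, dialect: str = "GFF3") -> list[GeneModel]:
    """Read gene models from GFF3 (feature type "gene") or BED6/BED12.

    GFF3's 1-based closed coordinates are converted to 0-based half-open.
    Duplicate gene IDs are rejected.
    """
    dialect = dialect.upper()
    if dialect not in ("GFF3", "BED"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "GFF3":
                    if len(fields) < 9:
                        raise ValueError("expected 9 tab-separated fields")
                    if fields[2] != "gene":
                        continue
                    chrom = fields[0]
                    start = int(fields[3]) - 1  # 1-based closed -> 0-based half-open
                    end = int(fields[4])
                    strand = fields[6]
                    attrs = _parse_gff3_attributes(fields[8])
                    gene_id = attrs.get("ID")
                    if gene_id is None:
                        raise ValueError("missing ID attribute")
                    is_te = attrs.get("is_te", "false").lower() in ("1", "true", "yes")
                else:
                    if len(fields) < 6:
                        raise ValueError("expected at least 6 BED fields")
                    chrom = fields[0]
                    start = int(fields[1])
                    end = int(fields[2])
                    gene_id = fields[3]
                    strand = fields[5]
                    is_te = False
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed {dialect} line: {exc}") from exc
            if gene_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            genes.append(GeneModel(gene_id=gene_id, chrom=chrom, start=start,
                                   end=end, strand=strand, is_te=is_te))
    return genes


def write_gene_annotation(genes: Sequence[GeneModel], path: str | Path,
                          dialect: str = "GFF3") -> None:
    dialect = dialect.upper()
    with open(path, "w") as fh:
        if dialect == "GFF3":
            fh.write("##gff-version 3\n")
            for g in genes:
                attrs = f"ID={g.gene_id}"
                if g.is_te:
                    attrs += ";is_te=true"
                fh.write(f"{g.chrom}\tepimarks\tgene\t{g.start + 1}\t{g.end}\t.\t"
                         f"{g.strand}\t.\t{attrs}\n")
        elif dialect == "BED":
            for g in genes:
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
        else:
            raise ValueError(f"unknown annotation dialect {dialect!r}")


# ---------------------------------------------------------------------------
# mapped reads (BED3 / BED6)
# ---------------------------------------------------------------------------

def read_reads_bed(path: str | Path, sample_label: str, genotype: str) -> ReadSet:
    """Read mapped-read intervals from BED3 or BED6 and deduplicate.

    BED3 files are assigned strand "+" (read strand is never used in density
    counting; only gene strand orients bins).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 3:
                    raise ValueError("expected at least 3 BED fields")
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                strand = fields[5] if len(fields) >= 6 else "+"
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed BED line: {exc}") from exc
            if end <= start:
                raise ValidationError(
                    f"{path}:{lineno}: read end ({end}) must exceed start ({start})")
            rows.append((chrom, start, end, strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    if df.empty:
        df = pd.DataFrame({"chrom": pd.Series(dtype=str),
                           "start": pd.Series(dtype=np.int64),
                           "end": pd.Series(dtype=np.int64),
                           "strand": pd.Series(dtype=str)})
    return ReadSet.from_dataframe(df, sample_label, genotype)


def write_reads_bed(readset: ReadSet, path: str | Path) -> None:
    df = readset.reads
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"],
        "end": df["end"],
        "name": [f"r{i}" for i in range(len(df))],
        "score": 0,
        "strand": df["strand"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# bedGraph density tracks
# ---------------------------------------------------------------------------

_BEDGRAPH_HEADER = "track type=bedGraph\n"


def write_bedgraph(track: pd.DataFrame, path: str | Path) -> None:
    """Write a density track (chrom/start/end/value) as bedGraph.

    Intervals must be sorted and non-overlapping within each chromosome.
    """
    required = ["chrom", "start", "end", "value"]
    missing = [c for c in required if c not in track.columns]
    if missing:
        raise ValidationError(f"track missing columns {missing}")
    for chrom, sub in track.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if np.any(starts[1:] < ends[:-1]):
            raise ValidationError(f"overlapping or unsorted intervals on {chrom}")
        if np.any(ends <= starts):
            raise ValidationError(f"empty interval on {chrom}")
    with open(path, "w") as fh:
        fh.write(_BEDGRAPH_HEADER)
        for row in track.itertuples(index=False):
            fh.write(f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{row.value:.10g}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("track") or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed bedGraph line") from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
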