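"""Metagene binning, input calibration and the per-gene mark-level statistic.

Every gene longer than 500 bp is rescaled to a common axis of
``flank_bins + body_bins + flank_bins`` bins (default 50 + 300 + 50 = 400):
the TSS-TTS body is split into 300 equal-width bins (fractional widths
allowed) and each 1-kb flank into 50 bins of 20 bp.  A read contributes to
every bin it overlaps, weighted by overlapped bp / read length, so the bin
vector conserves total fractional read mass.  Raw counts are scaled to a
common depth (10 million reads by default) and calibrated against the input
control by element-wise subtraction.

The per-gene level statistic is the depth-normalized read density over the
TSS-TTS span (reads per kb per normalized depth), ChIP minus input; it may
be negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, PipelineConfig, ReadSet, ValidationError

MIN_BINNED_GENE_LEN = 500  # genes at or below this length are not binned


@dataclass
class BinProfile:
    """Normalized reads-per-bin density vector for one gene, oriented 5'->3'."""

    gene_id: str
    values: np.ndarray


@dataclass
class MetageneProfile:
    """Per-bin arithmetic mean of BinProfiles over a gene set."""

    label: str
    n_genes: int
    mean_values: np.ndarray
    dispersion: np.ndarray | None = None


@dataclass
class GeneLevelStat:
    """Depth-normalized read density over the gene span, ChIP minus input."""

    gene_id: str
    chip_density: float
    input_density: float

    @property
    def level(self) -> float:
        return self.chip_density - self.input_density


def depth_factor(readset: ReadSet, norm_depth: int) -> float:
    """Multiplicative factor rescaling a library to ``norm_depth`` reads."""
    if readset.total_reads <= 0:
        raise ValidationError(
            f"empty library {readset.sample_label}/{readset.genotype}: "
            "cannot compute a depth factor")
    return norm_depth / readset.total_reads


class _ChromReads:
    """Per-chromosome read arrays with weighted-overlap queries.

    Overlap weight of a read with an interval is overlapped-bp / read-length,
    i.e. each read carries total mass 1 spread uniformly over its span.
    """

    def __init__(self, readset: ReadSet, chrom: str):
        starts, ends = readset.chrom_arrays(chrom)
        self.starts = starts
        self.ends = ends
        self.max_len = int((ends - starts).max()) if len(starts) else 0

    def _candidates(self, lo: int, hi: int) -> tuple[np.ndarray, np.ndarray]:
        if len(self.starts) == 0:
            return self.starts, self.ends
        i0 = np.searchsorted(self.starts, lo - self.max_len, side="left")
        i1 = np.searchsorted(self.starts, hi, side="left")
        return self.starts[i0:i1], self.ends[i0:i1]

    def weighted_count(self, lo: int, hi: int) -> float:
        """Sum over reads of (overlap with [lo, hi)) / read length."""
        s, e = self._candidates(lo, hi)
        if len(s) == 0:
            return 0.0
        ov = np.minimum(e, hi) - np.maximum(s, lo)
        mask = ov > 0
        return float(np.sum(ov[mask] / (e[mask] - s[mask])))

    def mass_coverage(self, lo: int, hi: int) -> np.ndarray:
        """Per-base coverage over [lo, hi) where each read adds 1/read_len."""
        cov = np.zeros(hi - lo + 1)
        s, e = self._candidates(lo, hi)
        if len(s):
            w = 1.0 / (e - s)
            cs = np.clip(s, lo, hi) - lo
            ce = np.clip(e, lo, hi) - lo
            keep = ce > cs
            np.add.at(cov, cs[keep], w[keep])
            np.add.at(cov, ce[keep], -w[keep])
        return np.cumsum(cov)[:-1]


def _bin_edges(gene: GeneModel, config: PipelineConfig) -> np.ndarray:
    """Genomic (unoriented) bin-edge positions, ascending, possibly negative."""
    up = np.linspace(gene.start - config.flank_len, gene.start,
                     config.flank_bins + 1)
    body = np.linspace(gene.start, gene.end, config.body_bins + 1)
    down = np.linspace(gene.end, gene.end + config.flank_len,
                       config.flank_bins + 1)
    return np.concatenate([up[:-1], body[:-1], down])


def bin_gene(gene: GeneModel, readset: ReadSet, config: PipelineConfig,
             chrom_len: int | None = None,
             _reads: "_ChromReads | None" = None,
             _factor: float | None = None) -> BinProfile | None:
    """Bin one gene's reads into the common flank/body/flank axis.

    Returns ``None`` for genes of 500 bp or less (they are excluded from
    binned profiles; callers record them in a skipped-gene report).  Flank
    bins extending past the chromosome are truncated: they keep their index
    and integrate whatever bases exist.
    """
    if gene.length <= MIN_BINNED_GENE_LEN:
        return None
    edges = _bin_edges(gene, config)
    lo = max(0, int(np.floor(edges[0])))
    hi = int(np.ceil(edges[-1]))
    if chrom_len is not None:
        hi = min(hi, chrom_len)
    cr = _reads if _reads is not None else _ChromReads(readset, gene.chrom)
    factor = _factor if _factor is not None else depth_factor(readset, config.norm_depth)
    clipped = np.clip(edges, lo, hi)
    if hi <= lo:
        values = np.zeros(len(edges) - 1)
    else:
        cov = cr.mass_coverage(lo, hi)
        # cumulative mass up to position x, piecewise linear between bases
        cum = np.concatenate([[0.0], np.cumsum(cov)])
        at_edges = np.interp(clipped - lo, np.arange(len(cum)), cum)
        values = np.diff(at_edges)
    values = values * factor
    if gene.strand == "-":
        values = values[::-1]
    return BinProfile(gene_id=gene.gene_id, values=values)


def bin_gene_set(genes: Sequence[GeneModel], readset: ReadSet,
                 config: PipelineConfig, chrom_lens: dict | None = None
                 ) -> tuple[dict[str, BinProfile], list[str]]:
    """Bin every gene; returns (profiles by gene_id, skipped gene_ids)."""
    factor = depth_factor(readset, config.norm_depth)
    cache: dict[str, _ChromReads] = {}
    profiles: dict[str, BinProfile] = {}
    skipped: list[str] = []
    for g in genes:
        if g.chrom not in cache:
            cache[g.chrom] = _ChromReads(readset, g.chrom)
        cl = chrom_lens.get(g.chrom) if chrom_lens else None
        prof = bin_gene(g, readset, config, chrom_len=cl,
                        _reads=cache[g.chrom], _factor=factor)
        if prof is None:
            skipped.append(g.gene_id)
        else:
            profiles[g.gene_id] = prof
    return profiles, skipped


def subtract_input(chip: BinProfile, input_profile: BinProfile) -> BinProfile:
    """Input calibration: element-wise difference of depth-normalized bins.

    Negative values are retained.
    """
    if len(chip.values) != len(input_profile.values):
        raise ValidationError("bin-profile length mismatch between ChIP and input")
    return BinProfile(gene_id=chip.gene_id,
                      values=chip.values - input_profile.values)


def average_profile(profiles: Sequence[BinProfile], label: str) -> MetageneProfile:
    """Per-bin arithmetic mean over a gene set (the metagene curve)."""
    if len(profiles) == 0:
        raise ValidationError(f"cannot average an empty profile set ({label!r})")
    mat = np.vstack([p.values for p in profiles])
    if not np.all([len(p.values) == mat.shape[1] for p in profiles]):
        raise ValidationError("profiles of differing length")
    return MetageneProfile(label=label, n_genes=mat.shape[0],
                           mean_values=mat.mean(axis=0),
                           dispersion=mat.std(axis=0, ddof=0))


def gene_level(gene: GeneModel, chip: ReadSet, input_rs: ReadSet,
               config: PipelineConfig) -> GeneLevelStat:
    """ChIP minus input normalized read density over the TSS-TTS span."""
    table = gene_level_table([gene], chip, input_rs, config)
    row = table.iloc[0]
    return GeneLevelStat(gene_id=gene.gene_id,
                         chip_density=row["chip_density"],
                         input_density=row["input_density"])


def gene_level_table(genes: Sequence[GeneModel], chip: ReadSet,
                     input_rs: ReadSet, config: PipelineConfig) -> pd.DataFrame:
    """Per-gene mark-level statistics for many genes at once.

    density = weighted read count over [start, end) x depth_factor / kb;
    level = chip_density - input_density.
    """
    f_chip = depth_factor(chip, config.norm_depth)
    f_input = depth_factor(input_rs, config.norm_depth)
    chip_cache: dict[str, _ChromReads] = {}
    input_cache: dict[str, _ChromReads] = {}
    rows = []
    for g in genes:
        if g.chrom not in chip_cache:
            chip_cache[g.chrom] = _ChromReads(chip, g.chrom)
            input_cache[g.chrom] = _ChromReads(input_rs, g.chrom)
        kb = g.length / 1000.0
        cd = chip_cache[g.chrom].weighted_count(g.start, g.end) * f_chip / kb
        idd = input_cache[g.chrom].weighted_count(g.start, g.end) * f_input / kb
        rows.append((g.gene_id, cd, idd, cd - idd))
    return pd.DataFrame(rows, columns=["gene_id", "chip_density",
                                       "input_density", "level"])


def profiles_to_frame(profiles: Iterable[BinProfile]) -> pd.DataFrame:
    """Genes x bins matrix for TSV export (heatmap-tool compatible)."""
    data = {p.gene_id: p.values for p in profiles}
    df = pd.DataFrame.from_dict(data, orient="index")
    df.index.name = "gene_id"
    df.columns = [f"bin_{i}" for i in range(df.shape[1])]
    return df
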