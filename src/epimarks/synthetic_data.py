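"""Synthetic annotation, ChIP reads and expression with planted ground truth.

The generator emulates the statistical structure of a two-genotype
histone-mark study on a small genome so that every downstream stage can be
verified against known truth:

* non-overlapping gene models on one chromosome, mixed strands;
* per-gene latent expression (log-normal) with overdispersed replicate
  counts and a planted fraction of differentially expressed genes (half up,
  half down, fold drawn from ``de_fold_range``), planted among genes
  expressed clearly enough for DE detection to be meaningful;
* mark-specific spatial read templates: a sharp TSS peak for H3K4me3, broad
  gene-body coverage with a weak TSS bump for H3K4me2, 5'-biased gene-body
  coverage for H3K36me3, uniform low gene-body coverage for H3K4me1, and a
  uniform background plus an input library that is background only;
* sign-controlled coupling between each mark and expression: per-gene
  signal mass is a linear function of the gene's expression *rank* with
  slope given by ``coupling[mark]`` in [-1, 1], so downstream Spearman
  correlations have an analytically predictable sign;
* a mutant genotype with a global reduction of H3K4me2/H3K4me3 signal plus
  gene-specific planted changes following five (delta-me2, delta-me3)
  patterns, coordinated with the planted DE labels (H3K4me3-loss patterns
  on down-regulated genes, the H3K4me2-only-loss pattern on up-regulated
  genes), which plants recoverable differential islands and a K-means
  peak-set structure.

The same seed yields byte-identical output; each operation draws from its
own seeded stream so the pieces are independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (INPUT_LABEL, MARKS, MUT, WT, GeneModel, ReadSet,
                         ValidationError, write_gene_annotation,
                         write_reads_bed)

# stable sub-stream keys so each operation has its own reproducible RNG
_RNG_ANNOTATION = 11
_RNG_EXPRESSION = 22
_RNG_PATTERNS = 33
_RNG_READS_BASE = 100

# mutant change patterns: set_index -> (H3K4me2 factor, H3K4me3 factor)
PATTERN_FACTORS = {
    1: (1.5, 0.2),   # me2 slightly up, me3 strongly down
    2: (1.0, 0.2),   # me2 unchanged, me3 strongly down
    3: (0.6, 0.2),   # me2 slightly down, me3 strongly down
    4: (0.2, 0.2),   # both strongly down
    5: (0.2, 1.0),   # me2 strongly down, me3 unchanged
}
# a factor at or below this counts as a planted "decreased" differential island
STRONG_LOSS_FACTOR = 0.5


@dataclass
class GeneratorParams:
    """Knobs of the synthetic study; defaults are the study conditions.

    Depth and library sizes are scaled to the toy genome: ~0.05 reads/bp of
    ChIP coverage matches the read-per-base density of a typical broad-mark
    ChIP-seq library, and the nominal RNA library size of 20 million mapped
    reads matches routine RNA-seq depth (the toy gene catalog is treated as
    a subsample of such a library, so FPKM values keep their usual scale).
    """

    n_genes: int = 2000
    chrom: str = "chr1"
    chrom_len: int = 20_000_000
    gene_len_range: tuple = (600, 3000)
    # keeps neighbouring genes' islands from merging under the largest gap
    # parameter (600 bp) plus window rounding, so each planted island maps
    # to exactly one called island
    min_intergenic_gap: int = 2000
    expr_meanlog: float = math.log(2.0)
    expr_sdlog: float = 1.5
    coupling: dict = field(default_factory=lambda: {
        "H3K4me1": 0.4, "H3K4me2": -0.8, "H3K4me3": 0.8, "H3K36me3": 0.8})
    reads_per_sample: int = 1_000_000
    signal_fraction: float = 0.8
    read_len: int = 51
    n_replicates: int = 3
    library_size: int = 20_000_000
    dispersion: float = 0.05
    fraction_de: float = 0.2
    de_fold_range: tuple = (2.0, 4.0)
    de_min_fpkm: float = 2.0
    mutant_global_factor: dict = field(default_factory=lambda: {
        "H3K4me2": 0.85, "H3K4me3": 0.85})
    pattern_sizes: dict = field(default_factory=lambda: {
        1: 80, 2: 80, 3: 80, 4: 80, 5: 80})
    pattern_band: tuple = (0.40, 0.65)   # expression-rank band for sets 3/4
    tss_sd: float = 150.0
    tss_span: int = 300
    me2_tss_bump: float = 0.15
    k36_beta: tuple = (1.5, 3.0)
    k36_span_fraction: float = 0.6
    planted_min_enrichment: float = 3.0
    seed: int = 1

    def validate(self) -> None:
        if self.n_genes < 0 or self.chrom_len <= 0 or self.reads_per_sample < 0:
            raise ValidationError("counts must be non-negative and chrom_len positive")
        if not (0 <= self.signal_fraction <= 1):
            raise ValidationError("signal_fraction must lie in [0, 1]")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        for mark, c in self.coupling.items():
            if not (-1 <= c <= 1):
                raise ValidationError(f"coupling[{mark}] must lie in [-1, 1]")


@dataclass
class SyntheticTruth:
    """Planted ground truth for a generated dataset."""

    expression: pd.DataFrame           # gene_id, latent_wt, latent_mut, rank_pct,
                                       # de_label, de_fold, set_index (0 = none)
    mark_coupling: dict
    planted_islands: pd.DataFrame      # mark, genotype, chrom, start, end, gene_id
    planted_differential: pd.DataFrame # mark, chrom, start, end, gene_id, direction


@dataclass
class SyntheticDataset:
    params: GeneratorParams
    genes: list
    expression_table: pd.DataFrame
    readsets: dict
    truth: SyntheticTruth


def _rng(params: GeneratorParams, key: int) -> np.random.Generator:
    return np.random.default_rng([int(params.seed), int(key)])


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(params: GeneratorParams) -> list[GeneModel]:
    """Non-overlapping gene models with mixed strands on one chromosome."""
    params.validate()
    n = params.n_genes
    if n == 0:
        return []
    rng = _rng(params, _RNG_ANNOTATION)
    lo, hi = params.gene_len_range
    lengths = rng.integers(lo, hi + 1, size=n)
    margin = 2000  # room for 1-kb flanks plus slack at the chromosome ends
    min_gap = max(0, params.min_intergenic_gap)
    slack = (params.chrom_len - 2 * margin - int(lengths.sum())
             - (n + 1) * min_gap)
    if slack < 0:
        raise ValidationError(
            f"cannot pack {n} genes totalling {int(lengths.sum())} bp into "
            f"{params.chrom_len} bp with {min_gap} bp minimum gaps")
    gaps = min_gap + np.floor(rng.dirichlet(np.ones(n + 1)) * slack).astype(np.int64)
    strands = rng.choice(["+", "-"], size=n)
    genes = []
    pos = margin
    for i in range(n):
        pos += int(gaps[i])
        start = pos
        end = start + int(lengths[i])
        genes.append(GeneModel(gene_id=f"g{i:05d}", chrom=params.chrom,
                               start=start, end=end, strand=str(strands[i])))
        pos = end
    return genes


# ---------------------------------------------------------------------------
# expression and planted DE
# ---------------------------------------------------------------------------

def generate_expression(genes: list, params: GeneratorParams
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate count/FPKM tables for both genotypes plus expression truth.

    Returns (long table with columns gene_id/genotype/replicate/count/fpkm,
    truth frame with latent means and DE labels).  DE genes are planted
    among genes with latent FPKM >= ``de_min_fpkm``, exactly half up and
    half down, each with a fold drawn from ``de_fold_range``.
    """
    if params.n_replicates < 2:
        raise ValidationError("generate_expression needs n_replicates >= 2")
    rng = _rng(params, _RNG_EXPRESSION)
    n = len(genes)
    latent_wt = rng.lognormal(params.expr_meanlog, params.expr_sdlog, size=n)
    de_label = np.full(n, "invariant", dtype=object)
    de_fold = np.ones(n)
    n_de = int(round(params.fraction_de * n))
    candidates = np.flatnonzero(latent_wt >= params.de_min_fpkm)
    if n_de > len(candidates):
        raise ValidationError(
            f"cannot plant {n_de} DE genes: only {len(candidates)} genes have "
            f"latent FPKM >= {params.de_min_fpkm}")
    chosen = rng.choice(candidates, size=n_de, replace=False)
    half = n_de // 2
    de_label[chosen[:half]] = "up"
    de_label[chosen[half:]] = "down"
    de_fold[chosen] = rng.uniform(*params.de_fold_range, size=n_de)
    latent_mut = latent_wt.copy()
    latent_mut[de_label == "up"] = (latent_wt * de_fold)[de_label == "up"]
    latent_mut[de_label == "down"] = (latent_wt / de_fold)[de_label == "down"]

    len_kb = np.array([g.length for g in genes]) / 1000.0
    lib_millions = params.library_size / 1e6
    rows = []
    for genotype, latent in ((WT, latent_wt), (MUT, latent_mut)):
        mean = latent * len_kb * lib_millions
        for rep in range(1, params.n_replicates + 1):
            if params.dispersion > 0:
                r = 1.0 / params.dispersion
                counts = rng.negative_binomial(r, r / (r + mean))
            else:
                counts = rng.poisson(mean)
            fpkm = counts / (len_kb * lib_millions)
            for g, c, f in zip(genes, counts, fpkm):
                rows.append((g.gene_id, genotype, rep, int(c), float(f)))
    table = pd.DataFrame(rows, columns=["gene_id", "genotype", "replicate",
                                        "count", "fpkm"])
    rank_pct = (stats.rankdata(latent_wt) - 0.5) / max(n, 1)
    truth = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "latent_wt": latent_wt,
        "latent_mut": latent_mut,
        "rank_pct": rank_pct,
        "de_label": de_label,
        "de_fold": de_fold,
    })
    return table, truth


def assign_differential_patterns(truth_expr: pd.DataFrame,
                                 params: GeneratorParams) -> pd.DataFrame:
    """Attach a mutant chromatin-change pattern (set 1-5) to chosen genes.

    Patterns with H3K4me3 loss but no H3K4me2 loss (sets 1, 2) go to
    down-regulated genes, the H3K4me2-only-loss pattern (set 5) to
    up-regulated ones (taking the least-expressed up genes so their
    H3K4me2 signal is strong enough to call), and the mixed patterns
    (sets 3, 4) to invariant genes in a mid-expression rank band where both
    marks carry callable wild-type islands.  Returns the truth frame with a
    ``set_index`` column (0 = no planted pattern).
    """
    rng = _rng(params, _RNG_PATTERNS)
    truth = truth_expr.copy()
    truth["set_index"] = 0
    sizes = params.pattern_sizes
    down = truth.index[truth["de_label"] == "down"].to_numpy()
    up_sorted = truth[truth["de_label"] == "up"].sort_values("latent_wt").index.to_numpy()
    lo, hi = params.pattern_band
    band = truth.index[(truth["de_label"] == "invariant")
                       & (truth["rank_pct"] >= lo)
                       & (truth["rank_pct"] <= hi)].to_numpy()
    need_down = sizes.get(1, 0) + sizes.get(2, 0)
    need_band = sizes.get(3, 0) + sizes.get(4, 0)
    need_up = sizes.get(5, 0)
    if need_down > len(down) or need_up > len(up_sorted) or need_band > len(band):
        raise ValidationError(
            "pattern_sizes exceed the available gene pools "
            f"(down {len(down)}, up {len(up_sorted)}, band {len(band)})")
    pick_down = rng.choice(down, size=need_down, replace=False)
    truth.loc[pick_down[:sizes.get(1, 0)], "set_index"] = 1
    truth.loc[pick_down[sizes.get(1, 0):], "set_index"] = 2
    pick_band = rng.choice(band, size=need_band, replace=False)
    truth.loc[pick_band[:sizes.get(3, 0)], "set_index"] = 3
    truth.loc[pick_band[sizes.get(3, 0):], "set_index"] = 4
    truth.loc[up_sorted[:need_up], "set_index"] = 5
    return truth


# ---------------------------------------------------------------------------
# ChIP reads
# ---------------------------------------------------------------------------

def _coupling_weights(truth_expr: pd.DataFrame, coupling: float) -> np.ndarray:
    """Per-gene signal weight 1 + c*(2*rank_pct - 1), clipped at zero."""
    rp = truth_expr["rank_pct"].to_numpy()
    return np.clip(1.0 + coupling * (2.0 * rp - 1.0), 0.0, None)


def _mark_span(gene: GeneModel, mark: str, params: GeneratorParams
               ) -> tuple[int, int]:
    """Genomic span of a mark's signal template on one gene."""
    if mark == "H3K4me3":
        return (max(0, gene.tss - params.tss_span),
                min(params.chrom_len, gene.tss + params.tss_span))
    if mark == "H3K36me3":
        span = int(round(params.k36_span_fraction * gene.length))
        if gene.strand == "+":
            return gene.start, gene.start + span
        return gene.end - span, gene.end
    # H3K4me1 / H3K4me2: whole gene body
    return gene.start, gene.end


def _mutant_factors(truth_expr: pd.DataFrame, mark: str,
                    params: GeneratorParams) -> np.ndarray:
    """Per-gene mutant signal scaling for one mark (1.0 everywhere for WT)."""
    factors = np.full(len(truth_expr),
                      params.mutant_global_factor.get(mark, 1.0))
    mark_col = 0 if mark == "H3K4me2" else (1 if mark == "H3K4me3" else None)
    if mark_col is not None:
        set_idx = truth_expr["set_index"].to_numpy()
        for s, fac in PATTERN_FACTORS.items():
            factors[set_idx == s] = fac[mark_col]
    return factors


def _signal_centers(gene: GeneModel, mark: str, n: int,
                    rng: np.random.Generator, params: GeneratorParams
                    ) -> np.ndarray:
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if mark == "H3K4me3":
        off = np.clip(rng.normal(0.0, params.tss_sd, n),
                      -params.tss_span, params.tss_span)
        return (gene.tss + off).astype(np.int64)
    if mark == "H3K36me3":
        t = rng.beta(*params.k36_beta, size=n)
        if gene.strand == "+":
            return (gene.start + t * gene.length).astype(np.int64)
        return (gene.end - t * gene.length).astype(np.int64)
    if mark == "H3K4me2":
        bump = rng.random(n) < params.me2_tss_bump
        centers = rng.integers(gene.start, gene.end, n)
        if bump.any():
            off = np.clip(rng.normal(0.0, params.tss_sd, int(bump.sum())),
                          -params.tss_span, params.tss_span)
            centers[bump] = (gene.tss + off).astype(np.int64)
        return centers
    if mark == "H3K4me1":
        return rng.integers(gene.start, gene.end, n)
    raise ValidationError(f"unknown mark {mark!r}")


def generate_chip_reads(genes: list, truth_expr: pd.DataFrame, mark: str,
                        genotype: str, params: GeneratorParams) -> ReadSet:
    """One ChIP (or input) library as a deduplicated ReadSet.

    Reads are a uniform genome-wide background plus, for ChIP marks,
    per-gene signal reads whose expected count is proportional to
    coupling-weight x gene length (so read *density* tracks the coupling
    weight) and whose positions follow the mark's spatial template.  The
    mutant genotype scales H3K4me2/H3K4me3 signal by a global factor and by
    the planted per-gene pattern factors.
    """
    if mark != INPUT_LABEL and mark not in MARKS:
        raise ValidationError(f"unknown mark {mark!r}")
    if genotype not in (WT, MUT):
        raise ValidationError(f"unknown genotype {genotype!r}")
    key = (_RNG_READS_BASE
           + 10 * ((MARKS.index(mark) + 1) if mark in MARKS else 0)
           + (0 if genotype == WT else 1))
    rng = _rng(params, key)
    half = params.read_len // 2
    starts_parts = []
    if mark == INPUT_LABEL:
        n_bg = params.reads_per_sample
    else:
        n_bg = rng.poisson((1.0 - params.signal_fraction) * params.reads_per_sample)
        weights = _coupling_weights(truth_expr, params.coupling[mark])
        lengths = np.array([g.length for g in genes], dtype=float)
        mass = weights * lengths
        total_mass = mass.sum()
        factors = (np.ones(len(genes)) if genotype == WT
                   else _mutant_factors(truth_expr, mark, params))
        if total_mass > 0:
            base = params.signal_fraction * params.reads_per_sample * mass / total_mass
            n_sig = rng.poisson(base * factors)
            for g, ns in zip(genes, n_sig):
                centers = _signal_centers(g, mark, int(ns), rng, params)
                starts_parts.append(centers - half)
    if n_bg > 0:
        starts_parts.append(rng.integers(0, max(1, params.chrom_len - params.read_len),
                                         n_bg))
    starts = (np.concatenate(starts_parts) if starts_parts
              else np.empty(0, dtype=np.int64))
    starts = np.clip(starts, 0, max(0, params.chrom_len - params.read_len))
    strands = rng.choice(["+", "-"], size=len(starts))
    df = pd.DataFrame({
        "chrom": params.chrom,
        "start": starts.astype(np.int64),
        "end": starts.astype(np.int64) + params.read_len,
        "strand": strands,
    })
    return ReadSet.from_dataframe(df, sample_label=mark, genotype=genotype)


# ---------------------------------------------------------------------------
# planted-island bookkeeping and the full dataset
# ---------------------------------------------------------------------------

def build_truth_islands(genes: list, truth_expr: pd.DataFrame,
                        params: GeneratorParams
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Record planted enrichment islands and planted differential islands.

    An island is recorded for (mark, genotype, gene) when the expected
    signal density over the mark's template span is at least
    ``planted_min_enrichment`` times the genome-average read density, i.e.
    when the generator actually planted a callable enrichment there.  A
    differential island is recorded where a pattern scales a mark's signal
    to <= ``STRONG_LOSS_FACTOR`` of wild type on a gene whose wild-type
    island is recorded.
    """
    avg_density = params.reads_per_sample / params.chrom_len
    island_rows = []
    diff_rows = []
    for mark in MARKS:
        weights = _coupling_weights(truth_expr, params.coupling[mark])
        lengths = np.array([g.length for g in genes], dtype=float)
        mass = weights * lengths
        total_mass = mass.sum()
        if total_mass == 0:
            continue
        base = params.signal_fraction * params.reads_per_sample * mass / total_mass
        wt_recorded = np.zeros(len(genes), dtype=bool)
        for genotype in (WT, MUT):
            factors = (np.ones(len(genes)) if genotype == WT
                       else _mutant_factors(truth_expr, mark, params))
            for i, g in enumerate(genes):
                lo, hi = _mark_span(g, mark, params)
                span = max(hi - lo, 1)
                density = base[i] * factors[i] / span
                if density >= params.planted_min_enrichment * avg_density:
                    island_rows.append((mark, genotype, g.chrom, lo, hi, g.gene_id))
                    if genotype == WT:
                        wt_recorded[i] = True
        mark_col = 0 if mark == "H3K4me2" else (1 if mark == "H3K4me3" else None)
        if mark_col is None:
            continue
        set_idx = truth_expr["set_index"].to_numpy()
        for i, g in enumerate(genes):
            s = int(set_idx[i])
            if s == 0 or not wt_recorded[i]:
                continue
            if PATTERN_FACTORS[s][mark_col] <= STRONG_LOSS_FACTOR:
                lo, hi = _mark_span(g, mark, params)
                diff_rows.append((mark, g.chrom, lo, hi, g.gene_id, "decreased"))
    planted = pd.DataFrame(island_rows, columns=[
        "mark", "genotype", "chrom", "start", "end", "gene_id"])
    diff = pd.DataFrame(diff_rows, columns=[
        "mark", "chrom", "start", "end", "gene_id", "direction"])
    return planted, diff


def generate_dataset(params: GeneratorParams) -> SyntheticDataset:
    """Run the whole generator: annotation, expression, truth, all libraries."""
    genes = generate_annotation(params)
    table, truth_expr = generate_expression(genes, params)
    truth_expr = assign_differential_patterns(truth_expr, params)
    planted, diff = build_truth_islands(genes, truth_expr, params)
    truth = SyntheticTruth(expression=truth_expr,
                           mark_coupling=dict(params.coupling),
                           planted_islands=planted,
                           planted_differential=diff)
    readsets = {}
    for mark in MARKS:
        for genotype in (WT, MUT):
            readsets[(mark, genotype)] = generate_chip_reads(
                genes, truth_expr, mark, genotype, params)
    for genotype in (WT, MUT):
        readsets[(INPUT_LABEL, genotype)] = generate_chip_reads(
            genes, truth_expr, INPUT_LABEL, genotype, params)
    return SyntheticDataset(params=params, genes=genes,
                            expression_table=table, readsets=readsets,
                            truth=truth)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Emit the dataset in the formats the io layer consumes; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    ann = outdir / "annotation.gff3"
    write_gene_annotation(ds.genes, ann, dialect="GFF3")
    paths["annotation"] = str(ann)
    for (mark, genotype), rs in ds.readsets.items():
        p = outdir / f"reads_{mark}_{genotype}.bed"
        write_reads_bed(rs, p)
        paths[f"reads_{mark}_{genotype}"] = str(p)
    expr = outdir / "expression.tsv"
    ds.expression_table.to_csv(expr, sep="\t", index=False)
    paths["expression"] = str(expr)
    truth = outdir / "truth_expression.tsv"
    ds.truth.expression.to_csv(truth, sep="\t", index=False)
    paths["truth_expression"] = str(truth)
    pi = outdir / "truth_planted_islands.tsv"
    ds.truth.planted_islands.to_csv(pi, sep="\t", index=False)
    paths["truth_planted_islands"] = str(pi)
    pdiff = outdir / "truth_planted_differential.tsv"
    ds.truth.planted_differential.to_csv(pdiff, sep="\t", index=False)
    paths["truth_planted_differential"] = str(pdiff)
    return paths
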