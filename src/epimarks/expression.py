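"""Expression classing and differential-expression calling.

Wild-type mean FPKM assigns each gene one of four classes (Non [0,1),
Low [1,2), Middle [2,10), High [10,inf); the published intervals are open
at the boundaries, resolved here as half-open ascending).  DE calls use the
threshold rule fold > 1.5 and BH-adjusted p < 0.05; the fold is computed
from mean FPKM with pseudocount 1 and the p-value from a two-group
overdispersed count comparison with a method-of-moments common dispersion
(a negative-binomial mean-variance model, delta-method z on log means).
The "expressed" filter (mean wild-type FPKM strictly above 1) is kept
independent of the classing rule: a gene at exactly FPKM = 1 is class Low
yet fails the expressed filter.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import MUT, WT, PipelineConfig, ValidationError

EXPRESSION_CLASSES = ("Non", "Low", "Middle", "High")


def classify_expression(mean_fpkm: float,
                        bounds: Sequence[float] = (1.0, 2.0, 10.0)) -> str:
    """Class label for one FPKM value under the half-open boundary rule."""
    if not np.isfinite(mean_fpkm) or mean_fpkm < 0:
        raise ValidationError(f"FPKM must be finite and non-negative, got {mean_fpkm}")
    lo, mid, hi = bounds
    if mean_fpkm < lo:
        return "Non"
    if mean_fpkm < mid:
        return "Low"
    if mean_fpkm < hi:
        return "Middle"
    return "High"


def classify_expression_vector(fpkm: np.ndarray,
                               bounds: Sequence[float] = (1.0, 2.0, 10.0)
                               ) -> np.ndarray:
    fpkm = np.asarray(fpkm, dtype=float)
    if np.any(~np.isfinite(fpkm)) or np.any(fpkm < 0):
        raise ValidationError("FPKM values must be finite and non-negative")
    idx = np.searchsorted(np.asarray(bounds, dtype=float), fpkm, side="right")
    return np.array(EXPRESSION_CLASSES, dtype=object)[idx]


def load_expression_table(path) -> pd.DataFrame:
    """Long-format table: gene_id, genotype, replicate, count[, fpkm]."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "genotype", "replicate", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"expression table missing columns {sorted(missing)}")
    return df


def compute_fpkm(counts: np.ndarray, gene_len_bp: np.ndarray,
                 library_size: float) -> np.ndarray:
    """FPKM = count / (gene length in kb x library size in millions)."""
    return np.asarray(counts, float) / (
        np.asarray(gene_len_bp, float) / 1000.0 * (library_size / 1e6))


def _moment_dispersion(mat_wt: np.ndarray, mat_mut: np.ndarray) -> float:
    """Method-of-moments common NB dispersion from within-group replicates.

    For NB counts, var = mu + alpha * mu^2, so alpha = (s^2 - m) / m^2 per
    gene per group; the common value is the median over informative genes.
    """
    ests = []
    for mat in (mat_wt, mat_mut):
        m = mat.mean(axis=1)
        v = mat.var(axis=1, ddof=1)
        ok = m >= 5
        if ok.any():
            ests.append((v[ok] - m[ok]) / m[ok] ** 2)
    if not ests:
        return 0.0
    pooled = np.concatenate(ests)
    return float(max(0.0, np.median(pooled)))


def call_de(table: pd.DataFrame, config: PipelineConfig,
            wt_label: str = WT, mut_label: str = MUT) -> pd.DataFrame:
    """Per-gene DE calls from replicate counts of two genotypes.

    Returns one row per gene with per-genotype mean FPKM, expression class
    (wild type), pseudocounted log2 fold change (mutant/wild type), raw and
    BH-adjusted p, and de_status in {up, down, invariant}.
    """
    for genotype in (wt_label, mut_label):
        sub = table[table["genotype"] == genotype]
        reps = sub["replicate"].nunique()
        if reps < 2:
            raise ValidationError(
                f"genotype {genotype!r} needs >= 2 replicates, found {reps}")
        per_gene = sub.groupby("gene_id")["replicate"].nunique()
        if (per_gene != reps).any():
            raise ValidationError(
                f"genotype {genotype!r}: missing replicate entries for some genes")

    counts = table.pivot_table(index="gene_id", columns=["genotype", "replicate"],
                               values="count")
    if counts.isna().any().any():
        raise ValidationError("missing replicate entries for some genes")
    mat_wt = counts[wt_label].to_numpy(dtype=float)
    mat_mut = counts[mut_label].to_numpy(dtype=float)

    # normalize for library depth (total-count size factors around the mean)
    totals = np.concatenate([mat_wt.sum(axis=0), mat_mut.sum(axis=0)])
    ref = totals.mean()
    sf_wt = mat_wt.sum(axis=0) / ref
    sf_mut = mat_mut.sum(axis=0) / ref
    norm_wt = mat_wt / sf_wt
    norm_mut = mat_mut / sf_mut

    alpha = _moment_dispersion(norm_wt, norm_mut)
    n1, n2 = norm_wt.shape[1], norm_mut.shape[1]
    m1 = norm_wt.mean(axis=1) + 0.5
    m2 = norm_mut.mean(axis=1) + 0.5
    # delta-method variance of log mean under var = mu + alpha mu^2
    se = np.sqrt((m1 + alpha * m1 ** 2) / (n1 * m1 ** 2)
                 + (m2 + alpha * m2 ** 2) / (n2 * m2 ** 2))
    z = (np.log(m2) - np.log(m1)) / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    informative = (mat_wt.sum(axis=1) + mat_mut.sum(axis=1)) > 0
    pvals = np.where(informative, pvals, 1.0)
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")

    if "fpkm" in table.columns:
        fpkm = table.pivot_table(index="gene_id", columns="genotype", values="fpkm",
                                 aggfunc="mean")
        fpkm = fpkm.reindex(counts.index)
        mean_fpkm_wt = fpkm[wt_label].to_numpy(dtype=float)
        mean_fpkm_mut = fpkm[mut_label].to_numpy(dtype=float)
    else:
        raise ValidationError(
            "expression table lacks an fpkm column; compute it with "
            "compute_fpkm from counts and gene lengths first")

    fold_mut_wt = (mean_fpkm_mut + 1.0) / (mean_fpkm_wt + 1.0)
    log2_fc = np.log2(fold_mut_wt)
    up = (fold_mut_wt > config.de_fold) & (p_adj < config.de_alpha)
    down = (1.0 / fold_mut_wt > config.de_fold) & (p_adj < config.de_alpha)
    de_status = np.full(len(counts), "invariant", dtype=object)
    de_status[up] = "up"
    de_status[down] = "down"

    out = pd.DataFrame({
        "gene_id": counts.index.to_numpy(),
        "mean_fpkm_wt": mean_fpkm_wt,
        "mean_fpkm_mut": mean_fpkm_mut,
        "expression_class": classify_expression_vector(
            mean_fpkm_wt, config.fpkm_class_bounds),
        "log2_fc": log2_fc,
        "p_value": pvals,
        "p_adj": p_adj,
        "de_status": de_status,
    })
    return out.reset_index(drop=True)


def expressed_filter(records: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Genes with wild-type mean FPKM strictly above the threshold."""
    return records[records["mean_fpkm_wt"] > threshold].reset_index(drop=True)
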