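"""Integrative statistics: mark-expression correlation, profile comparison,
expression contrasts between gene clusters, K-means peak sets and Fisher
enrichment against DEG lists.

Spearman's rank correlation (mid-rank ties, large-sample t approximation for
p) quantifies the mark-expression relationship on expressed genes, either
per gene (default) or on expression-rank-binned means.  Metagene profiles
are compared with the two-sample Kolmogorov-Smirnov test on their bin-value
vectors; cluster expression with the two-sided rank-sum test.  Differential
peaks are partitioned by K-means (k = 5) on standardized log2 density
changes with deterministic greedy farthest-point seeding, and each centroid
is matched to one of the five qualitative change patterns.  Peak-set/DEG
association uses the two-sided Fisher exact test with a Haldane-corrected
odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .io_formats import PipelineConfig, ValidationError

PEAK_SET_LABELS = {
    1: "me2_up_me3_down",
    2: "me2_stable_me3_down",
    3: "me2_slight_down_me3_down",
    4: "me2_down_me3_down",
    5: "me2_down_me3_stable",
}


@dataclass
class CorrelationResult:
    mark: str
    n_genes: int
    rho: float
    p_value: float
    mode: str
    n_bins: int | None = None


# ---------------------------------------------------------------------------
# Spearman mark vs expression
# ---------------------------------------------------------------------------

def spearman_mark_vs_expression(levels: pd.DataFrame, records: pd.DataFrame,
                                mark: str = "", mode: str = "per_gene",
                                n_bins: int = 20) -> CorrelationResult:
    """Spearman rho between per-gene mark level and mean FPKM.

    ``levels`` carries gene_id/level, ``records`` gene_id/mean_fpkm_wt and
    must already be restricted to expressed genes (FPKM > 1).  In
    ``rank_binned`` mode genes are sorted by FPKM into ``n_bins``
    equal-count bins and the bin means are correlated instead.
    """
    merged = levels.merge(records[["gene_id", "mean_fpkm_wt"]], on="gene_id")
    n = len(merged)
    if n < 10:
        raise ValidationError(f"need >= 10 genes for a correlation, got {n}")
    level = merged["level"].to_numpy(dtype=float)
    fpkm = merged["mean_fpkm_wt"].to_numpy(dtype=float)
    if np.ptp(level) == 0 or np.ptp(fpkm) == 0:
        raise ValidationError("correlation undefined on a constant vector")
    if mode == "per_gene":
        rho, p = stats.spearmanr(level, fpkm)
        return CorrelationResult(mark=mark, n_genes=n, rho=float(rho),
                                 p_value=float(p), mode=mode)
    if mode == "rank_binned":
        order = np.argsort(fpkm, kind="mergesort")
        bins = np.array_split(order, n_bins)
        bl = np.array([level[b].mean() for b in bins if len(b)])
        bf = np.array([fpkm[b].mean() for b in bins if len(b)])
        rho, p = stats.spearmanr(bl, bf)
        return CorrelationResult(mark=mark, n_genes=n, rho=float(rho),
                                 p_value=float(p), mode=mode, n_bins=len(bl))
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# profile and cluster comparisons
# ---------------------------------------------------------------------------

def ks_profile_compare(values_a: np.ndarray, values_b: np.ndarray
                       ) -> tuple[float, float]:
    """Two-sample KS statistic and p on two equal-length bin-value vectors.

    Accepts raw vectors or MetageneProfile objects.
    """
    a = np.asarray(getattr(values_a, "mean_values", values_a), dtype=float)
    b = np.asarray(getattr(values_b, "mean_values", values_b), dtype=float)
    if a.shape != b.shape:
        raise ValidationError("profiles have different bin counts")
    if np.array_equal(a, b):
        return 0.0, 1.0
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_cluster_expression(cluster_of: Mapping[str, str],
                                records: pd.DataFrame,
                                min_size: int = 3) -> pd.DataFrame:
    """Pairwise two-sided rank-sum p-values on mean FPKM between clusters.

    Clusters with fewer than ``min_size`` genes are skipped (NaN row/column).
    Ties are handled by mid-ranks; the diagonal is exactly 1.
    """
    df = records[["gene_id", "mean_fpkm_wt"]].copy()
    df["cluster"] = df["gene_id"].map(cluster_of)
    df = df.dropna(subset=["cluster"])
    groups = {c: sub["mean_fpkm_wt"].to_numpy(dtype=float)
              for c, sub in df.groupby("cluster")}
    labels = sorted(groups)
    mat = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i, a in enumerate(labels):
        if len(groups[a]) >= min_size:
            mat.loc[a, a] = 1.0
        for b in labels[i + 1:]:
            if len(groups[a]) < min_size or len(groups[b]) < min_size:
                continue
            res = stats.mannwhitneyu(groups[a], groups[b],
                                     alternative="two-sided",
                                     method="asymptotic", use_continuity=False)
            mat.loc[a, b] = mat.loc[b, a] = float(res.pvalue)
    return mat


# ---------------------------------------------------------------------------
# K-means peak sets
# ---------------------------------------------------------------------------

def _farthest_point_seeds(X: np.ndarray, k: int) -> np.ndarray:
    """Deterministic greedy farthest-point seeding (ties by lowest index)."""
    center = X.mean(axis=0)
    d = np.linalg.norm(X - center, axis=1)
    chosen = [int(np.argmax(d))]
    mind = np.linalg.norm(X - X[chosen[0]], axis=1)
    while len(chosen) < k:
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, np.linalg.norm(X - X[nxt], axis=1))
    return X[chosen]


def _match_centroids_to_patterns(centroids: np.ndarray, sd: np.ndarray,
                                 dead_zone_sd: float = 0.25) -> dict[int, int]:
    """Map centroid index -> peak-set number 1..5 by centroid sign pattern.

    ``centroids`` are in raw log2-delta units; a coordinate within
    ``dead_zone_sd`` standard deviations of zero counts as "unchanged".
    The two (me2 down, me3 down) patterns are told apart by |delta_me2|
    (set 3 = smaller loss).  If the sign classes do not form a bijection the
    assignment falls back to Hungarian matching against prototype vectors.
    """
    scale = max(np.abs(centroids).max(), 1e-12)
    zone = dead_zone_sd * np.maximum(sd, 1e-12)

    def sign(v: float, dim: int) -> int:
        if v > zone[dim]:
            return 1
        if v < -zone[dim]:
            return -1
        return 0

    assignment: dict[int, int] = {}
    down_down: list[int] = []
    for i, (d2, d3) in enumerate(centroids):
        s2, s3 = sign(d2, 0), sign(d3, 1)
        if s3 == -1 and s2 == 1:
            assignment[i] = 1
        elif s3 == -1 and s2 == 0:
            assignment[i] = 2
        elif s3 == -1 and s2 == -1:
            down_down.append(i)
        elif s3 == 0 and s2 == -1:
            assignment[i] = 5
    down_down.sort(key=lambda i: abs(centroids[i, 0]))
    for i, set_no in zip(down_down, (3, 4)):
        assignment[i] = set_no
    if (len(assignment) == len(centroids)
            and sorted(assignment.values()) == list(range(1, len(centroids) + 1))):
        return assignment
    prototypes = scale * np.array([
        [0.4, -1.0],    # set 1
        [0.0, -1.0],    # set 2
        [-0.4, -1.0],   # set 3
        [-1.0, -1.0],   # set 4
        [-1.0, 0.0],    # set 5
    ])
    cost = np.linalg.norm(centroids[:, None, :] - prototypes[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    return {int(r): int(c) + 1 for r, c in zip(rows, cols)}


def kmeans_peak_sets(deltas: pd.DataFrame, config: PipelineConfig
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition differential peaks into k sets on (delta_me2, delta_me3).

    ``deltas`` needs columns delta_me2/delta_me3 (log2 depth-normalized
    density changes, 0 where a mark has no signal).  Columns are
    standardized before clustering.  Returns (peaks with set_index and
    set_label, centroid table in standardized units).
    """
    k = config.kmeans_k
    if len(deltas) < k:
        raise ValidationError(f"need at least {k} peaks to form {k} sets")
    X = deltas[["delta_me2", "delta_me3"]].to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    seeds = _farthest_point_seeds(Z, k)
    km = KMeans(n_clusters=k, init=seeds, n_init=1, max_iter=300,
                random_state=config.seed % (2 ** 31))
    raw_labels = km.fit_predict(Z)
    raw_centroids = km.cluster_centers_ * sd + mu  # back to log2-delta units
    mapping = _match_centroids_to_patterns(raw_centroids, sd)
    out = deltas.reset_index(drop=True).copy()
    out["set_index"] = [mapping[int(l)] for l in raw_labels]
    out["set_label"] = out["set_index"].map(PEAK_SET_LABELS)
    cent = pd.DataFrame(raw_centroids, columns=["delta_me2", "delta_me3"])
    cent["set_index"] = [mapping[i] for i in range(k)]
    cent = cent.sort_values("set_index").reset_index(drop=True)
    return out, cent


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    set_id: str
    deg_direction: str
    in_set_deg: int
    in_set_not_deg: int
    deg_not_set: int
    neither: int
    odds_ratio: float
    p_value: float


def fisher_peakset_deg_enrichment(set_genes: set, deg_genes: set,
                                  universe: set, set_id: str = "",
                                  deg_direction: str = "") -> EnrichmentResult:
    """Two-sided Fisher exact test of a peak set against a DEG list.

    Odds ratio uses the Haldane correction (0.5 added to every cell) when
    any cell is zero.
    """
    if not universe:
        raise ValidationError("empty gene universe")
    if not set_genes <= universe or not deg_genes <= universe:
        raise ValidationError("set and DEG genes must be subsets of the universe")
    a = len(set_genes & deg_genes)
    b = len(set_genes - deg_genes)
    c = len(deg_genes - set_genes)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(set_id=set_id, deg_direction=deg_direction,
                            in_set_deg=a, in_set_not_deg=b, deg_not_set=c,
                            neither=d, odds_ratio=float(odds), p_value=float(p))
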