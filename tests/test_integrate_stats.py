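"""Correlation, KS, rank-sum, K-means peak sets and Fisher enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epimarks import (PipelineConfig, fisher_peakset_deg_enrichment,
                      kmeans_peak_sets, ks_profile_compare,
                      spearman_mark_vs_expression,
                      wilcoxon_cluster_expression)
from epimarks.io_formats import ValidationError


def frames(levels, fpkm):
    ids = [f"g{i}" for i in range(len(levels))]
    return (pd.DataFrame({"gene_id": ids, "level": levels}),
            pd.DataFrame({"gene_id": ids, "mean_fpkm_wt": fpkm}))


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def test_perfect_monotone_gives_rho_one():
    lv, rec = frames(np.arange(12.0), np.exp(np.arange(12.0)))
    res = spearman_mark_vs_expression(lv, rec)
    assert res.rho == pytest.approx(1.0)


def test_hand_computed_rho_minus_half():
    # levels (3,1,2) against fpkm ranks (1,2,3): rank-transform then Pearson
    # gives -0.5; padded with a strictly concordant tail to reach n >= 10
    levels = [3.0, 1.0, 2.0]
    fpkm = [0.1, 0.2, 0.3]
    rho_small = stats.spearmanr(levels, fpkm).statistic
    assert rho_small == pytest.approx(-0.5)
    lv, rec = frames(levels + list(np.arange(10, 17.0)),
                     fpkm + list(np.arange(1, 8.0)))
    res = spearman_mark_vs_expression(lv, rec)
    expect = stats.spearmanr(lv["level"], rec["mean_fpkm_wt"]).statistic
    assert res.rho == pytest.approx(expect)


def test_spearman_invariant_under_monotone_transform():
    rng = np.random.default_rng(0)
    levels = rng.normal(size=60)
    fpkm = rng.lognormal(size=60)
    lv, rec = frames(levels, fpkm)
    base = spearman_mark_vs_expression(lv, rec).rho
    lv2, rec2 = frames(np.exp(levels / 3), fpkm ** 2)
    assert spearman_mark_vs_expression(lv2, rec2).rho == pytest.approx(base)


def test_spearman_input_validation():
    lv, rec = frames(np.arange(5.0), np.arange(5.0))
    with pytest.raises(ValidationError, match=">= 10"):
        spearman_mark_vs_expression(lv, rec)
    lv, rec = frames(np.ones(12), np.arange(12.0))
    with pytest.raises(ValidationError, match="constant"):
        spearman_mark_vs_expression(lv, rec)


def test_rank_binned_mode_bins_means():
    rng = np.random.default_rng(1)
    fpkm = rng.lognormal(size=100)
    levels = 5.0 - 2.0 * stats.rankdata(fpkm) / 100 + rng.normal(0, 0.01, 100)
    lv, rec = frames(levels, fpkm)
    res = spearman_mark_vs_expression(lv, rec, mode="rank_binned", n_bins=10)
    assert res.n_bins == 10
    assert res.rho == pytest.approx(-1.0)


# ---------------------------------------------------------------------------
# KS
# ---------------------------------------------------------------------------

def test_ks_identical_and_disjoint_profiles():
    a = np.arange(40.0)
    assert ks_profile_compare(a, a) == (0.0, 1.0)
    d, _ = ks_profile_compare(np.zeros(20), np.ones(20) * 5)
    assert d == pytest.approx(1.0)
    with pytest.raises(ValidationError):
        ks_profile_compare(np.zeros(10), np.zeros(11))


def test_ks_statistic_matches_sup_difference_oracle():
    rng = np.random.default_rng(2)
    a = rng.normal(size=400)
    b = rng.normal(0.3, 1.2, size=400)
    d, _ = ks_profile_compare(a, b)
    grid = np.concatenate([a, b])
    sup = max(abs((a <= t).mean() - (b <= t).mean()) for t in grid)
    assert d == pytest.approx(sup, abs=1e-12)


# ---------------------------------------------------------------------------
# rank-sum between clusters
# ---------------------------------------------------------------------------

def records_with_clusters(groups):
    rows, cluster_of = [], {}
    i = 0
    for label, values in groups.items():
        for v in values:
            gid = f"g{i}"
            rows.append((gid, v))
            cluster_of[gid] = label
            i += 1
    return pd.DataFrame(rows, columns=["gene_id", "mean_fpkm_wt"]), cluster_of


def test_wilcoxon_diagonal_is_one_and_small_cluster_skipped():
    rec, cl = records_with_clusters({"a": [1, 2, 3, 4], "b": [2, 3, 4, 5],
                                     "c": [9, 9]})
    mat = wilcoxon_cluster_expression(cl, rec)
    assert mat.loc["a", "a"] == 1.0
    assert np.isnan(mat.loc["a", "c"])
    assert mat.loc["a", "b"] == mat.loc["b", "a"]


def test_rank_sum_statistic_matches_exact_enumeration():
    """For {1,2,3} vs {100,200,300} the U statistic is 0 and the exact
    two-sided enumeration p over all C(6,3) labelings is 2/20."""
    x, y = [1.0, 2.0, 3.0], [100.0, 200.0, 300.0]
    u = sum(1 for a in x for b in y if a > b) \
        + 0.5 * sum(1 for a in x for b in y if a == b)
    assert u == 0.0
    pooled = x + y
    count_as_extreme = 0
    for comb in itertools.combinations(range(6), 3):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(6) if i not in comb]
        u_c = sum(1 for a in xs for b in ys if a > b)
        if min(u_c, 9 - u_c) <= min(u, 9 - u):
            count_as_extreme += 1
    p_exact = count_as_extreme / 20
    assert p_exact == pytest.approx(2 / 20)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    assert res.pvalue == pytest.approx(p_exact)
    # the pipeline's asymptotic mid-rank value for the same contrast
    rec, cl = records_with_clusters({"a": x, "b": y})
    mat = wilcoxon_cluster_expression(cl, rec)
    z = (u - 4.5) / math.sqrt(3 * 3 * 7 / 12.0)
    assert mat.loc["a", "b"] == pytest.approx(2 * stats.norm.sf(abs(z)))


def test_rank_sum_p_decreases_with_planted_shift():
    rng = np.random.default_rng(3)
    base = rng.normal(10, 1, 40)
    pvals = []
    for shift in (0.2, 0.6, 1.2):
        rec, cl = records_with_clusters({"a": base, "b": base + shift})
        pvals.append(wilcoxon_cluster_expression(cl, rec).loc["a", "b"])
    assert pvals[0] > pvals[1] > pvals[2]


# ---------------------------------------------------------------------------
# K-means peak sets
# ---------------------------------------------------------------------------

def cloud(center, n, rng, sd=0.05):
    return np.column_stack([rng.normal(center[0], sd, n),
                            rng.normal(center[1], sd, n)])


def test_kmeans_recovers_separated_pattern_clouds():
    rng = np.random.default_rng(5)
    centers = {1: (0.8, -2.0), 2: (0.0, -2.0), 3: (-0.8, -2.0),
               4: (-2.2, -2.0), 5: (-2.2, 0.0)}
    pts, truth = [], []
    for s, c in centers.items():
        pts.append(cloud(c, 40, rng))
        truth += [s] * 40
    deltas = pd.DataFrame(np.vstack(pts), columns=["delta_me2", "delta_me3"])
    out, cents = kmeans_peak_sets(deltas, PipelineConfig())
    assert (out["set_index"].to_numpy() == np.array(truth)).all()
    assert sorted(cents["set_index"]) == [1, 2, 3, 4, 5]


def test_kmeans_invariant_to_point_duplication():
    rng = np.random.default_rng(6)
    centers = [(0.8, -2.0), (0.0, -2.0), (-0.8, -2.0), (-2.2, -2.0),
               (-2.2, 0.0)]
    pts = np.vstack([cloud(c, 25, rng) for c in centers])
    deltas = pd.DataFrame(pts, columns=["delta_me2", "delta_me3"])
    doubled = pd.concat([deltas, deltas], ignore_index=True)
    _, c1 = kmeans_peak_sets(deltas, PipelineConfig())
    _, c2 = kmeans_peak_sets(doubled, PipelineConfig())
    assert np.allclose(c1[["delta_me2", "delta_me3"]],
                       c2[["delta_me2", "delta_me3"]], atol=1e-9)


def test_kmeans_requires_at_least_k_peaks():
    deltas = pd.DataFrame({"delta_me2": [0.0, 1.0], "delta_me3": [0.0, 1.0]})
    with pytest.raises(ValidationError):
        kmeans_peak_sets(deltas, PipelineConfig())


def test_kmeans_is_deterministic_across_runs():
    rng = np.random.default_rng(7)
    deltas = pd.DataFrame(rng.normal(size=(200, 2)),
                          columns=["delta_me2", "delta_me3"])
    a, _ = kmeans_peak_sets(deltas, PipelineConfig())
    b, _ = kmeans_peak_sets(deltas, PipelineConfig())
    assert (a["set_index"] == b["set_index"]).all()


# ---------------------------------------------------------------------------
# Fisher
# ---------------------------------------------------------------------------

def fisher_two_sided_oracle(a, b, c, d):
    """Exact two-sided p by enumerating all tables with fixed margins."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def table_prob(x):
        return (math.comb(row1, x) * math.comb(n - row1, col1 - x)
                / math.comb(n, col1))

    p_obs = table_prob(a)
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    return sum(table_prob(x) for x in range(lo, hi + 1)
               if table_prob(x) <= p_obs * (1 + 1e-7))


def test_fisher_closed_form_34_over_70():
    universe = {f"g{i}" for i in range(8)}
    set_genes = {"g0", "g1", "g2", "g3"}       # a=3, b=1
    deg_genes = {"g0", "g1", "g2", "g4"}       # c=1, d=3
    res = fisher_peakset_deg_enrichment(set_genes, deg_genes, universe)
    assert abs(res.p_value - 34 / 70) < 1e-12
    assert (res.in_set_deg, res.in_set_not_deg,
            res.deg_not_set, res.neither) == (3, 1, 1, 3)


def test_fisher_matches_hypergeometric_enumeration_on_random_tables():
    rng = np.random.default_rng(9)
    for _ in range(100):
        a, b, c, d = (int(x) for x in rng.integers(0, 26, 4))
        if a + b + c + d == 0:
            continue
        p_scipy = stats.fisher_exact([[a, b], [c, d]]).pvalue
        assert abs(p_scipy - fisher_two_sided_oracle(a, b, c, d)) < 1e-12


def test_fisher_symmetric_under_transposition():
    rng = np.random.default_rng(10)
    for _ in range(20):
        a, b, c, d = (int(x) for x in rng.integers(0, 30, 4))
        p1 = stats.fisher_exact([[a, b], [c, d]]).pvalue
        p2 = stats.fisher_exact([[a, c], [b, d]]).pvalue
        assert p1 == pytest.approx(p2, abs=1e-12)


def test_disjoint_set_and_deg_depleted():
    universe = {f"g{i}" for i in range(20)}
    set_genes = {f"g{i}" for i in range(5)}
    deg_genes = {f"g{i}" for i in range(5, 10)}
    res = fisher_peakset_deg_enrichment(set_genes, deg_genes, universe)
    assert res.odds_ratio < 1.0
    with pytest.raises(ValidationError, match="empty"):
        fisher_peakset_deg_enrichment(set(), set(), set())
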