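"""SICER-style island calling, significance filtering and genotype contrasts.

The genome is tiled with non-overlapping windows of ``window_W`` bp; each
window's read count (reads assigned by midpoint) is scored against a uniform
Poisson background with mean ``window_W * chip_total / effective_genome_len``
where the effective genome length is an ``effective_fraction`` of the total.
Windows with upper-tail probability below an eligibility cutoff (default
0.2) are eligible; maximal runs of eligible windows separated by at most
``gap_G`` bp of ineligible span form islands, scored by the sum of
-ln(poisson_p) over their eligible members.

Islands are then tested against the input library (Poisson upper tail of the
ChIP count with depth-scaled input mean), BH-adjusted per mark, and kept as
significant when FDR < island_fdr_sig and IP/input fold >= island_fold_sig.
Two-genotype differential islands are evaluated on the union of the
per-genotype island calls with an exact binomial test of the two counts
conditioned on their sum, BH-adjusted, and thresholded at diff_fdr/diff_fold
in either direction.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import PipelineConfig, ReadSet, ValidationError

WINDOW_COLUMNS = ["chrom", "index", "start", "end", "chip_count",
                  "poisson_p", "eligible"]


def _midpoint_window_counts(readset: ReadSet, chrom: str, n_windows: int,
                            window_W: int) -> np.ndarray:
    starts, ends = readset.chrom_arrays(chrom)
    if len(starts) == 0:
        return np.zeros(n_windows, dtype=np.int64)
    mid = (starts + ends) // 2
    idx = np.clip(mid // window_W, 0, n_windows - 1)
    return np.bincount(idx, minlength=n_windows)


def score_windows(chip: ReadSet, input_rs: ReadSet | None,
                  chrom_sizes: dict[str, int],
                  config: PipelineConfig) -> pd.DataFrame:
    """Tile each chromosome into windows and score ChIP counts vs background.

    Returns one row per window with its Poisson upper-tail probability and
    eligibility flag.  ``input_rs`` is accepted for interface symmetry but
    window eligibility is judged against the uniform background model only;
    the input library enters at the island-testing stage.
    """
    W = config.window_W
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValidationError(f"zero-length chromosome {chrom!r}")
    for chrom in chip.reads["chrom"].unique():
        if chrom not in chrom_sizes:
            raise ValidationError(f"reads on {chrom!r} not covered by chrom sizes")
    total = chip.total_reads
    effective_len = config.effective_fraction * sum(chrom_sizes.values())
    lam = W * total / effective_len if effective_len > 0 else 0.0
    frames = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        n_windows = int(np.ceil(size / W))
        counts = _midpoint_window_counts(chip, chrom, n_windows, W)
        # upper tail P(X >= count); count 0 gives p = 1
        pvals = stats.poisson.sf(counts - 1, lam) if lam > 0 else np.ones(n_windows)
        pvals = np.clip(pvals, np.nextafter(0, 1), 1.0)
        starts = np.arange(n_windows, dtype=np.int64) * W
        ends = np.minimum(starts + W, size)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "index": np.arange(n_windows),
            "start": starts,
            "end": ends,
            "chip_count": counts,
            "poisson_p": pvals,
            "eligible": pvals < config.eligibility_p0,
        }))
    return pd.concat(frames, ignore_index=True)


def aggregate_islands(scores: pd.DataFrame, config: PipelineConfig,
                      gap_G: int) -> pd.DataFrame:
    """Merge eligible windows into maximal gap-tolerant islands.

    Consecutive eligible windows may be separated by at most ``gap_G`` bp of
    ineligible span.  The island score sums -ln(poisson_p) over eligible
    members only; ineligible gap windows contribute nothing.
    """
    rows = []
    for chrom, sub in scores.groupby("chrom", sort=False):
        idx = sub["index"].to_numpy()
        if np.any(np.diff(idx) <= 0):
            raise ValidationError(f"window scores for {chrom} are not sorted")
        elig = sub[sub["eligible"]]
        if elig.empty:
            continue
        e_idx = elig["index"].to_numpy()
        e_start = elig["start"].to_numpy()
        e_end = elig["end"].to_numpy()
        e_score = -np.log(elig["poisson_p"].to_numpy())
        # gap in bp between consecutive eligible windows
        gap_bp = (e_idx[1:] - e_idx[:-1] - 1) * config.window_W
        breaks = np.flatnonzero(gap_bp > gap_G)
        bounds = np.concatenate([[0], breaks + 1, [len(e_idx)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            rows.append((chrom, int(e_start[a]), int(e_end[b - 1]),
                         int(b - a), float(e_score[a:b].sum())))
    return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                       "n_eligible_windows", "score"])


def _interval_midpoint_counts(readset: ReadSet, islands: pd.DataFrame) -> np.ndarray:
    """Reads (by midpoint) inside each island interval."""
    counts = np.zeros(len(islands), dtype=np.int64)
    for chrom, sub in islands.groupby("chrom", sort=False):
        starts, ends = readset.chrom_arrays(chrom)
        if len(starts) == 0:
            continue
        mids = np.sort((starts + ends) // 2)
        lo = np.searchsorted(mids, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(mids, sub["end"].to_numpy(), side="left")
        counts[sub.index.to_numpy()] = hi - lo
    return counts


def test_islands(islands: pd.DataFrame, chip: ReadSet, input_rs: ReadSet,
                 config: PipelineConfig,
                 chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Score islands against the input library and BH-adjust per mark.

    p_value is the Poisson upper tail of the ChIP count with mean equal to
    the depth-scaled input count (pseudocount 1 where the input count is
    zero); fold is the ratio of depth-normalized densities with the same
    pseudocount.  Because island boundaries are chosen at upward-fluctuating
    windows, the background expectation is floored at the uniform window
    model over the island span when ``chrom_sizes`` is given — an island
    must beat both the input library and the random background that defined
    window eligibility, otherwise pure-noise islands re-tested against an
    average input come out anti-conservative.  ``called`` applies the
    discovery FDR, ``significant`` the stricter FDR and fold thresholds.
    """
    out = islands.reset_index(drop=True).copy()
    if out.empty:
        for col in ("chip_count", "input_count", "fold", "p_value", "fdr"):
            out[col] = pd.Series(dtype=float)
        out["called"] = pd.Series(dtype=bool)
        out["significant"] = pd.Series(dtype=bool)
        return out
    chip_n = _interval_midpoint_counts(chip, out)
    input_n = _interval_midpoint_counts(input_rs, out)
    input_pc = np.maximum(input_n, 1)
    scale = chip.total_reads / input_rs.total_reads
    lam = input_pc * scale
    if chrom_sizes is not None:
        effective_len = config.effective_fraction * sum(chrom_sizes.values())
        span = (out["end"] - out["start"]).to_numpy(dtype=float)
        lam = np.maximum(lam, span * chip.total_reads / effective_len)
    pvals = stats.poisson.sf(chip_n - 1, lam)
    pvals = np.clip(pvals, np.nextafter(0, 1), 1.0)
    fold = (chip_n / chip.total_reads) / (input_pc / input_rs.total_reads)
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    out["chip_count"] = chip_n
    out["input_count"] = input_n
    out["fold"] = fold
    out["p_value"] = pvals
    out["fdr"] = fdr
    out["called"] = fdr < config.island_fdr_call
    out["significant"] = (fdr < config.island_fdr_sig) & (fold >= config.island_fold_sig)
    return out


def call_islands(chip: ReadSet, input_rs: ReadSet, chrom_sizes: dict[str, int],
                 config: PipelineConfig, gap_G: int | None = None) -> pd.DataFrame:
    """Full island call for one (mark, genotype): score, aggregate, test."""
    if gap_G is None:
        gap_G = config.gap_G.get(chip.sample_label, config.window_W)
    scores = score_windows(chip, input_rs, chrom_sizes, config)
    islands = aggregate_islands(scores, config, gap_G)
    return test_islands(islands, chip, input_rs, config, chrom_sizes=chrom_sizes)


def union_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Merge two island interval sets into their union of merged intervals."""
    both = pd.concat([a[["chrom", "start", "end"]], b[["chrom", "start", "end"]]],
                     ignore_index=True)
    rows = []
    for chrom, sub in both.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        cur_s, cur_e = None, None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def differential_islands(islands_union: pd.DataFrame, chip_wt: ReadSet,
                         chip_mut: ReadSet, config: PipelineConfig) -> pd.DataFrame:
    """Two-genotype contrast over a region set.

    Counts are depth-normalized to ``norm_depth``; the p-value is the exact
    two-sided binomial comparison of the raw counts conditioned on their sum
    (success probability = wild-type share of the combined depth);
    fold_change is wild type / mutant on normalized counts with pseudocount
    1 raw read.  direction applies the diff_fdr/diff_fold thresholds
    symmetrically: "decreased" marks loss in the mutant, "increased" gain.
    """
    out = islands_union.reset_index(drop=True).copy()
    if out.empty:
        for col in ("count_wt", "count_mut", "norm_wt", "norm_mut",
                    "fold_change", "p_value", "fdr"):
            out[col] = pd.Series(dtype=float)
        out["direction"] = pd.Series(dtype=str)
        return out
    c_wt = _interval_midpoint_counts(chip_wt, out)
    c_mut = _interval_midpoint_counts(chip_mut, out)
    f_wt = config.norm_depth / chip_wt.total_reads
    f_mut = config.norm_depth / chip_mut.total_reads
    norm_wt = c_wt * f_wt
    norm_mut = c_mut * f_mut
    fold = ((c_wt + 1) * f_wt) / ((c_mut + 1) * f_mut)
    p0 = chip_wt.total_reads / (chip_wt.total_reads + chip_mut.total_reads)
    pvals = np.array([
        stats.binomtest(int(k), int(k + m), p0, alternative="two-sided").pvalue
        if (k + m) > 0 else 1.0
        for k, m in zip(c_wt, c_mut)
    ])
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    direction = np.full(len(out), "unchanged", dtype=object)
    sig = fdr < config.diff_fdr
    direction[sig & (fold >= config.diff_fold)] = "decreased"
    direction[sig & (1.0 / fold >= config.diff_fold)] = "increased"
    out["count_wt"] = c_wt
    out["count_mut"] = c_mut
    out["norm_wt"] = norm_wt
    out["norm_mut"] = norm_mut
    out["fold_change"] = fold
    out["p_value"] = pvals
    out["fdr"] = fdr
    out["direction"] = direction
    return out


def islands_to_bed(islands: pd.DataFrame, path) -> None:
    """BED6+ export: name = island id, score = -ln p capped at 1000."""
    score = np.minimum(-np.log(islands["p_value"].to_numpy(dtype=float)), 1000.0) \
        if "p_value" in islands.columns else np.zeros(len(islands))
    with open(path, "w") as fh:
        for i, row in enumerate(islands.itertuples(index=False)):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\tisland_{i}\t"
                     f"{score[i]:.3f}\t.\n")
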