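"""Island caller against exact Poisson arithmetic and a brute-force oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from epimarks import (PipelineConfig, ReadSet, aggregate_islands,
                      call_islands, differential_islands, score_windows,
                      union_intervals)
from epimarks.io_formats import ValidationError
from epimarks.islands import test_islands as evaluate_islands


# ---------------------------------------------------------------------------
# independent oracle (pure python, log-space Poisson, textbook BH)
# ---------------------------------------------------------------------------

def poisson_upper_tail(k, lam):
    """P(X >= k) by direct summation of the upper tail in log space."""
    if k <= 0:
        return 1.0
    term = math.exp(-lam + k * math.log(lam) - math.lgamma(k + 1))
    total = 0.0
    i = k
    while term > total * 1e-18 + 1e-320 and i < k + 100_000:
        total += term
        i += 1
        term *= lam / i
    return min(total, 1.0)


def textbook_bh(pvals):
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adj = [0.0] * n
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * n / rank_from_top)
        adj[i] = running
    return adj


def brute_force_caller(chip_reads, input_reads, chrom_len, config, gap_G):
    """Window scoring, gap aggregation and island testing by explicit scan."""
    W = config.window_W
    n_win = math.ceil(chrom_len / W)
    counts = [0] * n_win
    for s, e in chip_reads:
        idx = min(((s + e) // 2) // W, n_win - 1)
        counts[idx] += 1
    total = len(chip_reads)
    eff = config.effective_fraction * chrom_len
    lam = W * total / eff
    pvals = [poisson_upper_tail(c, lam) for c in counts]
    eligible = [p < config.eligibility_p0 for p in pvals]
    islands = []
    cur = None
    for i in range(n_win):
        if not eligible[i]:
            continue
        if cur is not None and (i - cur["last"] - 1) * W <= gap_G:
            cur["last"] = i
            cur["score"] += -math.log(pvals[i])
            cur["n"] += 1
        else:
            if cur is not None:
                islands.append(cur)
            cur = {"first": i, "last": i, "score": -math.log(pvals[i]), "n": 1}
    if cur is not None:
        islands.append(cur)
    out = []
    for isl in islands:
        start = isl["first"] * W
        end = min((isl["last"] + 1) * W, chrom_len)
        chip_n = sum(1 for s, e in chip_reads if start <= (s + e) // 2 < end)
        input_n = sum(1 for s, e in input_reads if start <= (s + e) // 2 < end)
        pc = max(input_n, 1)
        lam_isl = max(pc * total / len(input_reads),
                      (end - start) * total / eff)
        p = poisson_upper_tail(chip_n, lam_isl)
        fold = (chip_n / total) / (pc / len(input_reads))
        out.append(dict(start=start, end=end, n=isl["n"], score=isl["score"],
                        chip_count=chip_n, input_count=input_n,
                        p_value=p, fold=fold))
    for isl, fdr in zip(out, textbook_bh([i["p_value"] for i in out])):
        isl["fdr"] = fdr
        isl["significant"] = (fdr < config.island_fdr_sig
                              and isl["fold"] >= config.island_fold_sig)
    return out


def random_toy_library(rng, chrom_len, n_reads, clustered=0.3):
    reads = []
    n_clu = int(n_reads * clustered)
    if n_clu:
        lo = int(rng.integers(0, max(1, chrom_len - 2000)))
        hi = min(chrom_len - 51, lo + int(rng.integers(400, 2000)))
        starts = rng.integers(lo, max(lo + 1, hi), n_clu)
        reads += [(int(s), int(s) + 51) for s in starts]
    starts = rng.integers(0, chrom_len - 51, n_reads - n_clu)
    reads += [(int(s), int(s) + 51) for s in starts]
    return reads


def to_readset(reads, label, genotype):
    df = pd.DataFrame(reads, columns=["start", "end"])
    df.insert(0, "chrom", "chr1")
    df["strand"] = [f"s{i}" for i in range(len(df))]  # defeat dedup: keep all
    return ReadSet.from_dataframe(df, label, genotype)


def test_caller_equals_brute_force_on_random_toy_chromosomes():
    """Partition, scores, p-values and BH FDRs match the exhaustive oracle
    on many random small chromosomes."""
    rng = np.random.default_rng(42)
    cfg = PipelineConfig()
    for trial in range(60):
        n_win = int(rng.integers(5, 101))
        chrom_len = n_win * cfg.window_W - int(rng.integers(0, cfg.window_W))
        chip = random_toy_library(rng, chrom_len, int(rng.integers(30, 400)))
        inp = random_toy_library(rng, chrom_len, int(rng.integers(30, 400)),
                                 clustered=0.0)
        gap = int(rng.choice([0, 200, 600]))
        got = call_islands(to_readset(chip, "H3K4me2", "wild_type"),
                           to_readset(inp, "input", "wild_type"),
                           {"chr1": chrom_len}, cfg, gap_G=gap)
        want = brute_force_caller(chip, inp, chrom_len, cfg, gap)
        assert len(got) == len(want)
        for row, w in zip(got.itertuples(), want):
            assert (row.start, row.end) == (w["start"], w["end"])
            assert row.n_eligible_windows == w["n"]
            assert math.isclose(row.score, w["score"], rel_tol=1e-9, abs_tol=1e-9)
            assert (row.chip_count, row.input_count) == (w["chip_count"],
                                                         w["input_count"])
            assert math.isclose(row.p_value, w["p_value"], rel_tol=1e-7,
                                abs_tol=1e-12)
            assert math.isclose(row.fdr, w["fdr"], rel_tol=1e-7, abs_tol=1e-12)
            assert bool(row.significant) == w["significant"]


def test_no_reads_means_no_eligible_windows():
    cfg = PipelineConfig()
    empty = to_readset([], "H3K4me2", "wild_type")
    scores = score_windows(empty, None, {"chr1": 2000}, cfg)
    assert not scores["eligible"].any()


def test_window_at_background_rate_is_ineligible():
    """A window whose count equals the background mean has upper-tail
    probability > 0.3 for any mean >= 1, so it can never be eligible at
    the default 0.2 cutoff."""
    for lam in (1.0, 2.0, 5.0, 20.0):
        k = int(lam)
        assert stats.poisson.sf(k - 1, lam) > 0.3


def test_eligibility_matches_closed_form_poisson():
    rng = np.random.default_rng(0)
    cfg = PipelineConfig()
    chrom_len = 2000
    counts = [0, 0, 9, 9, 0, 0, 0, 9, 0, 0]
    reads = []
    for i, c in enumerate(counts):
        for j in range(c):
            s = i * 200 + 40 + j
            reads.append((s, s + 51))
    rs = to_readset(reads, "H3K4me2", "wild_type")
    scores = score_windows(rs, None, {"chr1": chrom_len}, cfg)
    lam = 200 * len(reads) / (cfg.effective_fraction * chrom_len)
    for row, c in zip(scores.itertuples(), counts):
        assert row.chip_count == c
        expect_p = poisson_upper_tail(c, lam)
        assert math.isclose(row.poisson_p, expect_p, rel_tol=1e-9)
        assert bool(row.eligible) == (expect_p < cfg.eligibility_p0)


def _scores_frame(eligible_flags, W=200):
    n = len(eligible_flags)
    return pd.DataFrame({
        "chrom": "chr1",
        "index": np.arange(n),
        "start": np.arange(n) * W,
        "end": (np.arange(n) + 1) * W,
        "chip_count": np.where(eligible_flags, 10, 0),
        "poisson_p": np.where(eligible_flags, 1e-4, 0.9),
        "eligible": np.asarray(eligible_flags, dtype=bool),
    })


def test_gap_boundary_inclusion():
    cfg = PipelineConfig()
    scores = _scores_frame([True, False, True])
    assert len(aggregate_islands(scores, cfg, gap_G=200)) == 1
    assert len(aggregate_islands(scores, cfg, gap_G=0)) == 2


@settings(derandomize=True, max_examples=80, deadline=None)
@given(st.lists(st.booleans(), min_size=1, max_size=100),
       st.sampled_from([0, 200, 400, 600]))
def test_aggregation_matches_exhaustive_scan(flags, gap):
    cfg = PipelineConfig()
    got = aggregate_islands(_scores_frame(flags), cfg, gap_G=gap)
    # oracle: group eligible indices by allowed ineligible span
    runs = []
    for i, f in enumerate(flags):
        if not f:
            continue
        if runs and (i - runs[-1][-1] - 1) * 200 <= gap:
            runs[-1].append(i)
        else:
            runs.append([i])
    assert len(got) == len(runs)
    for row, run in zip(got.itertuples(), runs):
        assert row.start == run[0] * 200
        assert row.end == (run[-1] + 1) * 200
        assert row.n_eligible_windows == len(run)


def test_unsorted_scores_rejected():
    cfg = PipelineConfig()
    scores = _scores_frame([True, True]).iloc[::-1]
    with pytest.raises(ValidationError, match="not sorted"):
        aggregate_islands(scores, cfg, gap_G=0)


def test_strong_p_but_weak_fold_is_rejected():
    """An island below the fold threshold stays non-significant no matter
    how small its p-value is (IP/input >= 2 rule)."""
    cfg = PipelineConfig()
    islands = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [2000]})
    rng = np.random.default_rng(8)
    chip = to_readset([(100 + i, 151 + i) for i in range(190)]
                      + [(int(s), int(s) + 51)
                         for s in rng.integers(10_000, 99_000, 810)],
                      "H3K4me2", "wild_type")
    inp = to_readset([(100 + i, 151 + i) for i in range(100)]
                     + [(int(s), int(s) + 51)
                        for s in rng.integers(10_000, 99_000, 900)],
                     "input", "wild_type")
    out = evaluate_islands(islands, chip, inp, cfg)
    assert out["fold"].iloc[0] == pytest.approx(1.9)
    assert out["p_value"].iloc[0] < 1e-10
    assert not out["significant"].iloc[0]


def test_bh_matches_hand_ranked_oracle_and_order_invariance():
    rng = np.random.default_rng(1)
    cfg = PipelineConfig()
    islands = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(20) * 5000,
        "end": np.arange(20) * 5000 + 1000,
    })
    chip_reads = []
    for i in range(20):
        n = int(rng.integers(5, 120))
        starts = rng.integers(i * 5000, i * 5000 + 949, n)
        chip_reads += [(int(s), int(s) + 51) for s in starts]
    inp_reads = [(int(s), int(s) + 51)
                 for s in rng.integers(0, 99_000, 2000)]
    chip = to_readset(chip_reads, "H3K4me2", "wild_type")
    inp = to_readset(inp_reads, "input", "wild_type")
    out = evaluate_islands(islands, chip, inp, cfg)
    expect = textbook_bh(list(out["p_value"]))
    assert np.allclose(out["fdr"], expect, rtol=1e-9)
    shuffled = islands.sample(frac=1.0, random_state=3)
    out2 = evaluate_islands(shuffled, chip, inp, cfg).sort_values("start")
    assert np.allclose(out2["fdr"].to_numpy(),
                       out.sort_values("start")["fdr"].to_numpy())


def test_eligibility_is_monotone_in_count():
    """Adding reads to a window never removes its eligibility."""
    cfg = PipelineConfig()
    base = [(400 + i, 451 + i) for i in range(30)]
    extra = base + [(400 + i, 451 + i) for i in range(30, 50)]
    bg = [(int(s), int(s) + 51)
          for s in np.random.default_rng(5).integers(0, 19_949, 200)]
    s1 = score_windows(to_readset(base + bg, "m", "g"), None,
                       {"chr1": 20_000}, cfg)
    s2 = score_windows(to_readset(extra + bg, "m", "g"), None,
                       {"chr1": 20_000}, cfg)
    # the spiked window (index 2) must stay eligible
    w1 = s1[s1["index"] == 2].iloc[0]
    w2 = s2[s2["index"] == 2].iloc[0]
    assert w2.chip_count > w1.chip_count
    assert bool(w1.eligible) and bool(w2.eligible)


def binom_two_sided_oracle(k, n, p):
    """Exact two-sided binomial p by pmf enumeration (min-likelihood rule)."""
    pk = stats.binom.pmf(k, n, p)
    probs = stats.binom.pmf(np.arange(n + 1), n, p)
    return float(probs[probs <= pk * (1 + 1e-7)].sum())


def test_differential_directions_and_exact_binomial():
    cfg = PipelineConfig()
    islands = pd.DataFrame({"chrom": ["chr1", "chr1"],
                            "start": [0, 10_000], "end": [2000, 12_000]})
    # equal-depth libraries: identical counts in one island, 100 vs 50 in
    # the other
    wt_reads = [(100 + i, 151 + i) for i in range(100)] \
        + [(10_100 + i, 10_151 + i) for i in range(100)] \
        + [(50_000 + i, 50_051 + i) for i in range(800)]
    mut_reads = [(100 + i, 151 + i) for i in range(100)] \
        + [(10_100 + i, 10_151 + i) for i in range(50)] \
        + [(50_000 + i, 50_051 + i) for i in range(850)]
    wt = to_readset(wt_reads, "H3K4me2", "wild_type")
    mut = to_readset(mut_reads, "H3K4me2", "mutant")
    out = differential_islands(islands, wt, mut, cfg)
    assert out["direction"].iloc[0] == "unchanged"
    row = out.iloc[1]
    assert row["fold_change"] >= cfg.diff_fold
    assert (row["direction"] == "decreased") == (row["fdr"] < cfg.diff_fdr)
    p0 = wt.total_reads / (wt.total_reads + mut.total_reads)
    assert math.isclose(row["p_value"],
                        binom_two_sided_oracle(100, 150, p0), rel_tol=1e-9)


def test_differential_pvalues_match_conditional_binomial_oracle():
    rng = np.random.default_rng(17)
    cfg = PipelineConfig()
    n_isl = 50
    islands = pd.DataFrame({"chrom": "chr1",
                            "start": np.arange(n_isl) * 4000,
                            "end": np.arange(n_isl) * 4000 + 1500})
    wt_reads, mut_reads = [], []
    for i in range(n_isl):
        for target, store in ((int(rng.integers(0, 60)), wt_reads),
                              (int(rng.integers(0, 60)), mut_reads)):
            starts = rng.integers(i * 4000, i * 4000 + 1449, target)
            store += [(int(s), int(s) + 51) for s in starts]
    wt = to_readset(wt_reads, "H3K4me2", "wild_type")
    mut = to_readset(mut_reads, "H3K4me2", "mutant")
    out = differential_islands(islands, wt, mut, cfg)
    p0 = wt.total_reads / (wt.total_reads + mut.total_reads)
    for row in out.itertuples():
        k, m = int(row.count_wt), int(row.count_mut)
        if k + m == 0:
            assert row.p_value == 1.0
        else:
            assert math.isclose(row.p_value,
                                binom_two_sided_oracle(k, k + m, p0),
                                rel_tol=1e-10, abs_tol=1e-12)


def test_union_intervals_merges_overlaps():
    a = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
    b = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [500, 3000],
                      "end": [1500, 4000]})
    u = union_intervals(a, b)
    assert list(u.itertuples(index=False)) == [
        ("chr1", 0, 1500), ("chr1", 3000, 4000)]
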