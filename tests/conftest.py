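"""Shared fixtures: the default synthetic study and its downstream results.

The default dataset (2,000 genes, seed 1, couplings me1 +0.4 / me2 -0.8 /
me3 +0.8 / K36 +0.8) is generated once per session and reused by every test
that needs genome-scale structure; unit tests build their own tiny inputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from epimarks import (GeneratorParams, PipelineConfig, call_de, call_islands,
                      differential_islands, generate_dataset, kmeans_peak_sets,
                      union_intervals)
from epimarks.io_formats import INPUT_LABEL, MUT, WT
from epimarks.pipeline import _peak_deltas

DIFF_MARKS = ("H3K4me2", "H3K4me3")


@pytest.fixture(scope="session")
def default_params() -> GeneratorParams:
    return GeneratorParams(seed=1)


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def dataset(default_params):
    return generate_dataset(default_params)


@pytest.fixture(scope="session")
def chrom_sizes(default_params):
    return {default_params.chrom: default_params.chrom_len}


@pytest.fixture(scope="session")
def island_calls(dataset, config, chrom_sizes):
    """Full island calls for the two differential marks in both genotypes."""
    calls = {}
    for mark in DIFF_MARKS:
        for genotype in (WT, MUT):
            calls[(mark, genotype)] = call_islands(
                dataset.readsets[(mark, genotype)],
                dataset.readsets[(INPUT_LABEL, genotype)],
                chrom_sizes, config)
    return calls


@pytest.fixture(scope="session")
def diff_calls(dataset, island_calls, config):
    out = {}
    for mark in DIFF_MARKS:
        wt = island_calls[(mark, WT)]
        mut = island_calls[(mark, MUT)]
        union = union_intervals(wt[wt["significant"]], mut[mut["significant"]])
        out[mark] = differential_islands(union, dataset.readsets[(mark, WT)],
                                         dataset.readsets[(mark, MUT)], config)
    return out


@pytest.fixture(scope="session")
def de_records(dataset, config):
    return call_de(dataset.expression_table, config)


@pytest.fixture(scope="session")
def peak_assignment(dataset, diff_calls, config):
    """Differential peaks clustered into the five change-pattern sets,
    with each peak matched back to its planted gene's truth set."""
    peaks = pd.concat(
        [diff_calls[m][diff_calls[m]["direction"] != "unchanged"]
         [["chrom", "start", "end"]] for m in DIFF_MARKS],
        ignore_index=True)
    deltas = _peak_deltas(peaks, dataset.readsets, config)
    assigned, centroids = kmeans_peak_sets(deltas, config)
    truth = dataset.truth.expression.set_index("gene_id")
    starts = np.array([g.start for g in dataset.genes])
    ends = np.array([g.end for g in dataset.genes])
    gids = [g.gene_id for g in dataset.genes]
    truth_set = []
    for row in assigned.itertuples():
        ov = np.minimum(ends, row.end) - np.maximum(starts, row.start)
        j = int(np.argmax(ov))
        truth_set.append(int(truth.loc[gids[j], "set_index"]) if ov[j] > 0 else 0)
    assigned = assigned.copy()
    assigned["truth_set"] = truth_set
    return assigned, centroids


def reciprocal_recovery(planted: pd.DataFrame, called: pd.DataFrame,
                        min_frac: float = 0.5,
                        reciprocal: bool = True) -> float:
    """Fraction of planted intervals matched by a called interval with at
    least ``min_frac`` overlap of the planted span (and of the called span
    when ``reciprocal``)."""
    if planted.empty:
        return 1.0
    cs = called["start"].to_numpy()
    ce = called["end"].to_numpy()
    hit = 0
    for row in planted.itertuples():
        ov = np.minimum(ce, row.end) - np.maximum(cs, row.start)
        ok = ov >= min_frac * (row.end - row.start)
        if reciprocal:
            ok &= ov >= min_frac * (ce - cs)
        if ok.any():
            hit += 1
    return hit / len(planted)
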