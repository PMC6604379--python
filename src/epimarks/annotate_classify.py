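"""Island-to-gene assignment and mark-combination gene clusters.

A gene is enriched for a mark when any significant island of that mark
overlaps its span extended 1 kb upstream of the TSS (strand-aware) by at
least one base.  Genes carrying at least one of H3K4me2/H3K4me3/H3K36me3
are partitioned into seven clusters a-g by which of the three marks they
carry; H3K4me1 enrichment is computed but excluded from clustering because
H3K4me1 marks only a vanishing fraction of genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel

CLUSTER_MARKS = ("H3K4me2", "H3K4me3", "H3K36me3")

# cluster letter by (me2, me3, K36me3) presence triple
_CLUSTER_TABLE = {
    (True, False, False): "a",
    (False, True, False): "b",
    (False, False, True): "c",
    (True, True, False): "d",
    (True, False, True): "e",
    (False, True, True): "f",
    (True, True, True): "g",
    (False, False, False): "none",
}


@dataclass
class GeneMarkState:
    gene_id: str
    enriched: dict
    cluster: str


def _extended_span(gene: GeneModel, upstream: int) -> tuple[int, int]:
    """[TSS - upstream, TTS) on the coding strand, in genomic coordinates."""
    if gene.strand == "+":
        return max(0, gene.start - upstream), gene.end
    return gene.start, gene.end + upstream


def assign_islands_to_genes(islands: pd.DataFrame, genes: Sequence[GeneModel],
                            upstream: int = 1000) -> dict[str, list[int]]:
    """Map gene_id -> row indices of islands overlapping the extended span.

    Overlap is half-open interval intersection of at least 1 bp with
    [TSS - upstream, TTS); callers pass significance-filtered islands.
    """
    by_chrom: dict[str, pd.DataFrame] = {}
    for chrom, sub in islands.groupby("chrom", sort=False):
        by_chrom[chrom] = sub.sort_values("start")
    result: dict[str, list[int]] = {}
    for g in genes:
        lo, hi = _extended_span(g, upstream)
        hits: list[int] = []
        sub = by_chrom.get(g.chrom)
        if sub is not None:
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            # sorted by start: overlap iff start < hi and end > lo
            upper = np.searchsorted(starts, hi, side="left")
            mask = ends[:upper] > lo
            hits = [int(i) for i in sub.index.to_numpy()[:upper][mask]]
        result[g.gene_id] = hits
    return result


def enrichment_flags(islands: pd.DataFrame, genes: Sequence[GeneModel],
                     upstream: int = 1000) -> dict[str, bool]:
    """gene_id -> whether any island overlaps the extended gene span."""
    assignment = assign_islands_to_genes(islands, genes, upstream)
    return {gid: len(hits) > 0 for gid, hits in assignment.items()}


def classify_gene_marks(enrichment: Mapping[str, Mapping[str, bool]],
                        ) -> list[GeneMarkState]:
    """Assign each gene its a-g cluster from the (me2, me3, K36me3) triple.

    ``enrichment`` maps mark name -> {gene_id -> bool}; all maps must cover
    the same gene universe.  Marks outside the clustering triple (H3K4me1)
    are carried through in ``enriched`` but do not affect the cluster.
    """
    universes = [set(m) for m in enrichment.values()]
    if universes and any(u != universes[0] for u in universes[1:]):
        raise ValueError("enrichment maps cover different gene universes")
    gene_ids = sorted(universes[0]) if universes else []
    states = []
    for gid in gene_ids:
        flags = {mark: bool(enrichment[mark].get(gid, False)) for mark in enrichment}
        triple = tuple(flags.get(mark, False) for mark in CLUSTER_MARKS)
        states.append(GeneMarkState(gene_id=gid, enriched=flags,
                                    cluster=_CLUSTER_TABLE[triple]))
    return states


def states_to_frame(states: Sequence[GeneMarkState]) -> pd.DataFrame:
    marks = sorted({m for s in states for m in s.enriched})
    rows = []
    for s in states:
        row = {"gene_id": s.gene_id}
        for m in marks:
            row[f"enriched_{m}"] = s.enriched.get(m, False)
        row["cluster"] = s.cluster
        rows.append(row)
    return pd.DataFrame(rows)


def cluster_sizes(states: Sequence[GeneMarkState]) -> pd.DataFrame:
    counts = pd.Series([s.cluster for s in states]).value_counts()
    order = [c for c in "abcdefg"] + ["none"]
    return pd.DataFrame({
        "cluster": order,
        "n_genes": [int(counts.get(c, 0)) for c in order],
    })
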