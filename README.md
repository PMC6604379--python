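# epimarks

Integrative ChIP-seq/RNA-seq analysis of histone H3 methylation marks and
gene expression, built for the question of how H3K4me1/H3K4me2/H3K4me3 and
H3K36me3 levels relate to transcription — in particular the unusual case of
a mark (H3K4me2, broad gene-body coverage in plants) that correlates
*negatively* with expression, unlike the TSS-peaked H3K4me3 and the
5'-body H3K36me3.

The package is aimed at epigenomics analysts who have mapped-read interval
files (BED) for several ChIP marks plus input controls in two genotypes, a
gene annotation (GFF3/BED), and per-replicate expression tables, and who
want the full integration chain as reusable, tested library code rather
than a one-off script stack:

1. **Metagene profiles** — each gene (TSS to TTS, genes > 500 bp) is split
   into 300 body bins plus 50 bins per 1-kb flank; read counts (fractional
   overlap weighting) are normalized to 10 million reads and calibrated
   against input. The per-gene mark level is
   `level_g = chip_density_g - input_density_g`
   (depth-normalized reads per kb over the gene span).
2. **Island calling** — SICER-style windows (`W = 200`) scored against a
   Poisson background, gap-merged (`G = 200` for H3K4me1/me2, `G = 600`
   for H3K4me3/H3K36me3), tested against input and BH-adjusted; significant
   islands satisfy `FDR < 1e-3` and `IP/input >= 2`.
3. **Gene classification** — genes overlapping significant islands (gene
   plus 1 kb upstream of the TSS, strand-aware) are mark-enriched; the
   (me2, me3, K36me3) triple partitions marked genes into clusters a-g.
4. **Differential expression** — fold > 1.5 on pseudocounted mean FPKM and
   BH-adjusted p < 0.05 from an overdispersed two-group count test;
   expression classes Non/Low/Middle/High at FPKM cuts 1 / 2 / 10.
5. **Differential islands and peak sets** — two-genotype contrasts on the
   union of island calls (exact conditional binomial, `FDR < 1e-4`,
   fold >= 1.5), then K-means (k = 5) on the (Δme2, Δme3) log2 density
   changes to recover the five qualitative change patterns.
6. **Integration** — Spearman ρ between mark level and FPKM on expressed
   genes (FPKM > 1), Kolmogorov-Smirnov comparison of metagene profiles,
   rank-sum contrasts of cluster expression, and Fisher exact enrichment of
   peak-set target genes in up-/down-regulated DEG lists.

A first-class synthetic-data generator plants all of this structure — mark
spatial templates, sign-controlled mark-expression coupling, DEGs,
differential islands in five patterns — with known truth, so every stage is
verifiable end to end. See `docs/methods.md` for the model, parameters and
limitations.

## Worked example

Generate the default synthetic study (2,000 genes on a 20-Mb chromosome,
couplings me1 +0.4, me2 −0.8, me3 +0.8, K36 +0.8, 20% planted DE, seed 1)
and measure the mark-expression relationship:

```python
from epimarks import (GeneratorParams, PipelineConfig, generate_dataset,
                      call_de, expressed_filter, gene_level_table,
                      spearman_mark_vs_expression)
from epimarks.io_formats import INPUT_LABEL, WT

params = GeneratorParams(seed=1)
config = PipelineConfig()
ds = generate_dataset(params)

records = call_de(ds.expression_table, config)
print("DEGs:", (records["de_status"] == "up").sum(), "up,",
      (records["de_status"] == "down").sum(), "down")

expressed = expressed_filter(records)
for mark in ("H3K4me2", "H3K4me3", "H3K36me3"):
    levels = gene_level_table(ds.genes, ds.readsets[(mark, WT)],
                              ds.readsets[(INPUT_LABEL, WT)], config)
    levels = levels[levels["gene_id"].isin(expressed["gene_id"])]
    res = spearman_mark_vs_expression(levels, expressed, mark=mark)
    print(f"{mark}: rho = {res.rho:+.3f} (n = {res.n_genes}, p = {res.p_value:.2g})")
```

Output:

```
DEGs: 197 up, 201 down
H3K4me2: rho = -0.972 (n = 1357, p = 0)
H3K4me3: rho = +0.864 (n = 1357, p = 0)
H3K36me3: rho = +0.966 (n = 1357, p = 0)
```

The DE caller recovers the 400 planted DEGs almost exactly (197 up / 201
down called), and the per-gene Spearman correlations recover the planted
coupling signs: strongly negative for the gene-body mark H3K4me2, strongly
positive for H3K4me3 and H3K36me3, over the 1,357 expressed genes.

The same analysis runs from the shell; `epimarks run-all` executes every
stage in dependency order and writes TSV artifacts plus a `manifest.json`
with the config snapshot, input checksums and per-stage counts:

```sh
epimarks make-dataset --outdir run --seed 1
epimarks run-all --config run.yaml
```

where `run.yaml` holds an `outdir`, a `pipeline:` section (any
`PipelineConfig` field) and either a `generator:` section or an `inputs:`
section pointing at your own annotation, read BEDs, expression table and
chromosome sizes.

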