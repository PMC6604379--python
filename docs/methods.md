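# Methods

## Overview

`epimarks` re-implements, at desk scale, an integrative ChIP-seq/RNA-seq
analysis of four histone H3 methylation marks (H3K4me1, H3K4me2, H3K4me3,
H3K36me3) in two genotypes — a wild type and a mutant with globally reduced
H3K4me2/H3K4me3. The pipeline establishes per-gene mark levels, classifies
genes by mark combinations and expression, detects and partitions
differential methylation peaks, and quantifies the mark-expression
relationship. A synthetic-data generator with planted ground truth stands in
for deposited sequencing data so that every stage is verifiable.

All genomic coordinates are 0-based half-open internally; GFF3's 1-based
closed convention is converted at the parse/serialize boundary only. Mapped
reads are deduplicated on (chrom, start, strand), the single-end
duplicate-removal convention; read length is retained because density
counting weights each read by overlapped bp / read length.

## Metagene binning and the per-gene level statistic

Each gene longer than 500 bp is rescaled to a common 400-bin axis: the
TSS-TTS body is split into 300 equal-width bins (fractional widths allowed)
and each 1-kb flank into 50 bins of 20 bp. A read contributes to every bin
it overlaps, weighted by overlapped bp / read length, so the bin vector
conserves total fractional read mass — the basis of the conservation
property tested against a per-base counting oracle. Counts are scaled
multiplicatively by `norm_depth / library_size` (normalization to 10 million
reads by default) and calibrated against the input control by element-wise
subtraction; negative values are retained. Minus-strand genes are flipped so
bin 0 is always 1 kb upstream of the TSS.

Genes of 500 bp or less are excluded from binned profiles but still receive
the per-gene level statistic and all classifications; the skipped genes are
reported so either summary can be drawn. Flanks running past a chromosome
end are truncated: the bin keeps its index and integrates the bases that
exist. Overlapping genes each count all overlapping reads independently;
no apportioning rule is applied. Fractional-overlap weighting was chosen
over 5'-end assignment because it is deterministic, conserves mass, and a
counting rule is otherwise under-determined.

The per-gene level statistic is `chip_density - input_density`, where each
density is the depth-normalized weighted read count over the TSS-TTS span
per kb. It may be negative.

## Island calling

The genome is tiled with non-overlapping windows of `window_W` = 200 bp.
Reads are assigned to windows by midpoint (a single unambiguous
assignment). Each window's count is scored against a uniform Poisson
background with mean `window_W * chip_total / effective_genome_length`,
where the effective genome length is `effective_fraction` (default 0.74) of
the total — the mappable-genome convention of gap-based broad-mark callers.
Windows with upper-tail probability below `eligibility_p0` = 0.2 are
eligible. Maximal runs of eligible windows separated by at most `gap_G` bp
of ineligible span (200 bp for H3K4me1/me2, 600 bp for H3K4me3/H3K36me3)
form islands, scored by the sum of `-ln p` over eligible members.

Islands are then tested against the input library: the p-value is the
Poisson upper tail of the ChIP count with mean equal to the depth-scaled
input count (pseudocount 1 where the input count is zero), BH-adjusted over
all islands of the mark. Because island boundaries are chosen at
upward-fluctuating windows, re-testing the same counts against an average
input is anti-conservative on pure noise; the background expectation is
therefore floored at the uniform window model over the island span, so an
island must beat both the input and the random background that defined
eligibility. With this floor, a library tested against a second background
library yields no significant islands, while planted enrichment is
unaffected (its density is several-fold above both references).

Two FDR knobs are kept separate, as the method they mirror defines them:
`island_fdr_call` = 1e-2 marks the discovery stage (`called` column),
`island_fdr_sig` = 1e-3 with fold >= 2 the significant-peak filter
(`significant` column). Fold is the ratio of depth-normalized densities
with the same input pseudocount.

Differential islands are evaluated on the union of the per-genotype
significant island calls (the region universe is otherwise unspecified).
Counts in each region are compared between genotypes with the exact
binomial test conditioned on their sum (success probability = wild-type
share of combined depth), BH-adjusted, and thresholded at FDR < 1e-4 and a
1.5-fold normalized change. The thresholds name only the decreased
direction in the source protocol; increases are detected symmetrically and
flagged `increased`.

## Gene annotation and mark clusters

A gene is enriched for a mark when any significant island of that mark
overlaps the gene span extended 1 kb upstream of the TSS — strand-aware,
half-open, minimum overlap 1 bp. Genes carrying at least one of
H3K4me2/H3K4me3/H3K36me3 are partitioned into seven clusters a-g by the
presence triple; H3K4me1 is recorded but excluded from clustering because
it marks a vanishing fraction of genes.

## Expression classes and differential expression

Wild-type mean FPKM assigns one of four classes: Non [0,1), Low [1,2),
Middle [2,10), High [10,inf). The published class intervals are open at the
boundaries; they are resolved as half-open ascending. The "expressed"
filter (FPKM strictly > 1) is kept independent of classing, exactly as the
two rules are printed: FPKM = 1 is class Low but not expressed.

DE calls follow the threshold contract — fold > 1.5 on pseudocounted mean
FPKM and BH-adjusted p < 0.05 — with the p-value from a two-group
overdispersed count comparison: counts are normalized by total-count size
factors, a common negative-binomial dispersion is estimated by the method
of moments (median of `(s^2 - m)/m^2` over informative genes), and a
delta-method z statistic compares log means with variance
`(m + alpha m^2)/(n m^2)` per group. The original study's transcript
quantification stack is deliberately not reproduced: its contract here is
only the threshold rule, and any calibrated test satisfies it; on synthetic
negative-binomial data this test attains ~0.96-0.98 recall at planted
fold >= 2 (n = 3 replicates) with observed FDR around 0.02.

## Integrative statistics

*Correlation.* Spearman's rank correlation (mid-rank ties, large-sample t
approximation) between per-gene mark level and mean FPKM over expressed
genes. Both a per-gene mode (default; this is what the level statistic
defines) and an expression-rank-binned mode (equal-count bins, bin means
correlated) are provided, because published scatter constructions of this
kind are sometimes binned; neither mode is asserted to reproduce any
particular printed magnitude.

*Profile comparison.* Two-sample Kolmogorov-Smirnov test on the 400-bin
mean vectors of two metagene profiles.

*Cluster expression.* Two-sided rank-sum test (mid-rank ties, asymptotic,
no continuity correction) on mean FPKM between every pair of gene clusters;
clusters under 3 genes are skipped.

*Peak sets.* Differential peaks are clustered by K-means (k = 5) on
standardized (delta_me2, delta_me3), the log2 depth-normalized density
changes with pseudocount 1 read. Initialization is deterministic greedy
farthest-point seeding, so a fixed seed reproduces assignments exactly.
Centroids are mapped to the five qualitative change patterns (1: me2 up /
me3 down, 2: me2 stable / me3 down, 3: me2 slightly down / me3 down,
4: both down, 5: me2 down / me3 stable) on the de-standardized centroids: a
coordinate within 0.25 standard deviations of zero counts as stable, and
the two (down, down) centroids are told apart by |delta_me2| (the smaller
loss is set 3). If the sign classes fail to form a bijection the mapping
falls back to Hungarian matching against prototype vectors.

*Enrichment.* Peak-set target genes (island-to-gene rule above) are tested
against up- and down-regulated DEG lists with the two-sided Fisher exact
test on the 2x2 table over the annotated gene universe; the odds ratio uses
the Haldane correction when any cell is zero. All multiple-testing
adjustment anywhere in the pipeline is Benjamini-Hochberg.

## The synthetic study

The generator emulates the statistical structure of the two-genotype study
on one 20-Mb chromosome with 2,000 non-overlapping genes of 600-3,000 bp,
mixed strands. Depths are scaled to the toy genome: 1 million ChIP reads
(0.05 reads/bp, the density of a typical broad-mark library), 51-bp
single-end reads, 20% uniform background and an input library that is
background only. A nominal RNA library of 20 million mapped reads matches
routine RNA-seq depth; the toy gene catalog is treated as a subsample of
such a library so FPKM values keep their usual scale (latent FPKM is
log-normal, meanlog = ln 2, sdlog = 1.5, spreading genes over all four
expression classes).

Genes are spaced at least 2 kb apart. This is the generator's side of the
planted-island recoverability contract: islands of neighbouring genes must
not merge under the largest gap parameter (600 bp) plus window rounding,
otherwise a planted island cannot be matched by reciprocal overlap even
when it is perfectly detected.

*Spatial templates.* H3K4me3 reads center on a truncated normal around the
TSS (sd 150 bp, span ±300 bp); H3K4me2 covers the gene body uniformly with
a weak TSS bump (15% of reads); H3K36me3 is 5'-biased over the body
(Beta(1.5, 3) position); H3K4me1 is uniform over the body.

*Coupling.* Per-gene signal mass is proportional to
`(1 + c (2r - 1)) * gene_length`, where `r` is the gene's expression rank
percentile and `c` the mark's coupling (defaults me1 +0.4, me2 -0.8,
me3 +0.8, K36 +0.8). Imposing the coupling on ranks rather than raw FPKM
makes the downstream Spearman sign analytically predictable regardless of
the expression distribution's tails; scaling signal with gene length makes
read *density* (the per-gene statistic) track the coupling weight directly.

*Planted DE.* 20% of genes are differentially expressed, exactly half up
and half down, with folds drawn uniformly from [2, 4], planted among genes
with latent FPKM >= 2 — DE detection presupposes detectable expression, and
this keeps the planted truth within the power of a 3-replicate design.
Replicate counts are negative-binomial with dispersion 0.05 (a typical
biological-replicate value).

*Planted differential chromatin.* The mutant scales H3K4me2/H3K4me3 signal
by a global factor 0.85 (the genome-wide decrease) plus per-gene pattern
factors for five planted change patterns, 80 genes each, mirroring the five
peak sets: (me2, me3) factors (1.5, 0.2), (1.0, 0.2), (0.6, 0.2),
(0.2, 0.2), (0.2, 1.0). Patterns are coordinated with the DE labels the way
the biology runs: H3K4me3-loss-only patterns (1, 2) are planted on
down-regulated genes, the H3K4me2-only-loss pattern (5) on up-regulated
genes (taking the least-expressed up genes, whose H3K4me2 signal — coupled
negatively to expression — is strong enough to call), and the mixed
patterns (3, 4) on invariant genes in the 0.40-0.65 expression-rank band
where both marks carry callable wild-type islands.

*Truth bookkeeping.* A planted island is recorded for (mark, genotype,
gene) when the expected signal density over the template span is at least
3x the genome-average read density — i.e. when the generator actually
planted a callable enrichment. A planted differential island is recorded
where a pattern scales a mark to <= 0.5 of wild type on a gene with a
recorded wild-type island. The same seed yields byte-identical output;
every operation draws from its own seeded stream.

*What the generator does not model* — and hence what passing tests do not
show about real data: sequence content and mappability (reads are
intervals), PCR artifacts beyond exact-duplicate removal, overlapping or
nested gene models, multi-exon structure (a gene is its TSS-TTS span),
chromatin-state autocorrelation beyond the mark templates, replicate-level
batch effects, and any coupling between marks other than through
expression rank. Recovery rates measured here characterize the method's
arithmetic and calibration, not its performance on a real genome.

## Problem sizes and determinism

Default verification runs use the 2,000-gene / 20-Mb / 1M-read study; the
end-to-end orchestration test uses an 80-gene / 1.6-Mb / 80k-read version
of the same design. These sizes keep every planted effect comfortably
within detection power while the whole suite completes in well under a
minute of compute. Randomness is confined to the generator and the K-means
seeding, both governed by configured seeds; re-running any stage with the
same configuration reproduces byte-identical tables.

## Known limitations

- The island caller is a faithful re-implementation of the gap-window
  scheme's semantics, not a bit-compatible clone of any released version
  of the original software.
- The background floor in island testing makes the caller conservative
  where the input library is locally depleted below the genome average.
- The DE test's moment-based common dispersion underestimates gene-specific
  dispersion heterogeneity; with strong heterogeneity its FDR control
  degrades (a per-gene shrinkage estimator would be the next step).
- Peak-set labels 3 vs 4 differ only by the magnitude of the H3K4me2 loss;
  the 0.25-SD dead zone and the |delta| ordering make the labeling
  deterministic but the boundary between "slight" and "strong" remains a
  convention.
- TE/non-TE stratification is carried as a flag but no TE caller is
  provided; SAM/BAM input is out of scope (convert to BED first, e.g.
  `bedtools bamtobed`).
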