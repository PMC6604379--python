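"""End-to-end orchestration: synthesize -> bin -> islands -> annotate -> DE
-> integrate, with a manifest of every artifact.

Stages communicate only through files under the output directory, so any
stage can be re-run from the declared artifacts of the previous ones.  All
thresholds come from the PipelineConfig section of the run configuration;
every threshold actually applied is echoed into the run log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate_classify import (classify_gene_marks, cluster_sizes,
                                enrichment_flags, states_to_frame)
from .expression import call_de, expressed_filter, load_expression_table
from .integrate_stats import (fisher_peakset_deg_enrichment, kmeans_peak_sets,
                              ks_profile_compare, spearman_mark_vs_expression,
                              wilcoxon_cluster_expression)
from .io_formats import (INPUT_LABEL, MARKS, MUT, WT, PipelineConfig, ReadSet,
                         ValidationError, read_gene_annotation, read_reads_bed)
from .islands import (call_islands, differential_islands, islands_to_bed,
                      union_intervals, _interval_midpoint_counts)
from .metagene import (average_profile, bin_gene_set, gene_level_table,
                       profiles_to_frame, subtract_input)
from .synthetic_data import GeneratorParams, generate_dataset, write_dataset

log = logging.getLogger("epimarks")

DIFF_MARKS = ("H3K4me2", "H3K4me3")


@dataclass
class RunManifest:
    """Everything needed to audit or reproduce one pipeline run."""

    version: str
    seed: int
    config: dict
    input_checksums: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_run_config(path: str | Path) -> dict:
    """Read and validate a run configuration; raises before any compute."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig.from_dict(raw.get("pipeline", {}))
    out = {
        "outdir": raw.get("outdir", "epimarks_run"),
        "pipeline": cfg,
        "generator": None,
        "inputs": raw.get("inputs"),
    }
    if "generator" in raw and raw["generator"] is not None:
        gen = dict(raw["generator"])
        gen.setdefault("seed", cfg.seed)
        for k in ("gene_len_range", "de_fold_range", "pattern_band", "k36_beta"):
            if k in gen:
                gen[k] = tuple(gen[k])
        if "pattern_sizes" in gen:
            gen["pattern_sizes"] = {int(k): int(v)
                                    for k, v in gen["pattern_sizes"].items()}
        params = GeneratorParams(**gen)
        params.validate()
        out["generator"] = params
    else:
        inputs = out["inputs"] or {}
        for key in ("annotation", "reads", "expression"):
            if key not in inputs:
                raise ValidationError(
                    f"run config without a generator section must provide "
                    f"inputs.{key}")
        if "chrom_sizes" not in inputs:
            raise ValidationError(
                "run config with real-data inputs must provide inputs.chrom_sizes")
    return out


def _read_readsets(reads_paths: dict) -> dict:
    readsets = {}
    for mark, by_geno in reads_paths.items():
        for genotype, path in by_geno.items():
            readsets[(mark, genotype)] = read_reads_bed(path, mark, genotype)
    return readsets


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_synthesize(params: GeneratorParams, outdir: Path) -> dict:
    ds = generate_dataset(params)
    paths = write_dataset(ds, outdir / "data")
    log.info("synthesize: %d genes, %d libraries", len(ds.genes), len(ds.readsets))
    return paths


def stage_bin(annotation: str, reads_paths: dict, config: PipelineConfig,
              chrom_sizes: dict, outdir: Path) -> dict:
    """Input-calibrated bin matrices and whole-set metagene profiles."""
    genes = read_gene_annotation(annotation, dialect="GFF3")
    readsets = _read_readsets(reads_paths)
    bindir = outdir / "bins"
    bindir.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}
    skipped_report = None
    for mark in [m for m in MARKS if (m, WT) in readsets]:
        for genotype in (WT, MUT):
            if (mark, genotype) not in readsets:
                continue
            chip_prof, skipped = bin_gene_set(genes, readsets[(mark, genotype)],
                                              config, chrom_sizes)
            input_prof, _ = bin_gene_set(genes, readsets[(INPUT_LABEL, genotype)],
                                         config, chrom_sizes)
            calibrated = [subtract_input(chip_prof[g], input_prof[g])
                          for g in chip_prof]
            mat = profiles_to_frame(calibrated)
            mpath = bindir / f"bins_{mark}_{genotype}.tsv"
            mat.to_csv(mpath, sep="\t", float_format="%.6g")
            outputs[f"bins_{mark}_{genotype}"] = str(mpath)
            meta = average_profile(calibrated, label=f"{mark}_{genotype}")
            ppath = bindir / f"metagene_{mark}_{genotype}.tsv"
            pd.DataFrame({"bin": np.arange(len(meta.mean_values)),
                          "mean": meta.mean_values}).to_csv(
                ppath, sep="\t", index=False, float_format="%.8g")
            outputs[f"metagene_{mark}_{genotype}"] = str(ppath)
            skipped_report = skipped
            # per-gene level statistic (ChIP minus input density)
            lv = gene_level_table(genes, readsets[(mark, genotype)],
                                  readsets[(INPUT_LABEL, genotype)], config)
            lpath = bindir / f"gene_level_{mark}_{genotype}.tsv"
            lv.to_csv(lpath, sep="\t", index=False, float_format="%.8g")
            outputs[f"gene_level_{mark}_{genotype}"] = str(lpath)
    if skipped_report is not None:
        spath = bindir / "skipped_genes.tsv"
        pd.DataFrame({"gene_id": skipped_report}).to_csv(spath, sep="\t", index=False)
        outputs["skipped_genes"] = str(spath)
        log.info("bin: %d genes skipped (<= 500 bp)", len(skipped_report))
    return outputs


def stage_islands(reads_paths: dict, config: PipelineConfig,
                  chrom_sizes: dict, outdir: Path) -> tuple[dict, dict]:
    readsets = _read_readsets(reads_paths)
    isdir = outdir / "islands"
    isdir.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}
    counts: dict = {}
    for mark in [m for m in MARKS if (m, WT) in readsets]:
        for genotype in (WT, MUT):
            if (mark, genotype) not in readsets:
                continue
            gap = config.gap_G.get(mark, config.window_W)
            log.info("call-islands %s/%s: W=%d G=%d fdr_sig=%g fold_sig=%g",
                     mark, genotype, config.window_W, gap,
                     config.island_fdr_sig, config.island_fold_sig)
            isl = call_islands(readsets[(mark, genotype)],
                               readsets[(INPUT_LABEL, genotype)],
                               chrom_sizes, config, gap_G=gap)
            tsv = isdir / f"islands_{mark}_{genotype}.tsv"
            isl.to_csv(tsv, sep="\t", index=False, float_format="%.8g")
            bed = isdir / f"islands_{mark}_{genotype}.bed"
            islands_to_bed(isl[isl["significant"]], bed)
            outputs[f"islands_{mark}_{genotype}"] = str(tsv)
            outputs[f"islands_bed_{mark}_{genotype}"] = str(bed)
            counts[f"islands_{mark}_{genotype}"] = int(len(isl))
            counts[f"significant_islands_{mark}_{genotype}"] = int(
                isl["significant"].sum())
    return outputs, counts


def stage_diff(reads_paths: dict, islands_paths: dict, config: PipelineConfig,
               outdir: Path) -> tuple[dict, dict]:
    readsets = _read_readsets(reads_paths)
    ddir = outdir / "differential"
    ddir.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}
    counts: dict = {}
    for mark in DIFF_MARKS:
        wt_key, mut_key = f"islands_{mark}_{WT}", f"islands_{mark}_{MUT}"
        if wt_key not in islands_paths or mut_key not in islands_paths:
            continue
        wt = pd.read_csv(islands_paths[wt_key], sep="\t")
        mut = pd.read_csv(islands_paths[mut_key], sep="\t")
        union = union_intervals(wt[wt["significant"]], mut[mut["significant"]])
        log.info("diff-islands %s: %d union regions, fdr=%g fold=%g",
                 mark, len(union), config.diff_fdr, config.diff_fold)
        diff = differential_islands(union, readsets[(mark, WT)],
                                    readsets[(mark, MUT)], config)
        tsv = ddir / f"differential_{mark}.tsv"
        diff.to_csv(tsv, sep="\t", index=False, float_format="%.8g")
        outputs[f"differential_{mark}"] = str(tsv)
        counts[f"differential_decreased_{mark}"] = int(
            (diff["direction"] == "decreased").sum())
        counts[f"differential_increased_{mark}"] = int(
            (diff["direction"] == "increased").sum())
    return outputs, counts


def stage_annotate(annotation: str, islands_paths: dict,
                   config: PipelineConfig, outdir: Path) -> tuple[dict, dict]:
    genes = read_gene_annotation(annotation, dialect="GFF3")
    adir = outdir / "annotate"
    adir.mkdir(parents=True, exist_ok=True)
    enrichment = {}
    for mark in MARKS:
        key = f"islands_{mark}_{WT}"
        if key not in islands_paths:
            continue
        isl = pd.read_csv(islands_paths[key], sep="\t")
        enrichment[mark] = enrichment_flags(isl[isl["significant"]], genes)
    states = classify_gene_marks(enrichment)
    spath = adir / "gene_mark_states.tsv"
    states_to_frame(states).to_csv(spath, sep="\t", index=False)
    sizes = cluster_sizes(states)
    cpath = adir / "cluster_sizes.tsv"
    sizes.to_csv(cpath, sep="\t", index=False)
    counts = {f"cluster_{r.cluster}": int(r.n_genes)
              for r in sizes.itertuples(index=False)}
    return {"gene_mark_states": str(spath), "cluster_sizes": str(cpath)}, counts


def stage_de(expression: str, config: PipelineConfig, outdir: Path
             ) -> tuple[dict, dict]:
    table = load_expression_table(expression)
    log.info("call-de: fold>%g adjusted p<%g (BH)", config.de_fold, config.de_alpha)
    records = call_de(table, config)
    edir = outdir / "expression"
    edir.mkdir(parents=True, exist_ok=True)
    path = edir / "de_records.tsv"
    records.to_csv(path, sep="\t", index=False, float_format="%.8g")
    counts = {
        "degs_up": int((records["de_status"] == "up").sum()),
        "degs_down": int((records["de_status"] == "down").sum()),
    }
    return {"de_records": str(path)}, counts


def _peak_deltas(peaks: pd.DataFrame, readsets: dict,
                 config: PipelineConfig) -> pd.DataFrame:
    """log2 depth-normalized density change per peak for both marks."""
    out = peaks.reset_index(drop=True).copy()
    for mark in DIFF_MARKS:
        wt, mut = readsets[(mark, WT)], readsets[(mark, MUT)]
        c_wt = _interval_midpoint_counts(wt, out)
        c_mut = _interval_midpoint_counts(mut, out)
        f_wt = config.norm_depth / wt.total_reads
        f_mut = config.norm_depth / mut.total_reads
        col = "delta_me2" if mark == "H3K4me2" else "delta_me3"
        out[col] = np.log2((c_mut + 1) * f_mut) - np.log2((c_wt + 1) * f_wt)
    return out


def stage_integrate(annotation: str, reads_paths: dict, bin_outputs: dict,
                    diff_outputs: dict, annotate_outputs: dict,
                    de_outputs: dict, config: PipelineConfig,
                    outdir: Path) -> tuple[dict, dict]:
    genes = read_gene_annotation(annotation, dialect="GFF3")
    readsets = _read_readsets(reads_paths)
    idir = outdir / "integrate"
    idir.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}
    counts: dict = {}
    records = pd.read_csv(de_outputs["de_records"], sep="\t")
    expressed = expressed_filter(records)

    # mark-expression correlations on expressed genes, both modes
    corr_rows = []
    for mark in MARKS:
        key = f"gene_level_{mark}_{WT}"
        if key not in bin_outputs:
            continue
        levels = pd.read_csv(bin_outputs[key], sep="\t")
        levels = levels[levels["gene_id"].isin(expressed["gene_id"])]
        for mode in ("per_gene", "rank_binned"):
            res = spearman_mark_vs_expression(levels, expressed, mark=mark,
                                              mode=mode)
            corr_rows.append((mark, mode, res.n_genes, res.n_bins,
                              res.rho, res.p_value))
    corr = pd.DataFrame(corr_rows, columns=["mark", "mode", "n_genes",
                                            "n_bins", "rho", "p_value"])
    cpath = idir / "correlations.tsv"
    corr.to_csv(cpath, sep="\t", index=False, float_format="%.8g")
    outputs["correlations"] = str(cpath)

    # genotype comparison of metagene profiles (KS on bin means)
    ks_rows = []
    for mark in MARKS:
        kwt, kmut = f"metagene_{mark}_{WT}", f"metagene_{mark}_{MUT}"
        if kwt in bin_outputs and kmut in bin_outputs:
            a = pd.read_csv(bin_outputs[kwt], sep="\t")["mean"].to_numpy()
            b = pd.read_csv(bin_outputs[kmut], sep="\t")["mean"].to_numpy()
            d, p = ks_profile_compare(a, b)
            ks_rows.append((mark, d, p))
    ks = pd.DataFrame(ks_rows, columns=["mark", "ks_D", "p_value"])
    kpath = idir / "ks_genotype.tsv"
    ks.to_csv(kpath, sep="\t", index=False, float_format="%.8g")
    outputs["ks_genotype"] = str(kpath)

    # DEG-stratified metagene profiles per mark and genotype
    status_of = dict(zip(records["gene_id"], records["de_status"]))
    deg_rows = []
    for mark in MARKS:
        for genotype in (WT, MUT):
            key = f"bins_{mark}_{genotype}"
            if key not in bin_outputs:
                continue
            mat = pd.read_csv(bin_outputs[key], sep="\t", index_col="gene_id")
            groups = mat.groupby(mat.index.map(status_of).fillna("invariant"))
            for label, sub in groups:
                mean = sub.to_numpy().mean(axis=0)
                for i, v in enumerate(mean):
                    deg_rows.append((mark, genotype, label, i, v))
    deg_prof = pd.DataFrame(deg_rows, columns=["mark", "genotype", "deg_set",
                                               "bin", "mean"])
    dpath = idir / "metagene_by_deg.tsv"
    deg_prof.to_csv(dpath, sep="\t", index=False, float_format="%.8g")
    outputs["metagene_by_deg"] = str(dpath)

    # cluster expression contrasts
    states = pd.read_csv(annotate_outputs["gene_mark_states"], sep="\t")
    cluster_of = dict(zip(states["gene_id"], states["cluster"]))
    wmat = wilcoxon_cluster_expression(cluster_of, records)
    wpath = idir / "wilcoxon_clusters.tsv"
    wmat.to_csv(wpath, sep="\t", float_format="%.8g")
    outputs["wilcoxon_clusters"] = str(wpath)

    # differential-peak K-means sets and Fisher enrichment against DEGs
    peaks_frames = []
    for mark in DIFF_MARKS:
        key = f"differential_{mark}"
        if key not in diff_outputs:
            continue
        diff = pd.read_csv(diff_outputs[key], sep="\t")
        sig = diff[diff["direction"] != "unchanged"].copy()
        sig["source_mark"] = mark
        peaks_frames.append(sig[["chrom", "start", "end", "source_mark"]])
    enrich_rows = []
    if peaks_frames:
        peaks = pd.concat(peaks_frames, ignore_index=True)
        if len(peaks) >= config.kmeans_k:
            deltas = _peak_deltas(peaks, readsets, config)
            assigned, centroids = kmeans_peak_sets(deltas, config)
            apath = idir / "peak_sets.tsv"
            assigned.to_csv(apath, sep="\t", index=False, float_format="%.8g")
            outputs["peak_sets"] = str(apath)
            ctpath = idir / "peak_set_centroids.tsv"
            centroids.to_csv(ctpath, sep="\t", index=False, float_format="%.8g")
            outputs["peak_set_centroids"] = str(ctpath)
            for s in sorted(assigned["set_index"].unique()):
                counts[f"peaks_set_{s}"] = int((assigned["set_index"] == s).sum())
            universe = set(records["gene_id"])
            up = set(records.loc[records["de_status"] == "up", "gene_id"])
            down = set(records.loc[records["de_status"] == "down", "gene_id"])
            for s in sorted(assigned["set_index"].unique()):
                sub = assigned[assigned["set_index"] == s]
                flags = enrichment_flags(sub, genes)
                set_genes = {g for g, hit in flags.items() if hit} & universe
                for direction, degs in (("up", up), ("down", down)):
                    r = fisher_peakset_deg_enrichment(
                        set_genes, degs, universe,
                        set_id=f"set_{s}", deg_direction=direction)
                    enrich_rows.append((r.set_id, direction, r.in_set_deg,
                                        r.in_set_not_deg, r.deg_not_set,
                                        r.neither, r.odds_ratio, r.p_value))
    enrich = pd.DataFrame(enrich_rows, columns=[
        "set_id", "deg_direction", "in_set_deg", "in_set_not_deg",
        "deg_not_set", "neither", "odds_ratio", "p_value"])
    epath = idir / "peakset_deg_enrichment.tsv"
    enrich.to_csv(epath, sep="\t", index=False, float_format="%.8g")
    outputs["peakset_deg_enrichment"] = str(epath)
    return outputs, counts


# ---------------------------------------------------------------------------
# run-all
# ---------------------------------------------------------------------------

def _reads_paths_from_dataset(paths: dict) -> dict:
    reads: dict = {}
    for key, p in paths.items():
        if key.startswith("reads_"):
            _, mark, genotype = key.split("_", 2)
            reads.setdefault(mark, {})[genotype] = p
    return reads


def run_pipeline(config_path: str | Path) -> RunManifest:
    """Execute all stages in dependency order and return the manifest."""
    rc = load_run_config(config_path)
    config: PipelineConfig = rc["pipeline"]
    outdir = Path(rc["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, seed=config.seed,
                           config={"pipeline": config.to_dict()})
    if rc["generator"] is not None:
        manifest.config["generator"] = dataclasses.asdict(rc["generator"])
        data_paths = stage_synthesize(rc["generator"], outdir)
        annotation = data_paths["annotation"]
        expression = data_paths["expression"]
        reads_paths = _reads_paths_from_dataset(data_paths)
        chrom_sizes = {rc["generator"].chrom: rc["generator"].chrom_len}
        manifest.outputs.update(data_paths)
    else:
        inputs = rc["inputs"]
        annotation = inputs["annotation"]
        expression = inputs["expression"]
        reads_paths = inputs["reads"]
        chrom_sizes = {str(k): int(v) for k, v in inputs["chrom_sizes"].items()}
    for name in ("annotation", "expression"):
        manifest.input_checksums[name] = _sha256(locals()[name])

    bin_outputs = stage_bin(annotation, reads_paths, config, chrom_sizes, outdir)
    manifest.outputs.update(bin_outputs)
    island_outputs, island_counts = stage_islands(reads_paths, config,
                                                  chrom_sizes, outdir)
    manifest.outputs.update(island_outputs)
    manifest.stage_counts.update(island_counts)
    diff_outputs, diff_counts = stage_diff(reads_paths, island_outputs,
                                           config, outdir)
    manifest.outputs.update(diff_outputs)
    manifest.stage_counts.update(diff_counts)
    ann_outputs, ann_counts = stage_annotate(annotation, island_outputs,
                                             config, outdir)
    manifest.outputs.update(ann_outputs)
    manifest.stage_counts.update(ann_counts)
    de_outputs, de_counts = stage_de(expression, config, outdir)
    manifest.outputs.update(de_outputs)
    manifest.stage_counts.update(de_counts)
    int_outputs, int_counts = stage_integrate(
        annotation, reads_paths, bin_outputs, diff_outputs, ann_outputs,
        de_outputs, config, outdir)
    manifest.outputs.update(int_outputs)
    manifest.stage_counts.update(int_counts)
    n_genes = len(read_gene_annotation(annotation, dialect="GFF3"))
    manifest.stage_counts["n_genes"] = n_genes
    manifest.to_json(outdir / "manifest.json")
    return manifest
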