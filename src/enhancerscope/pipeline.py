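"""End-to-end orchestration: demo-bundle generation and the full analysis run.

``make_demo`` writes every input the pipeline consumes (peaks, tracks, gene
annotation, expression table, peptidoform areas, ground-truth sidecar) from
the synthetic generator.  ``run_all`` executes the analysis on any bundle —
synthetic or user-supplied — producing the conventional and H3K4me3-variant
enhancer tables, enhancer-gene links, genome-binned correlation matrices,
the PTM comparison table and a JSON run summary.  All outputs are
deterministic: identical config and seed give byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .calling import (
    NoEnhancersError,
    SECallParams,
    call_h3k4me3_super_enhancers,
    call_super_enhancers,
    compare_enhancer_sets,
    plot_ranked_curve,
)
from .genes import ExpressionTable, assign_adjacent_genes, classify_expression_change
from .intervals import DistalityParams
from .io_formats import (
    read_bed,
    read_bedgraph,
    read_chrom_sizes,
    read_expression_table,
    read_gtf_genes,
    write_bed,
    write_bedgraph,
    write_chrom_sizes,
    write_enhancer_table,
    write_gtf_genes,
)
from .ptm import (
    all_single_marks,
    compare_all_marks,
    peptidoform_relative_abundance,
    read_peptidoform_table,
    volcano_table,
)
from .signal import BinMatrix, bin_genome, correlate_samples, enhancer_correlation
from .simulate import (
    SimConfig,
    simulate_expression,
    simulate_genome,
    simulate_peaks_and_tracks,
    simulate_peptidoform_areas,
)

logger = logging.getLogger("enhancerscope")

__all__ = ["RunConfig", "make_demo", "run_all"]


@dataclass
class RunConfig:
    """File paths and parameters of one full analysis run."""

    outdir: str
    genes_gtf: str
    chrom_sizes: str
    h3k27ac_peaks: str
    h3k27ac_track: str
    h3k4me3_peaks: str | None = None
    h3k4me3_track: str | None = None
    h4k8ac_track: str | None = None
    expression_table: str | None = None
    peptidoform_areas: str | None = None
    stitch_gap: int = 12500
    boundary_min: int = 1500
    center_min: int = 3000
    bin_width: int = 2000
    link_mode: str = "nearest"
    link_window: int = 50_000
    fc_threshold: float = 1.5
    pseudocount: float = 2.0 ** -5
    alpha: float = 0.05
    seed: int = 20190312
    make_plots: bool = True

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def make_demo(outdir: str | Path, seed: int = 20190312, config: SimConfig | None = None) -> RunConfig:
    """Write a complete synthetic input bundle plus its ground-truth sidecar.

    Returns a :class:`RunConfig` pointing at the bundle, ready for
    :func:`run_all`; the config is also saved as ``config.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config if config is not None else SimConfig(seed=seed)
    if config is not None and config.seed != seed:
        cfg = dataclasses.replace(config, seed=seed)
    genome = simulate_genome(cfg)
    sim = simulate_peaks_and_tracks(cfg, genome)
    expr = simulate_expression(cfg, genome, sim.truth)
    areas = simulate_peptidoform_areas(cfg)

    write_chrom_sizes(genome.chrom_sizes, outdir / "chrom.sizes")
    write_gtf_genes(genome.genes, outdir / "genes.gtf")
    write_bed(sim.peaks["H3K27ac"], outdir / "h3k27ac_peaks.bed")
    write_bed(sim.peaks["H3K4me3"], outdir / "h3k4me3_peaks.bed")
    write_bedgraph(sim.tracks["H3K27ac"], outdir / "h3k27ac.bedgraph")
    write_bedgraph(sim.tracks["H4K8ac"], outdir / "h4k8ac.bedgraph")
    write_bedgraph(sim.tracks["H3K4me3"], outdir / "h3k4me3.bedgraph")
    expr.fpkm.to_csv(outdir / "expression.tsv", sep="\t", float_format="%.6f")
    areas.to_csv(outdir / "peptidoform_areas.tsv", sep="\t", index=False, float_format="%.4f")

    truth = {
        "super_regions": [[r.chrom, r.start, r.end, r.name] for r in sim.truth.super_regions],
        "typical_regions": [[r.chrom, r.start, r.end, r.name] for r in sim.truth.typical_regions],
        "k4_super_regions": [[r.chrom, r.start, r.end, r.name] for r in sim.truth.k4_super_regions],
        "k4_on_super": sim.truth.k4_on_super,
        "se_adjacent_genes": sim.truth.se_adjacent_genes,
        "region_signal": sim.truth.region_signal,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")

    run_cfg = RunConfig(
        outdir=str(outdir / "results"),
        genes_gtf=str(outdir / "genes.gtf"),
        chrom_sizes=str(outdir / "chrom.sizes"),
        h3k27ac_peaks=str(outdir / "h3k27ac_peaks.bed"),
        h3k27ac_track=str(outdir / "h3k27ac.bedgraph"),
        h3k4me3_peaks=str(outdir / "h3k4me3_peaks.bed"),
        h3k4me3_track=str(outdir / "h3k4me3.bedgraph"),
        h4k8ac_track=str(outdir / "h4k8ac.bedgraph"),
        expression_table=str(outdir / "expression.tsv"),
        peptidoform_areas=str(outdir / "peptidoform_areas.tsv"),
        seed=seed,
    )
    run_cfg.to_json(outdir / "config.json")
    return run_cfg


def run_all(config: RunConfig) -> dict:
    """Run every analysis stage the supplied inputs allow.

    Stages: (1) conventional super-enhancer call, (2) H3K4me3-enriched
    variant, (3) enhancer-gene linking with expression clusters, (4)
    genome-binned mark correlations, (5) PTM condition comparison.  Stages
    whose inputs are missing are skipped with a warning; a failing stage
    aborts with its name.  Returns the run-summary dict (also written as
    ``run_summary.json``).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "stitch_gap": config.stitch_gap,
            "boundary_min": config.boundary_min,
            "center_min": config.center_min,
            "bin_width": config.bin_width,
            "fc_threshold": config.fc_threshold,
            "pseudocount": config.pseudocount,
            "alpha": config.alpha,
            "link_mode": config.link_mode,
        },
        "stages": {},
    }
    params = SECallParams(
        stitch_gap=config.stitch_gap,
        distality=DistalityParams(config.boundary_min, config.center_min),
    )
    genes = read_gtf_genes(config.genes_gtf)
    chrom_sizes = read_chrom_sizes(config.chrom_sizes)
    k27_peaks = read_bed(config.h3k27ac_peaks)
    k27_track = read_bedgraph(config.h3k27ac_track)

    # stage 1: conventional super-enhancers
    try:
        se_table = call_super_enhancers(k27_peaks, genes, k27_track, params)
    except NoEnhancersError as exc:
        raise RuntimeError(f"stage call-se failed: {exc}") from exc
    write_enhancer_table(se_table, out / "enhancers.tsv")
    if config.make_plots:
        plot_ranked_curve(se_table, str(out / "ranked_curve.png"))
    summary["stages"]["call_se"] = {
        "n_enhancers": len(se_table),
        "n_super": se_table.n_super,
        "n_typical": se_table.n_typical,
        "cutoff_index": se_table.cutoff_index,
        "cutoff_signal": round(float(se_table.signals[se_table.cutoff_index]), 6),
    }
    logger.info("call-se: %d enhancers, %d super", len(se_table), se_table.n_super)

    # stage 2: H3K4me3-enriched variant
    k4_table = None
    if config.h3k4me3_peaks:
        k4_peaks = read_bed(config.h3k4me3_peaks)
        try:
            k4_table = call_h3k4me3_super_enhancers(k4_peaks, genes, k27_track, params)
        except NoEnhancersError as exc:
            raise RuntimeError(f"stage call-k4se failed: {exc}") from exc
        write_enhancer_table(k4_table, out / "k4_enhancers.tsv")
        if config.make_plots:
            plot_ranked_curve(k4_table, str(out / "k4_ranked_curve.png"))
        cmp = compare_enhancer_sets(k4_table, se_table)
        summary["stages"]["call_k4se"] = {
            "n_enhancers": len(k4_table),
            "n_super": k4_table.n_super,
            "n_typical": k4_table.n_typical,
            "cutoff_index": k4_table.cutoff_index,
            "super_overlapping_conventional": cmp.overlapping,
            "super_k4_only": cmp.a_only,
        }
    else:
        logger.warning("no H3K4me3 peaks supplied; skipping call-k4se")
        summary["stages"]["call_k4se"] = None

    # stage 3: enhancer-gene links and expression clusters
    if config.expression_table:
        expr_frame = read_expression_table(config.expression_table)
        conditions = {c: c.rsplit("_", 1)[0] for c in expr_frame.columns}
        expr = ExpressionTable(fpkm=expr_frame, conditions=conditions)
        links = assign_adjacent_genes(
            se_table.super_regions(), genes,
            window=config.link_window, mode=config.link_mode,
        )
        links = classify_expression_change(
            links, expr, fc_threshold=config.fc_threshold, pseudocount=config.pseudocount
        )
        link_frame = pd.DataFrame(
            {
                "chrom": [l.enhancer.chrom for l in links],
                "start": [l.enhancer.start for l in links],
                "end": [l.enhancer.end for l in links],
                "gene_id": [l.gene_id for l in links],
                "distance": [l.distance for l in links],
                "fold_change": [round(l.fold_change, 6) for l in links],
                "cluster": [l.cluster for l in links],
            }
        )
        link_frame.to_csv(out / "gene_links.tsv", sep="\t", index=False)
        counts = link_frame["cluster"].value_counts().to_dict()
        summary["stages"]["link_genes"] = {
            "n_links": len(links),
            "clusters": {k: int(v) for k, v in sorted(counts.items())},
        }
    else:
        logger.warning("no expression table supplied; skipping gene linking")
        summary["stages"]["link_genes"] = None

    # stage 4: genome-binned mark correlation + enhancer-level scatter
    track_paths = {
        "H3K27ac": config.h3k27ac_track,
        "H4K8ac": config.h4k8ac_track,
        "H3K4me3": config.h3k4me3_track,
    }
    tracks = {
        name: read_bedgraph(p) for name, p in track_paths.items() if p
    }
    if len(tracks) >= 2:
        bm = BinMatrix(bins=bin_genome(chrom_sizes, width=config.bin_width))
        for name, track in sorted(tracks.items()):
            bm.add_track(name, track)
        corr = correlate_samples(bm, method="spearman")
        corr.round(6).to_csv(out / "bin_correlation_spearman.tsv", sep="\t")
        stage4 = {"n_bins": len(bm.bins), "marks": sorted(tracks)}
        if "H4K8ac" in tracks:
            r = enhancer_correlation(
                tracks["H3K27ac"], tracks["H4K8ac"], se_table.regions, method="pearson"
            )
            stage4["enhancer_pearson_h3k27ac_h4k8ac"] = round(float(r), 6)
        summary["stages"]["correlate"] = stage4
    else:
        logger.warning("fewer than two tracks supplied; skipping correlation")
        summary["stages"]["correlate"] = None

    # stage 5: PTM comparison
    if config.peptidoform_areas:
        areas = read_peptidoform_table(config.peptidoform_areas)
        percents = peptidoform_relative_abundance(areas)
        marks = all_single_marks(percents)
        sample_cols = [c for c in areas.columns if c not in ("peptide_id", "ptm_combo")]
        group_a = [c for c in sample_cols if c.startswith("normal")]
        group_b = [c for c in sample_cols if c.startswith("tumor")]
        results = compare_all_marks(marks, group_a, group_b, alpha=config.alpha)
        vt = volcano_table(results)
        vt.round(6).to_csv(out / "ptm_comparison.tsv", sep="\t", index=False)
        summary["stages"]["ptm_compare"] = {
            "n_marks": len(results),
            "n_significant": int(vt["significant"].sum()),
            "n_one_condition": int(vt["one_condition"].sum()),
        }
    else:
        logger.warning("no peptidoform areas supplied; skipping PTM comparison")
        summary["stages"]["ptm_compare"] = None

    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
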