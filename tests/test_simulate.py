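"""Synthetic-data generator: determinism, layout invariants, planted effects."""

import statistics

import numpy as np
import pytest
from scipy import stats

from enhancerscope import (
    SimConfig,
    call_super_enhancers,
    classify_expression_change,
    assign_adjacent_genes,
    simulate_expression,
    simulate_genome,
    simulate_peaks_and_tracks,
    simulate_peptidoform_areas,
    peptidoform_relative_abundance,
    compare_all_marks,
)
from enhancerscope.ptm import all_single_marks
from enhancerscope.intervals import tss_positions_by_chrom, nearest_tss_distances


class TestDeterminismAndLayout:
    def test_same_seed_identical_outputs(self, default_cfg):
        g1, g2 = simulate_genome(default_cfg), simulate_genome(default_cfg)
        assert g1.chrom_sizes == g2.chrom_sizes
        assert g1.genes == g2.genes
        s1 = simulate_peaks_and_tracks(default_cfg, g1)
        s2 = simulate_peaks_and_tracks(default_cfg, g2)
        assert s1.peaks["H3K27ac"] == s2.peaks["H3K27ac"]
        assert list(s1.tracks["H3K27ac"].intervals()) == list(s2.tracks["H3K27ac"].intervals())

    def test_different_seeds_differ(self):
        s1 = simulate_peaks_and_tracks(SimConfig(seed=1), simulate_genome(SimConfig(seed=1)))
        s2 = simulate_peaks_and_tracks(SimConfig(seed=2), simulate_genome(SimConfig(seed=2)))
        assert s1.peaks["H3K27ac"] != s2.peaks["H3K27ac"]

    def test_no_genes_gives_empty_annotation(self):
        cfg = SimConfig(seed=0, n_genes=0)
        assert simulate_genome(cfg).genes == []

    def test_gene_minimum_spacing(self, sim_bundle):
        genome, _, _ = sim_bundle
        by_chrom = {}
        for g in genome.genes:
            by_chrom.setdefault(g.chrom, []).append(g.tss)
        for positions in by_chrom.values():
            positions.sort()
            assert min(np.diff(positions)) >= 40_000

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            simulate_genome(SimConfig(seed=0, chrom_length=100_000, n_genes=500))

    def test_planted_clusters_are_distal(self, sim_bundle):
        genome, sim, _ = sim_bundle
        tss = tss_positions_by_chrom(genome.genes)
        for peak in sim.peaks["H3K27ac"]:
            b, c = nearest_tss_distances(peak, tss)
            assert b > 1500 or c > 3000

    def test_expression_tsv_byte_identical(self, tmp_path, default_cfg, sim_bundle):
        genome, sim, _ = sim_bundle
        paths = []
        for name in ("a.tsv", "b.tsv"):
            expr = simulate_expression(default_cfg, genome, sim.truth)
            p = tmp_path / name
            expr.fpkm.to_csv(p, sep="\t", float_format="%.6f")
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


class TestPlantedSignalStructure:
    def test_unit_ratio_gives_nearly_linear_curve(self):
        counts = []
        for seed in range(10):
            cfg = SimConfig(seed=seed, se_signal_ratio=1.0)
            genome = simulate_genome(cfg)
            sim = simulate_peaks_and_tracks(cfg, genome)
            table = call_super_enhancers(
                sim.peaks["H3K27ac"], genome.genes, sim.tracks["H3K27ac"]
            )
            counts.append(table.n_super)
        assert statistics.median(counts) <= 1

    def test_perfect_mark_correlation_gives_proportional_tracks(self):
        cfg = SimConfig(seed=4, mark_correlation=1.0)
        genome = simulate_genome(cfg)
        sim = simulate_peaks_and_tracks(cfg, genome)
        k27 = np.array([v for *_, v in sim.tracks["H3K27ac"].intervals()])
        k8 = np.array([v for *_, v in sim.tracks["H4K8ac"].intervals()])
        ratio = k8 / k27
        assert ratio.std() / ratio.mean() < 1e-9

    def test_zero_k4_overlap_fraction_avoids_planted_supers(self):
        cfg = SimConfig(seed=6, k4_overlap_fraction=0.0)
        genome = simulate_genome(cfg)
        sim = simulate_peaks_and_tracks(cfg, genome)
        supers = sim.truth.super_regions
        for region in sim.truth.k4_super_regions:
            assert not any(
                p.chrom == region.chrom and min(p.end, region.end) > max(p.start, region.start)
                for p in supers
            )


class TestPlantedExpression:
    def test_no_boost_makes_conditions_exchangeable(self):
        low_p = 0
        for seed in range(10):
            cfg = SimConfig(seed=seed, expr_boost_for_se_adjacent=1.0)
            genome = simulate_genome(cfg)
            sim = simulate_peaks_and_tracks(cfg, genome)
            expr = simulate_expression(cfg, genome, sim.truth)
            normal = expr.fpkm[expr.samples("normal")].values.ravel()
            tumor = expr.fpkm[expr.samples("tumor")].values.ravel()
            if stats.ks_2samp(normal, tumor).pvalue <= 0.01:
                low_p += 1
        assert low_p <= 1

    def test_boost_marks_se_adjacent_genes_increased(self):
        hits, total = 0, 0
        for seed in range(5):
            cfg = SimConfig(seed=seed, n_super_clusters=20, expr_boost_for_se_adjacent=4.0)
            genome = simulate_genome(cfg)
            sim = simulate_peaks_and_tracks(cfg, genome)
            expr = simulate_expression(cfg, genome, sim.truth)
            links = assign_adjacent_genes(sim.truth.super_regions, genome.genes)
            labeled = classify_expression_change(links, expr, fc_threshold=1.5)
            boosted = set(sim.truth.se_adjacent_genes)
            for l in labeled:
                if l.gene_id in boosted:
                    total += 1
                    hits += l.cluster == "increased"
        assert hits / total >= 0.9


class TestPlantedPeptidoforms:
    def test_percent_conservation_on_generator_output(self, default_cfg):
        areas = simulate_peptidoform_areas(default_cfg)
        pct = peptidoform_relative_abundance(areas)
        samples = [c for c in pct.columns if c not in ("peptide_id", "ptm_combo")]
        sums = pct.groupby("peptide_id")[samples].sum()
        assert np.allclose(sums.values, 100.0, atol=1e-9)

    def test_null_effect_rejection_rate_near_alpha(self):
        rejected, total = 0, 0
        for seed in range(40):
            cfg = SimConfig(seed=seed, ptm_effects=())
            areas = simulate_peptidoform_areas(cfg)
            pct = peptidoform_relative_abundance(areas)
            marks = all_single_marks(pct)
            results = compare_all_marks(
                marks, ["normal_1", "normal_2", "normal_3"],
                ["tumor_1", "tumor_2", "tumor_3"],
            )
            rejected += sum(r.significant for r in results)
            total += len(results)
        assert 0.01 <= rejected / total <= 0.10

    def test_planted_effects_detected_with_high_power(self):
        detected, total = 0, 0
        planted = ("H3K27ac", "H4K8ac", "H3K4me3", "H3K36me3")
        for seed in range(20):
            cfg = SimConfig(seed=seed)
            areas = simulate_peptidoform_areas(cfg)
            pct = peptidoform_relative_abundance(areas)
            marks = all_single_marks(pct)
            results = {
                r.mark: r
                for r in compare_all_marks(
                    marks, ["normal_1", "normal_2", "normal_3"],
                    ["tumor_1", "tumor_2", "tumor_3"],
                )
            }
            for m in planted:
                total += 1
                detected += results[m].significant
        assert detected / total >= 0.8

    def test_planted_direction_matches_effect_sign(self):
        cfg = SimConfig(seed=12)
        areas = simulate_peptidoform_areas(cfg)
        pct = peptidoform_relative_abundance(areas)
        marks = all_single_marks(pct)
        results = {
            r.mark: r
            for r in compare_all_marks(
                marks, ["normal_1", "normal_2", "normal_3"],
                ["tumor_1", "tumor_2", "tumor_3"],
            )
        }
        assert results["H3K27ac"].fold_change > 1
        assert results["H3K36me3"].fold_change < 1
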