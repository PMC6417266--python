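"""Ranked-signal curve, slope-1 cutoff and the two super-enhancer callers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enhancerscope import (
    NoEnhancersError,
    SECallParams,
    SimConfig,
    StitchedRegion,
    call_h3k4me3_super_enhancers,
    call_super_enhancers,
    compare_enhancer_sets,
    find_inflection,
    rank_and_scale,
    simulate_genome,
    simulate_peaks_and_tracks,
)
from enhancerscope.calling import RankedEnhancerTable


def regions_with_signals(signals, chrom="chr1"):
    return [
        StitchedRegion(chrom=chrom, start=10_000 * i, end=10_000 * i + 1000, signal=float(s))
        for i, s in enumerate(signals)
    ]


def oracle_cutoff(signals):
    """Exhaustive scan for the vertical-gap maximizer on the scaled curve."""
    signals = sorted(signals)
    n = len(signals)
    best_i, best_gap = 0, -np.inf
    for i, s in enumerate(signals):
        gap = i / (n - 1) - s / signals[-1]
        if gap >= best_gap:  # ties -> largest index
            best_i, best_gap = i, gap
    return best_i


class TestRankAndScale:
    def test_sorts_and_scales(self):
        table = rank_and_scale(regions_with_signals([5, 1, 3]))
        assert list(table.signals) == [1.0, 3.0, 5.0]
        assert list(table.scaled_signal) == [0.2, 0.6, 1.0]
        assert list(table.scaled_rank) == [0.0, 0.5, 1.0]

    def test_ties_broken_by_genomic_position(self):
        a = StitchedRegion(chrom="chr2", start=100, end=200, signal=2.0)
        b = StitchedRegion(chrom="chr1", start=500, end=600, signal=2.0)
        c = StitchedRegion(chrom="chr1", start=50, end=80, signal=9.0)
        table = rank_and_scale([a, b, c])
        assert [r.chrom for r in table.regions] == ["chr1", "chr2", "chr1"]

    def test_all_zero_signals_rejected(self):
        with pytest.raises(NoEnhancersError):
            rank_and_scale(regions_with_signals([0, 0, 0]))

    def test_fewer_than_three_regions_rejected(self):
        with pytest.raises(NoEnhancersError):
            rank_and_scale(regions_with_signals([1, 2]))


class TestFindInflection:
    def test_linear_curve_yields_zero_supers(self):
        table = rank_and_scale(regions_with_signals([1, 2, 3, 4, 5]))
        cutoff = find_inflection(table)
        assert cutoff == 4
        assert table.n_super == 0

    def test_single_outlier(self):
        table = rank_and_scale(regions_with_signals([1, 1, 1, 1, 100]))
        assert find_inflection(table) == 3
        assert table.n_super == 1

    def test_geometric_curve_matches_oracle(self):
        signals = [2.0**k for k in range(10)]
        table = rank_and_scale(regions_with_signals(signals))
        assert find_inflection(table) == oracle_cutoff(signals)

    def test_scale_invariance(self):
        signals = [1, 2, 2, 5, 8, 40, 200]
        t1 = rank_and_scale(regions_with_signals(signals))
        t2 = rank_and_scale(regions_with_signals([s * 37.5 for s in signals]))
        assert find_inflection(t1) == find_inflection(t2)
        assert list(t1.is_super) == list(t2.is_super)

    def test_top_region_above_interpolation_gives_super(self):
        # convex bend: top point far above the diagonal's continuation
        table = rank_and_scale(regions_with_signals([1, 2, 3, 4, 50]))
        find_inflection(table)
        assert table.n_super >= 1

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.001, 1e6, allow_nan=False), min_size=3, max_size=1000)
    )
    def test_matches_exhaustive_oracle_on_random_curves(self, signals):
        table = rank_and_scale(regions_with_signals(signals))
        assert find_inflection(table) == oracle_cutoff(signals)
        # label partition: super + typical = all
        assert table.n_super + table.n_typical == len(table)


class TestCallSuperEnhancers:
    def test_recovers_planted_supers(self, default_cfg, sim_bundle):
        genome, sim, _ = sim_bundle
        table = call_super_enhancers(
            sim.peaks["H3K27ac"], genome.genes, sim.tracks["H3K27ac"]
        )
        called = {(r.chrom, r.start, r.end) for r in table.super_regions()}
        planted = {(r.chrom, r.start, r.end) for r in sim.truth.super_regions}
        assert called == planted
        assert len(table) == len(sim.truth.super_regions) + len(sim.truth.typical_regions)

    def test_no_distal_peaks_is_an_error(self, sim_bundle):
        genome, sim, _ = sim_bundle
        from enhancerscope import GenomicInterval

        promoter_peaks = [
            GenomicInterval(g.chrom, g.tss, g.tss + 200) for g in genome.genes[:5]
        ]
        with pytest.raises(NoEnhancersError):
            call_super_enhancers(promoter_peaks, genome.genes, sim.tracks["H3K27ac"])

    def test_subtracting_track_from_itself_is_degenerate(self, sim_bundle):
        genome, sim, _ = sim_bundle
        params = SECallParams(
            control_track=sim.tracks["H3K27ac"], subtract_control=True
        )
        with pytest.raises(NoEnhancersError):
            call_super_enhancers(
                sim.peaks["H3K27ac"], genome.genes, sim.tracks["H3K27ac"], params
            )


class TestCallK4SuperEnhancers:
    def test_supers_contained_in_planted_high_regions(self, sim_bundle):
        genome, sim, _ = sim_bundle
        table = call_h3k4me3_super_enhancers(
            sim.peaks["H3K4me3"], genome.genes, sim.tracks["H3K27ac"]
        )
        planted = {(r.chrom, r.start, r.end) for r in sim.truth.k4_super_regions}
        called = {(r.chrom, r.start, r.end) for r in table.super_regions()}
        assert called <= planted

    def test_promoter_proximal_k4_peaks_error(self, sim_bundle):
        genome, sim, _ = sim_bundle
        from enhancerscope import GenomicInterval

        proximal = [GenomicInterval(g.chrom, g.tss, g.tss + 300) for g in genome.genes[:4]]
        with pytest.raises(NoEnhancersError):
            call_h3k4me3_super_enhancers(proximal, genome.genes, sim.tracks["H3K27ac"])

    def test_zero_k27_signal_over_regions_error(self, sim_bundle):
        from enhancerscope import SignalTrack

        genome, sim, _ = sim_bundle
        # a track on an unrelated chromosome quantifies to zero everywhere
        with pytest.raises(NoEnhancersError):
            call_h3k4me3_super_enhancers(
                sim.peaks["H3K4me3"], genome.genes,
                SignalTrack([("chrZ", 0, 10, 1.0)]),
            )


class TestCompareEnhancerSets:
    def _table(self, spans, n_super):
        regions = [
            StitchedRegion(chrom=c, start=s, end=e, signal=float(sig))
            for (c, s, e), sig in zip(spans, range(1, len(spans) + 1))
        ]
        table = rank_and_scale(regions)
        table.cutoff_index = len(regions) - n_super - 1
        return table

    def test_identical_sets_fully_overlap(self):
        spans = [("chr1", 0, 1000), ("chr1", 5000, 6000), ("chr1", 9000, 9500), ("chr1", 20000, 21000)]
        a = self._table(spans, 2)
        b = self._table(spans, 2)
        cmp = compare_enhancer_sets(a, b)
        assert (cmp.a_only, cmp.b_only, cmp.overlapping) == (0, 0, 2)

    def test_disjoint_chromosomes_never_overlap(self):
        a = self._table([("chr1", 0, 1000), ("chr1", 50_000, 51_000), ("chr1", 99_000, 99_500)], 2)
        b = self._table([("chr2", 0, 1000), ("chr2", 50_000, 51_000), ("chr2", 99_000, 99_500)], 2)
        cmp = compare_enhancer_sets(a, b)
        assert cmp.overlapping == 0 and cmp.a_only == 2 and cmp.b_only == 2

    def test_single_base_overlap_counts_at_min_overlap_one(self):
        a = self._table([("chr1", 0, 100), ("chr1", 300, 400), ("chr1", 500, 600)], 1)
        b = self._table([("chr1", 900, 950), ("chr1", 1200, 1300), ("chr1", 599, 700)], 1)
        # a's super is [500,600); b's super is [599,700): they share one base
        cmp = compare_enhancer_sets(a, b, min_overlap=1)
        assert cmp.overlapping == 1


def test_planted_recovery_is_scale_free(sim_bundle, default_cfg):
    """Super labels depend only on signal ratios, not absolute track depth."""
    genome, sim, _ = sim_bundle
    t1 = call_super_enhancers(sim.peaks["H3K27ac"], genome.genes, sim.tracks["H3K27ac"])
    from enhancerscope import SignalTrack

    scaled = SignalTrack(
        [(c, s, e, v * 12.0) for c, s, e, v in sim.tracks["H3K27ac"].intervals()]
    )
    t2 = call_super_enhancers(sim.peaks["H3K27ac"], genome.genes, scaled)
    assert t1.cutoff_index == t2.cutoff_index
    assert list(t1.is_super) == list(t2.is_super)
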