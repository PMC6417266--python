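"""Super-enhancer calling from ranked region signal.

Candidate enhancer regions (stitched distal peaks) are ranked by total
H3K27ac signal, both axes are scaled to [0, 1], and the cutoff is the point
where a tangent of slope 1 touches the ascending curve — realized as the
maximizer of vertical distance between the curve and the diagonal y = x.
Regions whose signal lies strictly above the cutoff region's signal are
super-enhancers; the rest are typical enhancers.

The H3K4me3-enriched variant builds the candidate regions from distal
H3K4me3 peaks instead, but still ranks them by H3K27ac signal quantified
over those regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .intervals import (
    DistalityParams,
    GeneModel,
    GenomicInterval,
    StitchedRegion,
    filter_distal,
    stitch,
)
from .signal import SignalTrack, quantify

__all__ = [
    "NoEnhancersError",
    "SECallParams",
    "RankedEnhancerTable",
    "EnhancerRow",
    "rank_and_scale",
    "find_inflection",
    "call_super_enhancers",
    "call_h3k4me3_super_enhancers",
    "compare_enhancer_sets",
    "EnhancerSetComparison",
]


class NoEnhancersError(RuntimeError):
    """No candidate enhancers survive filtering, or the signal curve is flat."""


@dataclass(frozen=True)
class SECallParams:
    """Parameters of the end-to-end super-enhancer call."""

    stitch_gap: int = 12500
    distality: DistalityParams = field(default_factory=DistalityParams)
    control_track: SignalTrack | None = None
    subtract_control: bool = False

    def __post_init__(self) -> None:
        if self.stitch_gap <= 0:
            raise ValueError("stitch_gap must be positive")


@dataclass(frozen=True)
class EnhancerRow:
    region: StitchedRegion
    signal: float
    rank: int
    scaled_rank: float
    scaled_signal: float
    is_super: bool


@dataclass
class RankedEnhancerTable:
    """Regions sorted ascending by signal, with scaled curve coordinates.

    ``cutoff_index`` is None until :func:`find_inflection` has run; after
    that, ``is_super`` marks regions with signal strictly above the signal
    at the cutoff.
    """

    regions: list[StitchedRegion]
    signals: np.ndarray
    cutoff_index: int | None = None

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def scaled_rank(self) -> np.ndarray:
        n = len(self.regions)
        if n == 1:
            return np.zeros(1)
        return np.arange(n) / (n - 1)

    @property
    def scaled_signal(self) -> np.ndarray:
        return self.signals / self.signals[-1]

    @property
    def is_super(self) -> np.ndarray:
        if self.cutoff_index is None:
            raise ValueError("cutoff not computed; call find_inflection first")
        return self.signals > self.signals[self.cutoff_index]

    @property
    def n_super(self) -> int:
        return int(self.is_super.sum())

    @property
    def n_typical(self) -> int:
        return len(self) - self.n_super

    def super_regions(self) -> list[StitchedRegion]:
        return [r for r, s in zip(self.regions, self.is_super) if s]

    def typical_regions(self) -> list[StitchedRegion]:
        return [r for r, s in zip(self.regions, self.is_super) if not s]

    def rows(self) -> Iterator[EnhancerRow]:
        if not self.regions:
            return
        sr, ss, sup = self.scaled_rank, self.scaled_signal, self.is_super
        for i, region in enumerate(self.regions):
            yield EnhancerRow(
                region=region,
                signal=float(self.signals[i]),
                rank=i,
                scaled_rank=float(sr[i]),
                scaled_signal=float(ss[i]),
                is_super=bool(sup[i]),
            )


def rank_and_scale(regions: Sequence[StitchedRegion]) -> RankedEnhancerTable:
    """Sort regions ascending by signal and attach scaled curve coordinates.

    Ties are broken by genomic position (chrom, start) for determinism.
    """
    if len(regions) < 3:
        raise NoEnhancersError(f"need >=3 regions to draw a curve, got {len(regions)}")
    for r in regions:
        if r.signal is None:
            raise ValueError("region without quantified signal")
    ordered = sorted(regions, key=lambda r: (r.signal, r.chrom, r.start))
    signals = np.array([r.signal for r in ordered], dtype=np.float64)
    if signals[-1] <= 0:
        raise NoEnhancersError("all region signals are zero; no ranked curve")
    return RankedEnhancerTable(regions=ordered, signals=signals)


def find_inflection(table: RankedEnhancerTable) -> int:
    """Slope-1 tangent cutoff on the scaled ranked-signal curve.

    Computed as the index maximizing ``scaled_rank - scaled_signal`` (the
    vertical distance below the diagonal), which is where the ascending
    curve's tangent reaches slope 1 for a convex curve and is well defined
    for any curve.  Ties take the largest index, so an exactly linear curve
    yields zero super-enhancers.  Sets ``table.cutoff_index`` and returns it.
    """
    if len(table) < 3:
        raise NoEnhancersError("need >=3 regions")
    gap = table.scaled_rank - table.scaled_signal
    # argmax with ties resolved toward the largest index (fewest supers)
    cutoff = len(gap) - 1 - int(np.argmax(gap[::-1]))
    table.cutoff_index = cutoff
    return cutoff


def _quantified_regions(
    regions: Sequence[StitchedRegion],
    track: SignalTrack,
    params: SECallParams,
) -> list[StitchedRegion]:
    if params.subtract_control:
        if params.control_track is None:
            raise ValueError("subtract_control set but no control_track given")
        track = track.subtract(params.control_track)
        if track.total_mass <= 0:
            raise NoEnhancersError("control subtraction removed all signal")
    for region, qs in zip(regions, quantify(track, regions)):
        region.signal = qs.rpm
    return list(regions)


def call_super_enhancers(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    track: SignalTrack,
    params: SECallParams = SECallParams(),
) -> RankedEnhancerTable:
    """Full conventional super-enhancer call from H3K27ac peaks and signal.

    Pipeline: TSS-distality filter → 12.5-kb stitching → RPM quantification
    (optionally control-subtracted) → ranking/scaling → slope-1 cutoff.
    """
    distal = filter_distal(peaks, genes, params.distality)
    if not distal:
        raise NoEnhancersError("no distal peaks survive TSS filtering")
    regions = stitch(distal, gap=params.stitch_gap)
    table = rank_and_scale(_quantified_regions(regions, track, params))
    find_inflection(table)
    return table


def call_h3k4me3_super_enhancers(
    k4_peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    k27_track: SignalTrack,
    params: SECallParams = SECallParams(),
) -> RankedEnhancerTable:
    """H3K4me3-enriched variant: regions from distal H3K4me3 peaks, ranked
    by the H3K27ac signal quantified over those regions."""
    distal = filter_distal(k4_peaks, genes, params.distality)
    if not distal:
        raise NoEnhancersError("no distal H3K4me3 peaks survive TSS filtering")
    regions = stitch(distal, gap=params.stitch_gap)
    table = rank_and_scale(_quantified_regions(regions, k27_track, params))
    find_inflection(table)
    return table


@dataclass(frozen=True)
class EnhancerSetComparison:
    """Overlap report between two super-enhancer sets."""

    a_only: int
    b_only: int
    overlapping: int  # super-enhancers of `a` overlapping any super of `b`
    mean_signal_a_only: float
    mean_signal_b_only: float
    mean_signal_overlapping: float


def _overlap_bp(a: StitchedRegion, b: StitchedRegion) -> int:
    if a.chrom != b.chrom:
        return 0
    return min(a.end, b.end) - max(a.start, b.start)


def compare_enhancer_sets(
    a: RankedEnhancerTable,
    b: RankedEnhancerTable,
    min_overlap: int = 1,
) -> EnhancerSetComparison:
    """Partition the super-enhancers of two calls by mutual overlap.

    A region counts as overlapping when it shares at least ``min_overlap``
    bases with some super-enhancer of the other set.
    """
    sup_a, sup_b = a.super_regions(), b.super_regions()
    a_over = [r for r in sup_a if any(_overlap_bp(r, s) >= min_overlap for s in sup_b)]
    a_only = [r for r in sup_a if r not in a_over]
    b_only = [
        r for r in sup_b if not any(_overlap_bp(r, s) >= min_overlap for s in sup_a)
    ]

    def mean_sig(rs: list[StitchedRegion]) -> float:
        return float(np.mean([r.signal for r in rs])) if rs else float("nan")

    return EnhancerSetComparison(
        a_only=len(a_only),
        b_only=len(b_only),
        overlapping=len(a_over),
        mean_signal_a_only=mean_sig(a_only),
        mean_signal_b_only=mean_sig(b_only),
        mean_signal_overlapping=mean_sig(a_over),
    )


def plot_ranked_curve(table: RankedEnhancerTable, path: str) -> None:
    """Hockey-stick plot of scaled rank vs scaled signal with the cutoff."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(table.scaled_rank, table.scaled_signal, lw=1.5, color="#1f77b4")
    if table.cutoff_index is not None:
        x = table.scaled_rank[table.cutoff_index]
        y = table.scaled_signal[table.cutoff_index]
        ax.axvline(x, ls="--", color="grey", lw=0.8)
        ax.plot([x], [y], "o", color="crimson", ms=5)
        ax.set_title(f"{table.n_super} super / {table.n_typical} typical")
    ax.plot([0, 1], [0, 1], ls=":", color="grey", lw=0.8)
    ax.set_xlabel("enhancers ranked by signal (scaled)")
    ax.set_ylabel("signal (scaled to max)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
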