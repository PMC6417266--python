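"""Genomic intervals, TSS-distality filtering and gap-based peak stitching.

All coordinates are 0-based half-open, the BED convention.  Distal peaks are
peaks far enough from every annotated transcription start site (TSS) that
they plausibly mark enhancers rather than promoters; two alternative
distance rules are supported (boundary gap, or peak-center distance) and a
peak passing either is called distal.  Stitching is single-linkage merging
of same-chromosome peaks whose end-to-start gap is below a threshold
(12.5 kb by default), the standard construction of candidate enhancer
regions from individual acetylation peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "DistalityParams",
    "StitchedRegion",
    "tss_positions_by_chrom",
    "nearest_tss_distances",
    "filter_distal",
    "stitch",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` with optional name/score."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.score is not None and self.score < 0:
            raise ValueError(f"negative score {self.score}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS/TES, 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gene span for {self.gene_id}")

    @property
    def tss(self) -> int:
        """Transcription start site (last base of the span on minus strand)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class DistalityParams:
    """Thresholds for calling a peak distal to all TSSs.

    A peak is distal when its boundary is more than ``boundary_min`` bp from
    every TSS, or its center is more than ``center_min`` bp from every TSS.
    """

    boundary_min: int = 1500
    center_min: int = 3000

    def __post_init__(self) -> None:
        if self.boundary_min <= 0 or self.center_min <= 0:
            raise ValueError("distality thresholds must be positive")


@dataclass
class StitchedRegion:
    """A merged cluster of peaks: hull span plus constituent provenance."""

    chrom: str
    start: int
    end: int
    constituents: list[GenomicInterval] = field(default_factory=list)
    signal: float | None = None

    @property
    def n_constituents(self) -> int:
        return len(self.constituents)

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def tss_positions_by_chrom(genes: Iterable[GeneModel]) -> dict[str, np.ndarray]:
    """Sorted TSS positions per chromosome, strand-ignored."""
    out: dict[str, list[int]] = {}
    for g in genes:
        out.setdefault(g.chrom, []).append(g.tss)
    return {c: np.array(sorted(v), dtype=np.int64) for c, v in out.items()}


def nearest_tss_distances(
    peak: GenomicInterval, tss_positions: Mapping[str, np.ndarray]
) -> tuple[float, float]:
    """Distance from a peak to its nearest TSS, under both distality rules.

    Returns ``(boundary_dist, center_dist)``.  ``boundary_dist`` is 0 when a
    TSS lies inside the peak, otherwise the gap to the nearest peak edge.
    ``center_dist`` is the distance from the peak center to the nearest TSS.
    Both are ``inf`` when the chromosome carries no TSS.
    """
    tss = tss_positions.get(peak.chrom)
    if tss is None or len(tss) == 0:
        return math.inf, math.inf
    # boundary: gap of each TSS to the nearest span edge, 0 inside/touching
    left = peak.start - tss
    right = tss - peak.end
    boundary = np.maximum(np.maximum(left, right), 0)
    center = np.abs(tss - peak.center)
    return float(boundary.min()), float(center.min())


def filter_distal(
    peaks: Sequence[GenomicInterval],
    genes: Iterable[GeneModel],
    params: DistalityParams = DistalityParams(),
) -> list[GenomicInterval]:
    """Keep peaks distal to every TSS; input order is preserved.

    A peak is kept when ``boundary_dist > boundary_min`` or
    ``center_dist > center_min`` (either rule suffices).
    """
    tss = tss_positions_by_chrom(genes)
    kept = []
    for p in peaks:
        b, c = nearest_tss_distances(p, tss)
        if b > params.boundary_min or c > params.center_min:
            kept.append(p)
    return kept


def stitch(
    peaks: Sequence[GenomicInterval], gap: int = 12500
) -> list[StitchedRegion]:
    """Merge same-chromosome peaks whose end-to-start gap is ``< gap`` bp.

    Merging is transitive (single linkage): a chain of peaks each within the
    gap of its neighbour forms one region regardless of the total span.
    Overlapping or book-ended peaks always merge.  Regions are returned
    sorted by (chrom, start) and each input peak belongs to exactly one
    region.
    """
    if gap <= 0:
        raise ValueError("gap must be positive")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    regions: list[StitchedRegion] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end))
        current: list[GenomicInterval] = []
        cur_end = -1
        for p in ordered:
            if current and p.start - cur_end < gap:
                current.append(p)
                cur_end = max(cur_end, p.end)
            else:
                if current:
                    regions.append(_make_region(chrom, current))
                current = [p]
                cur_end = p.end
        if current:
            regions.append(_make_region(chrom, current))
    return regions


def _make_region(chrom: str, constituents: list[GenomicInterval]) -> StitchedRegion:
    return StitchedRegion(
        chrom=chrom,
        start=min(p.start for p in constituents),
        end=max(p.end for p in constituents),
        constituents=list(constituents),
    )
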