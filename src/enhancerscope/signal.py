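"""Signal quantification over regions, genome binning and correlation.

A :class:`SignalTrack` stores per-chromosome sorted, non-overlapping
intervals with non-negative values (coverage semantics: the value applies to
every base of the interval).  Region signal is the per-base integral over
the region, and RPM normalization divides by the track's ``total_mass``
(library size when known, otherwise the track integral) times 1e6 — the
"reads per million" scaling used to compare enhancer signal across samples.

Genome-wide comparisons use fixed-width bins (2 kb by default) tiling each
chromosome; binned vectors from different marks or samples are compared by
Spearman or Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, StitchedRegion

__all__ = [
    "SignalTrack",
    "RegionSignal",
    "BinMatrix",
    "quantify",
    "bin_genome",
    "bin_signal",
    "correlate_samples",
    "enhancer_correlation",
]


class SignalTrack:
    """Sorted non-overlapping weighted intervals per chromosome."""

    def __init__(
        self,
        intervals: Iterable[tuple[str, int, int, float]],
        total_mass: float | None = None,
    ) -> None:
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in intervals:
            if value < 0:
                raise ValueError(f"negative signal value {value} at {chrom}:{start}")
            if not (0 <= start < end):
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end, value))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts = np.array([i[0] for i in ivs], dtype=np.int64)
            ends = np.array([i[1] for i in ivs], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping intervals on {chrom}")
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._values[chrom] = np.array([i[2] for i in ivs], dtype=np.float64)
        self._integral = float(
            sum(
                ((self._ends[c] - self._starts[c]) * self._values[c]).sum()
                for c in self._starts
            )
        )
        self.total_mass = float(total_mass) if total_mass is not None else self._integral
        if self._integral > 0 and self.total_mass <= 0:
            raise ValueError("total_mass must be positive for a non-empty track")

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def integral(self, chrom: str | None = None) -> float:
        """Sum over bases of value, for one chromosome or the whole track."""
        if chrom is None:
            return self._integral
        if chrom not in self._starts:
            return 0.0
        return float(
            ((self._ends[chrom] - self._starts[chrom]) * self._values[chrom]).sum()
        )

    def intervals(self) -> Iterable[tuple[str, int, int, float]]:
        for chrom in self.chroms:
            for s, e, v in zip(
                self._starts[chrom], self._ends[chrom], self._values[chrom]
            ):
                yield chrom, int(s), int(e), float(v)

    def region_raw(self, chrom: str, start: int, end: int) -> float:
        """Per-base integral of the track over ``[start, end)``."""
        if chrom not in self._starts:
            return 0.0
        starts, ends, values = self._starts[chrom], self._ends[chrom], self._values[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        return float((ov * values[lo:hi]).sum())

    def subtract(self, other: "SignalTrack") -> "SignalTrack":
        """Per-interval control subtraction; negative residues clamp to 0.

        Evaluated on the union of interval boundaries of both tracks so the
        result is exact for piecewise-constant inputs.
        """
        chroms = set(self.chroms) | set(other.chroms)
        out: list[tuple[str, int, int, float]] = []
        for chrom in sorted(chroms):
            bounds = np.unique(
                np.concatenate(
                    [
                        self._starts.get(chrom, np.empty(0, np.int64)),
                        self._ends.get(chrom, np.empty(0, np.int64)),
                        other._starts.get(chrom, np.empty(0, np.int64)),
                        other._ends.get(chrom, np.empty(0, np.int64)),
                    ]
                )
            )
            for s, e in zip(bounds[:-1], bounds[1:]):
                w = e - s
                v = self.region_raw(chrom, int(s), int(e)) / w
                c = other.region_raw(chrom, int(s), int(e)) / w
                net = max(v - c, 0.0)
                if net > 0:
                    out.append((chrom, int(s), int(e), net))
        return SignalTrack(out)


@dataclass(frozen=True)
class RegionSignal:
    """Raw and RPM-normalized signal for one region."""

    region: GenomicInterval | StitchedRegion
    raw: float
    rpm: float


def quantify(
    track: SignalTrack,
    regions: Sequence[GenomicInterval | StitchedRegion],
) -> list[RegionSignal]:
    """Integrate track signal over each region and normalize to RPM.

    ``rpm = raw * 1e6 / total_mass``; regions without overlapping signal get
    zero.  A track with zero total mass but non-zero raw signal is
    impossible by construction and rejected defensively.
    """
    out = []
    for r in regions:
        raw = track.region_raw(r.chrom, r.start, r.end)
        if raw > 0 and track.total_mass <= 0:
            raise ValueError("non-zero signal with zero total_mass")
        rpm = raw * 1e6 / track.total_mass if track.total_mass > 0 else 0.0
        out.append(RegionSignal(region=r, raw=raw, rpm=rpm))
    return out


def bin_genome(
    chrom_sizes: Mapping[str, int], width: int = 2000
) -> list[GenomicInterval]:
    """Tile each chromosome with fixed-width bins, last bin truncated."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    bins = []
    for chrom in sorted(chrom_sizes):
        length = chrom_sizes[chrom]
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}")
        for start in range(0, length, width):
            bins.append(GenomicInterval(chrom, start, min(start + width, length)))
    return bins


def bin_signal(track: SignalTrack, bins: Sequence[GenomicInterval]) -> np.ndarray:
    """Raw per-base signal integral in each bin."""
    return np.array([track.region_raw(b.chrom, b.start, b.end) for b in bins])


@dataclass
class BinMatrix:
    """Fixed genome bins with one signal vector per sample/mark."""

    bins: list[GenomicInterval]
    data: dict[str, np.ndarray] = field(default_factory=dict)

    def add_track(self, name: str, track: SignalTrack) -> None:
        self.data[name] = bin_signal(track, self.bins)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data)


def correlate_samples(matrix: BinMatrix | pd.DataFrame, method: str = "spearman") -> pd.DataFrame:
    """Pairwise sample correlation of binned signal vectors.

    Returns a symmetric matrix with unit diagonal; pairs involving a
    zero-variance vector are NaN rather than silently zero.  Spearman uses
    average ranks for ties.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    frame = matrix.to_frame() if isinstance(matrix, BinMatrix) else matrix
    if frame.shape[1] < 2:
        raise ValueError("need at least two samples")
    if frame.shape[0] < 3:
        raise ValueError("need at least three bins")
    corr = frame.corr(method=method)
    # pandas leaves the diagonal at 1 even for constant columns; mark those NaN
    degenerate = frame.std(ddof=0) == 0
    for name in frame.columns[degenerate]:
        corr.loc[name, :] = np.nan
        corr.loc[:, name] = np.nan
    return corr


def enhancer_correlation(
    track_a: SignalTrack,
    track_b: SignalTrack,
    regions: Sequence[GenomicInterval | StitchedRegion],
    method: str = "pearson",
    log_transform: bool = False,
) -> float:
    """Correlation of two marks' RPM signal over a shared set of regions.

    ``log_transform`` applies log2(x + 1) to both RPM vectors first, which
    compresses the heavy tail before a Pearson fit; off by default.
    """
    if len(regions) < 3:
        raise ValueError("need at least three regions")
    a = np.array([q.rpm for q in quantify(track_a, regions)])
    b = np.array([q.rpm for q in quantify(track_b, regions)])
    if log_transform:
        a, b = np.log2(a + 1), np.log2(b + 1)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    frame = pd.DataFrame({"a": a, "b": b})
    return float(frame.corr(method=method).iloc[0, 1])
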