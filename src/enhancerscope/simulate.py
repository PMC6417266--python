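"""Synthetic ChIP-seq / RNA-seq / histone-MS inputs with planted ground truth.

The generator lays out a small genome as a sequence of fixed-width slots
(50 kb), each holding one element: a gene, a typical enhancer cluster, a
super-enhancer cluster, or an H3K4me3-marked region.  Slot spacing keeps
every planted cluster well clear of all TSSs (so distality filtering keeps
them) and further apart than the stitch gap (so each cluster becomes
exactly one stitched region).

Signal model: each cluster carries a planted region-level H3K27ac signal
mass — a class base (super = base x ``se_signal_ratio``) times a log-normal
factor with modest dispersion (``region_sigma``, z-scores truncated at 2 so
planted classes stay separable and the ground truth is well defined).
Within a cluster the mass is split across constituent peaks with
heavy-tailed log-normal per-peak heights (``signal_sigma``).  H4K8ac is a
per-region log-correlated copy of H3K27ac (``mark_correlation``), emulating
the co-localization of the two acetylations on enhancers.

H3K4me3 distal peaks are planted over a fraction of the super clusters
(``k4_overlap_fraction``), over dedicated high-H3K27ac regions that carry
no H3K27ac peak call, and over low-signal regions — giving the
H3K4me3-route caller its own hockey-stick curve whose super set overlaps
the conventional planted supers at the configured fraction.

Expression: per-gene FPKM means are gamma-distributed; replicate values are
gamma around the mean; genes nearest to planted supers get their tumor mean
multiplied by ``expr_boost_for_se_adjacent``.  Peptidoform areas are
log-normal around per-form means with multiplicative tumor effects on
designated marks.

Every output is a pure function of the configuration (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval

__all__ = [
    "SimConfig",
    "Genome",
    "GroundTruth",
    "SimulatedTracks",
    "simulate_genome",
    "simulate_peaks_and_tracks",
    "simulate_expression",
    "simulate_peptidoform_areas",
]

SLOT = 50_000  # bp per layout slot; spacing >> stitch gap and TSS thresholds

# slot roles
_GENE, _TYP, _SUP, _K4HIGH, _K4TYP = "gene", "typical", "super", "k4_high", "k4_typical"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic bundle.

    ``se_signal_ratio`` is the planted super:typical region-signal ratio;
    ``mark_correlation`` the log-scale H3K27ac/H4K8ac correlation across
    regions; ``k4_overlap_fraction`` the fraction of high-signal H3K4me3
    regions planted on conventional super clusters.
    """

    seed: int = 20190312
    n_chroms: int = 2
    chrom_length: int | None = None  # derived from the layout when None
    n_genes: int = 120
    n_typical_clusters: int = 60
    n_super_clusters: int = 5
    peaks_per_cluster: tuple[int, int] = (2, 5)
    se_signal_ratio: float = 20.0
    k4_overlap_fraction: float = 0.5
    n_k4_high_clusters: int = 6
    n_k4_typical_clusters: int = 30
    mark_correlation: float = 0.8
    signal_sigma: float = 0.3  # per-peak log-normal height noise
    region_sigma: float = 0.1  # region-level log-normal mass noise (z clipped at 2)
    h4k8ac_scale: float = 0.8
    typical_mass: float = 3000.0  # base per-region H3K27ac signal mass (value*bp)
    expr_boost_for_se_adjacent: float = 4.0
    fpkm_shape: float = 3.0  # gamma shape of replicate FPKM around gene mean
    fpkm_mean_shape: float = 1.5
    fpkm_mean_scale: float = 8.0
    n_replicates: int = 3
    area_sigma: float = 0.25  # log-normal noise of peptidoform peak areas
    ptm_effects: tuple[tuple[str, float], ...] = (
        ("H3K27ac", 2.5),
        ("H4K8ac", 2.0),
        ("H3K4me3", 2.5),
        ("H3K36me3", 0.4),
    )

    def __post_init__(self) -> None:
        if min(
            self.n_chroms, self.n_genes + 1, self.n_typical_clusters,
            self.n_replicates,
        ) < 0:
            raise ValueError("counts must be non-negative")
        if not (0.0 <= self.k4_overlap_fraction <= 1.0):
            raise ValueError("k4_overlap_fraction must be in [0, 1]")
        if not (-1.0 <= self.mark_correlation <= 1.0):
            raise ValueError("mark_correlation must be in [-1, 1]")
        if self.se_signal_ratio < 1.0:
            raise ValueError("se_signal_ratio must be >= 1")
        lo, hi = self.peaks_per_cluster
        if not (1 <= lo <= hi):
            raise ValueError("invalid peaks_per_cluster range")

    def rng(self, stage: int) -> np.random.Generator:
        """Independent stream per pipeline stage, derived from the seed."""
        return np.random.default_rng([self.seed, stage])


@dataclass(frozen=True)
class _Slot:
    chrom: str
    start: int  # slot origin
    role: str
    index: int  # index within its role class


@dataclass
class Genome:
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    slots: list[_Slot]

    def slots_of(self, role: str) -> list[_Slot]:
        return [s for s in self.slots if s.role == role]


@dataclass
class GroundTruth:
    """Planted regions and expectations the tests check recovery against."""

    super_regions: list[GenomicInterval]
    typical_regions: list[GenomicInterval]
    k4_super_regions: list[GenomicInterval]  # high-signal H3K4me3 regions
    k4_on_super: list[bool]  # parallel: planted on a conventional super?
    se_adjacent_genes: list[str]
    region_signal: dict[str, float]  # region name -> planted H3K27ac mass


@dataclass
class SimulatedTracks:
    peaks: dict[str, list[GenomicInterval]]  # mark -> peak calls
    tracks: dict[str, "SignalTrack"]  # mark -> signal track
    truth: GroundTruth


def simulate_genome(config: SimConfig) -> Genome:
    """Lay out chromosomes, assign slot roles and place genes."""
    n_k4_on_super = round(config.k4_overlap_fraction * config.n_k4_high_clusters)
    if n_k4_on_super > config.n_super_clusters:
        raise ValueError(
            "k4_overlap_fraction requires more super clusters than configured"
        )
    n_k4_only = config.n_k4_high_clusters - n_k4_on_super
    roles = (
        [_GENE] * config.n_genes
        + [_TYP] * config.n_typical_clusters
        + [_SUP] * config.n_super_clusters
        + [_K4HIGH] * n_k4_only
        + [_K4TYP] * config.n_k4_typical_clusters
    )
    rng = config.rng(1)
    order = rng.permutation(len(roles))
    roles = [roles[i] for i in order]

    n_slots = len(roles)
    per_chrom = -(-n_slots // config.n_chroms)  # ceil
    needed = per_chrom * SLOT + SLOT
    if config.chrom_length is not None and config.chrom_length < needed:
        raise ValueError(
            f"chrom_length {config.chrom_length} too small for layout "
            f"(need >= {needed}); too many elements to pack"
        )
    length = config.chrom_length if config.chrom_length is not None else needed
    chrom_sizes = {f"chr{i + 1}": length for i in range(config.n_chroms)}

    counters: dict[str, int] = {}
    slots: list[_Slot] = []
    genes: list[GeneModel] = []
    for i, role in enumerate(roles):
        chrom = f"chr{i % config.n_chroms + 1}"
        start = (i // config.n_chroms) * SLOT
        idx = counters.get(role, 0)
        counters[role] = idx + 1
        slots.append(_Slot(chrom=chrom, start=start, role=role, index=idx))
    # genes: TSS mid-slot with jitter; strand alternates deterministically
    jitter = config.rng(2).integers(-5000, 5001, size=counters.get(_GENE, 0))
    for k, slot in enumerate(s for s in slots if s.role == _GENE):
        tss = slot.start + SLOT // 2 + int(jitter[k])
        strand = "+" if k % 2 == 0 else "-"
        if strand == "+":
            start, end = tss, tss + 5000
        else:
            start, end = tss - 4999, tss + 1
        genes.append(GeneModel(f"gene_{k:04d}", slot.chrom, strand, start, end))
    return Genome(chrom_sizes=chrom_sizes, genes=genes, slots=slots)


def _cluster_peaks(
    slot: _Slot, rng: np.random.Generator, n_range: tuple[int, int], prefix: str
) -> list[GenomicInterval]:
    """Place 1..k peaks inside a slot, gaps well under the stitch threshold."""
    k = int(rng.integers(n_range[0], n_range[1] + 1))
    pos = slot.start + 4000
    peaks = []
    for j in range(k):
        width = int(rng.integers(500, 1501))
        peaks.append(
            GenomicInterval(slot.chrom, pos, pos + width, name=f"{prefix}_{slot.index}_{j}")
        )
        pos += width + int(rng.integers(1000, 8001))
    return peaks


def _clipped_normal(rng: np.random.Generator, size: int, clip: float = 2.0) -> np.ndarray:
    return np.clip(rng.normal(0.0, 1.0, size), -clip, clip)


def simulate_peaks_and_tracks(config: SimConfig, genome: Genome) -> SimulatedTracks:
    """Plant peaks, signal tracks and ground truth on a simulated genome."""
    from .signal import SignalTrack

    rng = config.rng(3)
    cluster_slots = [s for s in genome.slots if s.role in (_TYP, _SUP, _K4HIGH)]
    # constituent H3K27ac-scale peaks per cluster (K4HIGH carries track only)
    peaks_by_slot = {
        id(s): _cluster_peaks(s, rng, config.peaks_per_cluster, s.role)
        for s in cluster_slots
    }

    # planted region-level H3K27ac mass, log-correlated H4K8ac copy
    n = len(cluster_slots)
    z1 = _clipped_normal(config.rng(4), n)
    w = _clipped_normal(config.rng(5), n)
    rho = config.mark_correlation
    z2 = np.clip(rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * w, -2.0, 2.0)
    k27_mass, k8_mass = {}, {}
    for i, slot in enumerate(cluster_slots):
        base = config.typical_mass * (
            config.se_signal_ratio if slot.role in (_SUP, _K4HIGH) else 1.0
        )
        k27_mass[id(slot)] = base * float(np.exp(config.region_sigma * z1[i]))
        k8_mass[id(slot)] = (
            config.h4k8ac_scale * base * float(np.exp(config.region_sigma * z2[i]))
        )

    # per-peak heavy-tailed heights, renormalized to the planted region mass
    hrng = config.rng(6)
    k27_iv, k8_iv = [], []
    for slot in cluster_slots:
        pk = peaks_by_slot[id(slot)]
        widths = np.array([p.width for p in pk], dtype=float)
        g = np.exp(config.signal_sigma * hrng.normal(0.0, 1.0, len(pk)))
        unit = widths * g
        h27 = k27_mass[id(slot)] * g / unit.sum()
        h8 = k8_mass[id(slot)] * g / unit.sum()
        for p, a, b in zip(pk, h27, h8):
            k27_iv.append((p.chrom, p.start, p.end, float(a)))
            k8_iv.append((p.chrom, p.start, p.end, float(b)))

    # H3K4me3: one distal peak over a fraction of supers, plus dedicated
    # high- and low-signal H3K4me3 regions
    k4rng = config.rng(7)
    k4_peaks: list[GenomicInterval] = []
    k4_iv = []
    k4_super_regions: list[GenomicInterval] = []
    k4_on_super: list[bool] = []
    super_slots = genome.slots_of(_SUP)
    n_on_super = round(config.k4_overlap_fraction * config.n_k4_high_clusters)

    def hull_peak(slot: _Slot, name: str) -> GenomicInterval:
        # broad H3K4me3 domain spanning the cluster, so the stitched
        # H3K4me3 region carries the cluster's full planted H3K27ac mass
        pk = peaks_by_slot[id(slot)]
        return GenomicInterval(
            slot.chrom, min(p.start for p in pk), max(p.end for p in pk), name=name
        )

    for on_super, slot in [(True, s) for s in super_slots[:n_on_super]] + [
        (False, s) for s in genome.slots_of(_K4HIGH)
    ]:
        pk = hull_peak(slot, f"k4{'sup' if on_super else 'high'}_{slot.index}")
        k4_peaks.append(pk)
        k4_iv.append((pk.chrom, pk.start, pk.end, float(np.exp(k4rng.normal(0, 0.2)))))
        k4_super_regions.append(pk)
        k4_on_super.append(on_super)
    for slot in genome.slots_of(_K4TYP):
        width = int(k4rng.integers(800, 1500))
        start = slot.start + 4000
        pk = GenomicInterval(slot.chrom, start, start + width, name=f"k4typ_{slot.index}")
        k4_peaks.append(pk)
        k4_iv.append((pk.chrom, pk.start, pk.end, float(np.exp(k4rng.normal(0, 0.2)))))
        # low H3K27ac signal under low-class H3K4me3 regions (no H3K27ac peak)
        mass = config.typical_mass * float(
            np.exp(config.region_sigma * np.clip(k4rng.normal(), -2, 2))
        )
        k27_iv.append((pk.chrom, pk.start, pk.end, mass / pk.width))
        k8_iv.append(
            (pk.chrom, pk.start, pk.end, config.h4k8ac_scale * mass / pk.width)
        )

    # H3K27ac peak calls exist only for typical + super clusters
    k27_peaks = [
        p
        for slot in cluster_slots
        if slot.role in (_TYP, _SUP)
        for p in peaks_by_slot[id(slot)]
    ]

    def hull(pk: list[GenomicInterval], name: str) -> GenomicInterval:
        return GenomicInterval(
            pk[0].chrom, min(p.start for p in pk), max(p.end for p in pk), name=name
        )

    region_signal: dict[str, float] = {}
    super_regions, typical_regions = [], []
    for slot in cluster_slots:
        name = f"{slot.role}_{slot.index}"
        region = hull(peaks_by_slot[id(slot)], name)
        region_signal[name] = k27_mass[id(slot)]
        if slot.role == _SUP:
            super_regions.append(region)
        elif slot.role == _TYP:
            typical_regions.append(region)

    # SE-adjacent genes: nearest TSS to each planted super's midpoint
    se_genes = []
    for region in super_regions:
        candidates = [g for g in genome.genes if g.chrom == region.chrom]
        if candidates:
            best = min(
                candidates, key=lambda g: (abs(g.tss - region.center), g.gene_id)
            )
            se_genes.append(best.gene_id)

    truth = GroundTruth(
        super_regions=super_regions,
        typical_regions=typical_regions,
        k4_super_regions=k4_super_regions,
        k4_on_super=k4_on_super,
        se_adjacent_genes=sorted(set(se_genes)),
        region_signal=region_signal,
    )
    tracks = {
        "H3K27ac": SignalTrack(k27_iv),
        "H4K8ac": SignalTrack(k8_iv),
        "H3K4me3": SignalTrack(k4_iv),
    }
    peaks = {"H3K27ac": k27_peaks, "H3K4me3": sorted(k4_peaks, key=lambda p: (p.chrom, p.start))}
    return SimulatedTracks(peaks=peaks, tracks=tracks, truth=truth)


def simulate_expression(
    config: SimConfig, genome: Genome, truth: GroundTruth
) -> "ExpressionTable":
    """Gene-by-sample FPKM with boosted tumor expression near planted supers."""
    from .genes import ExpressionTable

    rng = config.rng(8)
    gene_ids = [g.gene_id for g in genome.genes]
    means = rng.gamma(config.fpkm_mean_shape, config.fpkm_mean_scale, len(gene_ids))
    boosted = set(truth.se_adjacent_genes)
    shape = config.fpkm_shape
    data = {}
    for cond in ("normal", "tumor"):
        for r in range(1, config.n_replicates + 1):
            col = f"{cond}_{r}"
            mu = np.array(
                [
                    m * config.expr_boost_for_se_adjacent
                    if (cond == "tumor" and g in boosted)
                    else m
                    for g, m in zip(gene_ids, means)
                ]
            )
            data[col] = rng.gamma(shape, mu / shape)
    frame = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    conditions = {c: c.rsplit("_", 1)[0] for c in frame.columns}
    return ExpressionTable(fpkm=frame, conditions=conditions)


# peptide -> (PTM combo, base relative weight); "unmod" carries no marks
_PEPTIDE_FORMS: tuple[tuple[str, str, float], ...] = (
    ("H3 3-8", "unmod", 50), ("H3 3-8", "H3K4me1", 12), ("H3 3-8", "H3K4me2", 6),
    ("H3 3-8", "H3K4me3", 4), ("H3 3-8", "H3K4ac", 8),
    ("H3 9-17", "unmod", 30), ("H3 9-17", "H3K9me1", 15), ("H3 9-17", "H3K9me2", 12),
    ("H3 9-17", "H3K9me3", 10), ("H3 9-17", "H3K9ac", 8), ("H3 9-17", "H3K14ac", 14),
    ("H3 9-17", "H3K9me3+H3K14ac", 4),
    ("H3 18-26", "unmod", 45), ("H3 18-26", "H3K18ac", 15), ("H3 18-26", "H3K23ac", 20),
    ("H3 18-26", "H3K18ac+H3K23ac", 8), ("H3 18-26", "H3K23me1", 6),
    ("H3 27-40", "unmod", 20), ("H3 27-40", "H3K27me1", 12), ("H3 27-40", "H3K27me2", 16),
    ("H3 27-40", "H3K27me3", 10), ("H3 27-40", "H3K27ac", 6), ("H3 27-40", "H3K36me1", 9),
    ("H3 27-40", "H3K36me2", 11), ("H3 27-40", "H3K36me3", 7),
    ("H3 27-40", "H3K27me2+H3K36me2", 5), ("H3 27-40", "H3K27ac+H3K36me1", 3),
    ("H4 4-17", "unmod", 40), ("H4 4-17", "H4K5ac", 8), ("H4 4-17", "H4K8ac", 10),
    ("H4 4-17", "H4K12ac", 9), ("H4 4-17", "H4K16ac", 18), ("H4 4-17", "H4K8ac+H4K12ac", 4),
    ("H4 20-23", "unmod", 25), ("H4 20-23", "H4K20me1", 30), ("H4 20-23", "H4K20me2", 35),
    ("H4 20-23", "H4K20me3", 10),
)


def simulate_peptidoform_areas(config: SimConfig) -> pd.DataFrame:
    """Peptidoform peak-area table for 3+3 (default) replicates.

    Tumor samples multiply the areas of forms carrying a designated mark by
    that mark's effect factor; all areas carry log-normal noise.
    """
    if config.n_replicates < 2:
        raise ValueError("need at least two replicates per condition")
    rng = config.rng(9)
    effects = dict(config.ptm_effects)
    rows = []
    total_area = 1e7
    for pep, combo, weight in _PEPTIDE_FORMS:
        marks = [] if combo == "unmod" else combo.split("+")
        effect = float(np.prod([effects.get(m, 1.0) for m in marks]))
        row: dict[str, object] = {"peptide_id": pep, "ptm_combo": combo}
        for cond in ("normal", "tumor"):
            for r in range(1, config.n_replicates + 1):
                mean = total_area * weight / 100.0
                if cond == "tumor":
                    mean *= effect
                noise = float(np.exp(config.area_sigma * rng.normal()))
                row[f"{cond}_{r}"] = mean * noise
        rows.append(row)
    return pd.DataFrame(rows)
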