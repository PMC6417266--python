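"""Enhancer-to-gene assignment and expression-change classification.

Enhancer target genes are approximated by adjacency: either the single gene
whose TSS is closest to the enhancer midpoint (``nearest``), or every gene
whose TSS falls within a window of the enhancer span (``window``).  Linked
genes are classified by their tumor/normal fold change of mean FPKM into
increased / decreased / no-change clusters, with an optional four-way
variant that additionally splits the unchanged genes into low- and
high-expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, StitchedRegion

__all__ = [
    "ExpressionTable",
    "EnhancerGeneLink",
    "assign_adjacent_genes",
    "classify_expression_change",
    "classify_four_way",
    "summarize_expression_by_class",
]


@dataclass
class ExpressionTable:
    """Gene-by-sample FPKM values plus a sample → condition mapping."""

    fpkm: pd.DataFrame  # rows: gene_id, columns: sample names
    conditions: dict[str, str]  # sample -> {"normal", "tumor"}

    def __post_init__(self) -> None:
        missing = set(self.fpkm.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")
        if (self.fpkm.values < 0).any():
            raise ValueError("negative FPKM values")

    def samples(self, condition: str) -> list[str]:
        return [s for s in self.fpkm.columns if self.conditions[s] == condition]

    def mean_by_condition(self, condition: str) -> pd.Series:
        cols = self.samples(condition)
        if not cols:
            raise ValueError(f"no samples for condition {condition!r}")
        return self.fpkm[cols].mean(axis=1)

    def swap_conditions(self) -> "ExpressionTable":
        flipped = {
            s: ("tumor" if c == "normal" else "normal" if c == "tumor" else c)
            for s, c in self.conditions.items()
        }
        return ExpressionTable(fpkm=self.fpkm, conditions=flipped)


@dataclass(frozen=True)
class EnhancerGeneLink:
    enhancer: StitchedRegion | GenomicInterval
    gene_id: str
    distance: int  # bp from the enhancer span to the gene TSS; 0 if inside
    cluster: str | None = None
    fold_change: float | None = None


def _span_distance(enhancer, tss: int) -> int:
    """Gap between a TSS and the enhancer span, 0 when the TSS is inside."""
    return max(enhancer.start - tss, tss - enhancer.end, 0)


def assign_adjacent_genes(
    enhancers: Sequence[StitchedRegion | GenomicInterval],
    genes: Sequence[GeneModel],
    window: int = 50_000,
    mode: str = "nearest",
) -> list[EnhancerGeneLink]:
    """Link each enhancer to its adjacent gene(s).

    ``nearest`` keeps the single gene whose TSS is closest to the enhancer
    midpoint (ties broken by lexicographically smaller gene_id); ``window``
    keeps every gene with a TSS within ``window`` bp of the enhancer span.
    Enhancers on chromosomes without genes produce no link.
    """
    if mode not in ("nearest", "window"):
        raise ValueError(f"unknown mode {mode!r}")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    links: list[EnhancerGeneLink] = []
    for enh in enhancers:
        candidates = by_chrom.get(enh.chrom, [])
        if not candidates:
            continue
        if mode == "nearest":
            mid = enh.center
            best = min(candidates, key=lambda g: (abs(g.tss - mid), g.gene_id))
            links.append(
                EnhancerGeneLink(
                    enhancer=enh,
                    gene_id=best.gene_id,
                    distance=_span_distance(enh, best.tss),
                )
            )
        else:
            for g in sorted(candidates, key=lambda g: g.gene_id):
                d = _span_distance(enh, g.tss)
                if d <= window:
                    links.append(
                        EnhancerGeneLink(enhancer=enh, gene_id=g.gene_id, distance=d)
                    )
    return links


def _fold_changes(
    gene_ids: Sequence[str], expr: ExpressionTable, pseudocount: float
) -> pd.Series:
    missing = [g for g in gene_ids if g not in expr.fpkm.index]
    if missing:
        raise KeyError(f"genes absent from expression table: {missing[:5]}")
    m_t = expr.mean_by_condition("tumor")
    m_n = expr.mean_by_condition("normal")
    return (m_t + pseudocount) / (m_n + pseudocount)


def classify_expression_change(
    links: Sequence[EnhancerGeneLink],
    expr: ExpressionTable,
    fc_threshold: float = 1.5,
    pseudocount: float = 2.0 ** -5,
) -> list[EnhancerGeneLink]:
    """Label each link increased / decreased / no_change by FPKM fold change.

    The ratio ``(mean_tumor + pc) / (mean_normal + pc)`` is compared to the
    threshold: ``increased`` at >= fc_threshold, ``decreased`` at
    <= 1/fc_threshold, else ``no_change``.  The pseudocount guards genes
    silent in one condition.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must exceed 1")
    ratios = _fold_changes([l.gene_id for l in links], expr, pseudocount)
    out = []
    for link in links:
        r = float(ratios[link.gene_id])
        if r >= fc_threshold:
            label = "increased"
        elif r <= 1.0 / fc_threshold:
            label = "decreased"
        else:
            label = "no_change"
        out.append(replace(link, cluster=label, fold_change=r))
    return out


def classify_four_way(
    links: Sequence[EnhancerGeneLink],
    expr: ExpressionTable,
    fc_threshold: float = 1.5,
    pseudocount: float = 2.0 ** -5,
    flat_split_fpkm: float = 1.0,
) -> list[EnhancerGeneLink]:
    """Four-cluster variant: up / down / flat_low / flat_high.

    Unchanged genes are split at ``flat_split_fpkm`` mean FPKM (across all
    samples) into weakly and robustly expressed clusters.
    """
    three = classify_expression_change(links, expr, fc_threshold, pseudocount)
    overall_mean = expr.fpkm.mean(axis=1)
    out = []
    for link in three:
        if link.cluster == "increased":
            label = "up"
        elif link.cluster == "decreased":
            label = "down"
        else:
            label = (
                "flat_high"
                if float(overall_mean[link.gene_id]) >= flat_split_fpkm
                else "flat_low"
            )
        out.append(replace(link, cluster=label))
    return out


def summarize_expression_by_class(
    expr: ExpressionTable,
    gene_sets: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Quartile summary of per-gene mean FPKM for named gene classes.

    One row per (class, condition) with n, median and quartiles of the
    condition-mean FPKM; empty classes are reported with n = 0.
    """
    rows = []
    for cls, gene_ids in gene_sets.items():
        gene_ids = [g for g in gene_ids if g in expr.fpkm.index]
        for condition in sorted(set(expr.conditions.values())):
            if gene_ids:
                means = expr.mean_by_condition(condition).loc[list(gene_ids)]
                q1, med, q3 = np.percentile(means, [25, 50, 75])
            else:
                q1 = med = q3 = float("nan")
            rows.append(
                {
                    "class": cls,
                    "condition": condition,
                    "n": len(gene_ids),
                    "q1": q1,
                    "median": med,
                    "q3": q3,
                }
            )
    return pd.DataFrame(rows)
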