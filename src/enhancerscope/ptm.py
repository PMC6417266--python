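"""Histone peptidoform relative abundance and two-condition comparison.

Bottom-up histone MS quantifies each proteolytic peptide in all of its PTM
forms (peptidoforms).  The relative abundance of one form is its
chromatographic peak area divided by the summed area of every form of the
same peptide, expressed in percent.  A single mark's abundance is the sum
of the relative abundances of all forms carrying that mark; because
peptides are short, marks co-occurring on different peptides are never
combined.  Conditions are compared per mark with a two-sided equal-variance
(homoscedastic) t-test on the replicate abundances; significance is plain
p < 0.05 by default, with an optional Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MarkAbundance",
    "peptidoform_relative_abundance",
    "single_mark_abundance",
    "all_single_marks",
    "compare_conditions",
    "compare_all_marks",
    "volcano_table",
    "read_peptidoform_table",
]

UNMODIFIED = "unmod"


def read_peptidoform_table(path) -> pd.DataFrame:
    """Read a peptidoform area table (TSV).

    Expected columns: ``peptide_id``, ``ptm_combo`` (mark labels joined by
    '+', or ``unmod``), then one column of non-negative areas per sample.
    """
    frame = pd.read_csv(path, sep="\t")
    required = {"peptide_id", "ptm_combo"}
    if not required.issubset(frame.columns):
        raise ValueError(f"peptidoform table must have columns {sorted(required)}")
    sample_cols = [c for c in frame.columns if c not in required]
    if (frame[sample_cols].values < 0).any():
        raise ValueError("negative peak areas")
    dup = frame.duplicated(subset=["peptide_id", "ptm_combo"])
    if dup.any():
        raise ValueError("duplicate (peptide_id, ptm_combo) rows")
    return frame


def _combo_marks(combo: str) -> frozenset[str]:
    if combo == UNMODIFIED or not combo:
        return frozenset()
    return frozenset(combo.split("+"))


def peptidoform_relative_abundance(areas: pd.DataFrame) -> pd.DataFrame:
    """Percent abundance of each peptidoform within its peptide, per sample.

    ``areas`` has columns peptide_id, ptm_combo and one column per sample;
    the result has the same shape with areas replaced by percentages that
    sum to 100 within each (peptide, sample).  A peptide with zero total
    area in some sample is an error.
    """
    sample_cols = [c for c in areas.columns if c not in ("peptide_id", "ptm_combo")]
    out = areas.copy()
    for pep, group in areas.groupby("peptide_id"):
        totals = group[sample_cols].sum(axis=0)
        zero = totals[totals <= 0]
        if not zero.empty:
            raise ValueError(
                f"peptide {pep!r} has zero total area in sample(s) {list(zero.index)}"
            )
        out.loc[group.index, sample_cols] = 100.0 * group[sample_cols] / totals
    return out


def single_mark_abundance(percents: pd.DataFrame, mark: str) -> pd.Series:
    """Sum of peptidoform percentages carrying ``mark``, per sample.

    Summation runs over the forms of the one peptide that hosts the mark's
    residue; a mark present in no combo yields 0 with a warning.
    """
    sample_cols = [c for c in percents.columns if c not in ("peptide_id", "ptm_combo")]
    carries = percents["ptm_combo"].map(lambda c: mark in _combo_marks(c))
    if not carries.any():
        warnings.warn(f"mark {mark!r} not found in any peptidoform", stacklevel=2)
        return pd.Series(0.0, index=sample_cols, name=mark)
    result = percents.loc[carries, sample_cols].sum(axis=0)
    result.name = mark
    return result


def all_single_marks(percents: pd.DataFrame) -> pd.DataFrame:
    """Mark-by-sample matrix of single-mark abundances (percent)."""
    marks = sorted({m for c in percents["ptm_combo"] for m in _combo_marks(c)})
    return pd.DataFrame(
        {m: single_mark_abundance(percents, m) for m in marks}
    ).T


@dataclass(frozen=True)
class MarkAbundance:
    """Per-mark comparison of relative abundance between two conditions."""

    mark: str
    mean_a: float
    mean_b: float
    fold_change: float  # mean_b / mean_a (condition b over a, e.g. tumor/normal)
    t_statistic: float
    p_value: float
    significant: bool
    one_condition: bool  # detected (non-zero) in only one condition


def compare_conditions(
    abundances: pd.Series,
    group_a: list[str],
    group_b: list[str],
    mark: str = "",
    alpha: float = 0.05,
) -> MarkAbundance:
    """Homoscedastic two-sided t-test of one mark between two groups.

    Degenerate variance is handled explicitly: identical means give p = 1,
    while zero variance with different means gives a p = 0 sentinel with a
    warning (the test statistic is unbounded there).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least two replicates per group")
    a = abundances[group_a].to_numpy(dtype=float)
    b = abundances[group_b].to_numpy(dtype=float)
    mean_a, mean_b = float(a.mean()), float(b.mean())
    pooled_var = (
        ((a - mean_a) ** 2).sum() + ((b - mean_b) ** 2).sum()
    ) / (len(a) + len(b) - 2)
    if pooled_var == 0:
        if mean_a == mean_b:
            t, p = 0.0, 1.0
        else:
            warnings.warn(
                f"zero within-group variance with unequal means for {mark!r}",
                stacklevel=2,
            )
            t, p = float("inf") if mean_b > mean_a else float("-inf"), 0.0
    else:
        t, p = stats.ttest_ind(b, a, equal_var=True)
        t, p = float(t), float(p)
    fold = mean_b / mean_a if mean_a > 0 else float("inf") if mean_b > 0 else 1.0
    return MarkAbundance(
        mark=mark,
        mean_a=mean_a,
        mean_b=mean_b,
        fold_change=fold,
        t_statistic=t,
        p_value=p,
        significant=p < alpha,
        one_condition=(mean_a == 0) != (mean_b == 0),
    )


def compare_all_marks(
    mark_matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> list[MarkAbundance]:
    """Run :func:`compare_conditions` for every mark (rows of the matrix).

    ``bh_correction`` recomputes the significance flags after a
    Benjamini-Hochberg adjustment; raw p-values are reported either way.
    """
    results = [
        compare_conditions(mark_matrix.loc[m], group_a, group_b, mark=m, alpha=alpha)
        for m in mark_matrix.index
    ]
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(
            [r.p_value for r in results], alpha=alpha, method="fdr_bh"
        )
        results = [
            MarkAbundance(
                r.mark, r.mean_a, r.mean_b, r.fold_change, r.t_statistic,
                r.p_value, bool(rej), r.one_condition,
            )
            for r, rej in zip(results, reject)
        ]
    return results


def volcano_table(results: list[MarkAbundance]) -> pd.DataFrame:
    """Tabulate log2 fold change vs -log10 p per mark for a volcano plot.

    Marks detected in only one condition are flagged and carry NaN on the
    fold-change axis instead of an infinite coordinate.
    """
    rows = []
    for r in results:
        one = r.one_condition
        log2fc = float("nan") if one else float(np.log2(r.fold_change))
        neglogp = float(-np.log10(r.p_value)) if r.p_value > 0 else float("inf")
        rows.append(
            {
                "mark": r.mark,
                "log2_fold_change": log2fc,
                "neg_log10_p": neglogp,
                "significant": r.significant,
                "one_condition": one,
            }
        )
    return pd.DataFrame(rows)
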