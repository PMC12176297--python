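"""Replicate-aware statistics for grouped per-cell measurements.

Superplot conventions: per-cell values are summarized at the biological-
replicate level (per-replicate means), and group location/spread are the
mean and SD of replicate means. Group comparisons follow the conventions
of the figures this package serves: a one-way ANOVA over per-cell values
followed by all-pairs Tukey HSD, with an additional Bonferroni
multiplication of the Tukey p-values reported alongside the plain ones
(the combination is unusual — Tukey already controls family-wise error —
but both columns are emitted, labelled). Percent-positive scoring
aggregates binary per-cell calls per replicate and compares genotypes with
an unpaired two-sided t-test (Welch by default) on replicate percentages.
Fold changes between conditions come with a seeded bootstrap percentile
confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "superplot_summary",
    "anova_tukey",
    "percent_positive",
    "fold_change",
    "AnovaTukeyResult",
    "FoldChangeResult",
]


def superplot_summary(
    df: pd.DataFrame,
    value: str = "value",
    genotype: str = "genotype",
    replicate: str = "replicate",
) -> pd.DataFrame:
    """Replicate-level summary of per-cell values.

    One row per genotype with the list of replicate means, their grand mean
    (mean of replicate means — invariant to within-replicate duplication of
    cells) and the SD across replicate means (NaN for a single replicate).
    Empty replicates are dropped with a warning column in the output.
    """
    rows = []
    for g, sub in df.groupby(genotype, sort=True):
        rep_means = sub.groupby(replicate)[value].mean()
        rep_n = sub.groupby(replicate)[value].size()
        rep_means = rep_means[rep_n > 0]
        rows.append(
            {
                "genotype": g,
                "n_replicates": len(rep_means),
                "n_cells": int(len(sub)),
                "replicate_means": rep_means.to_list(),
                "grand_mean": float(rep_means.mean()),
                "sd_of_replicate_means": float(rep_means.std(ddof=1))
                if len(rep_means) > 1
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AnovaTukeyResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, mean_diff, tukey_p, bonferroni_tukey_p


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> AnovaTukeyResult:
    """One-way ANOVA plus all-pairs Tukey HSD.

    The Tukey p-values come from the studentized range distribution; the
    ``bonferroni_tukey_p`` column multiplies them by the number of pairwise
    comparisons (capped at 1). Degenerate input with zero variance
    everywhere and equal means yields F = 0, p = 1.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[n], dtype=np.float64) for n in names]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")

    grand = np.concatenate(arrays)
    df_b = len(names) - 1
    df_w = grand.size - len(names)
    if np.ptp(grand) == 0:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = sps.f_oneway(*arrays)
        if np.isnan(f_stat):  # zero within-group variance, equal means
            f_stat, p = 0.0, 1.0
        f_stat, p = float(f_stat), float(p)

    degenerate = np.ptp(grand) == 0
    tk = None if degenerate else sps.tukey_hsd(*arrays)
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for i, j in combinations(range(len(names)), 2):
        tukey_p = 1.0 if degenerate else float(tk.pvalue[i, j])
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                "tukey_p": tukey_p,
                "bonferroni_tukey_p": min(1.0, tukey_p * n_pairs),
            }
        )
    pairwise = pd.DataFrame(rows)
    pairwise.attrs["n_comparisons"] = n_pairs
    return AnovaTukeyResult(
        f_statistic=f_stat, df_between=df_b, df_within=df_w, p_value=p, pairwise=pairwise
    )


def percent_positive(
    df: pd.DataFrame,
    positive: str = "positive",
    genotype: str = "genotype",
    replicate: str = "replicate",
    welch: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent-positive scoring with replicate-level t-tests.

    ``df`` holds one row per scored cell with a binary ``positive`` column.
    Returns ``(summary, tests)``: per-genotype replicate percentages with
    mean and SD, and pairwise unpaired two-sided t-tests on the replicate
    percentages (skipped with a notice when a genotype has < 2 replicates).
    """
    per_rep = (
        df.groupby([genotype, replicate])[positive]
        .agg(n="size", n_positive="sum")
        .reset_index()
    )
    per_rep["percent"] = 100.0 * per_rep["n_positive"] / per_rep["n"]
    summary = (
        per_rep.groupby(genotype)["percent"]
        .agg(n_replicates="size", mean_percent="mean", sd_percent=lambda s: s.std(ddof=1))
        .reset_index()
    )
    tests = []
    for ga, gb in combinations(summary[genotype], 2):
        pa = per_rep.loc[per_rep[genotype] == ga, "percent"].to_numpy()
        pb = per_rep.loc[per_rep[genotype] == gb, "percent"].to_numpy()
        if pa.size < 2 or pb.size < 2:
            tests.append(
                {"group_a": ga, "group_b": gb, "t": np.nan, "p": np.nan,
                 "note": "skipped: fewer than 2 replicates"}
            )
            continue
        if np.ptp(np.concatenate([pa, pb])) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(pa, pb, equal_var=not welch)
        tests.append({"group_a": ga, "group_b": gb, "t": float(t), "p": float(p), "note": ""})
    return per_rep, pd.DataFrame(tests)


@dataclass
class FoldChangeResult:
    fold: float
    ci_low: float
    ci_high: float
    n_boot: int


def fold_change(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_boot: int = 10_000,
    seed: int = 0,
    ci: float = 0.95,
) -> FoldChangeResult:
    """Ratio of means mean(B)/mean(A) with a bootstrap percentile CI."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if a.mean() <= 0:
        raise ValueError("mean of the reference condition must be positive")
    fold = float(b.mean() / a.mean())
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, a.size, size=(n_boot, a.size))
    idx_b = rng.integers(0, b.size, size=(n_boot, b.size))
    means_a = a[idx_a].mean(axis=1)
    means_b = b[idx_b].mean(axis=1)
    ok = means_a > 0
    ratios = means_b[ok] / means_a[ok]
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(ratios, [alpha, 1.0 - alpha])
    return FoldChangeResult(fold=fold, ci_low=float(lo), ci_high=float(hi), n_boot=n_boot)
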