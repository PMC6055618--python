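"""Cohort-level demographic and clinical statistics.

Group counts and one-decimal percentages, per-group means and sample SDs,
2x2 chi-square tests of seizure-onset side by language-dominance group (both
the Pearson statistic and the Yates continuity-corrected variant are exposed),
and a one-way ANOVA on handedness with Bonferroni-adjusted pairwise post-hoc
comparisons.  An ANOVA F can also be reconstructed from published summary
statistics (means, SDs, group sizes) for cross-checking reported values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import CohortTable
from .profiling import round_half_away

__all__ = [
    "CohortSummary",
    "ChiSquareResult",
    "AnovaResult",
    "summarize_cohort",
    "percentages",
    "chi_square_2x2",
    "group_anova_posthoc",
    "anova_from_summary",
]


@dataclass
class CohortSummary:
    total_n: int
    group_n: dict[str, int]
    group_percent: dict[str, float]
    group_stats: pd.DataFrame  # per group: mean/sd of age, ehi, age_of_onset, duration
    sex_counts: pd.DataFrame
    side_counts: pd.DataFrame


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    variant: str

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("chi-square statistic must be >= 0")


@dataclass
class AnovaResult:
    f: float
    df: tuple[int, int]
    p: float
    pairwise_p: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        if self.f < 0:
            raise ValueError("F must be >= 0")


def percentages(counts: dict[str, int] | list[int], total: int | None = None) -> dict | list:
    """One-decimal percentages (half away from zero) from counts."""
    if isinstance(counts, dict):
        tot = total if total is not None else sum(counts.values())
        return {k: round_half_away(100.0 * v / tot, 1) for k, v in counts.items()}
    tot = total if total is not None else sum(counts)
    return [round_half_away(100.0 * v / tot, 1) for v in counts]


def summarize_cohort(table: CohortTable) -> CohortSummary:
    """Counts, one-decimal percentages and per-group mean (SD) summaries."""
    df = table.frame
    if df.empty:
        raise ValueError("empty cohort table")
    group_n = df.groupby("hld_group").size().to_dict()
    group_percent = percentages(group_n, len(df))
    stats_rows = []
    for g, sub in df.groupby("hld_group"):
        row = {"hld_group": g, "n": len(sub)}
        for col in ("age", "ehi", "age_of_onset", "duration"):
            vals = sub[col].dropna()
            row[f"{col}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        stats_rows.append(row)
    group_stats = pd.DataFrame(stats_rows).set_index("hld_group")
    sex_counts = df.groupby(["hld_group", "sex"]).size().unstack(fill_value=0)
    side_counts = df.groupby(["hld_group", "epilepsy_side"]).size().unstack(fill_value=0)
    return CohortSummary(len(df), group_n, group_percent, group_stats, sex_counts, side_counts)


def chi_square_2x2(table, variant: str = "pearson") -> ChiSquareResult:
    """2x2 chi-square test of independence (df = 1).

    pearson: chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d));
    yates: |ad - bc| replaced by max(0, |ad - bc| - n/2) before squaring.
    """
    t = np.asarray(table, dtype=np.float64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    a, b, c, d = t.ravel()
    n = t.sum()
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("zero margin: chi-square statistic undefined")
    det = a * d - b * c
    if variant == "pearson":
        num = det**2
    elif variant == "yates":
        num = max(0.0, abs(det) - n / 2.0) ** 2
    else:
        raise ValueError(f"unknown variant: {variant}")
    chi2 = n * num / np.prod(margins)
    p = float(stats.chi2.sf(chi2, 1))
    return ChiSquareResult(float(chi2), 1, p, variant)


def group_anova_posthoc(values, groups, alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA plus Bonferroni-adjusted pairwise two-sample t-tests."""
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    split = [values[groups == g] for g in levels]
    for g, arr in zip(levels, split):
        if len(arr) < 2:
            raise ValueError(f"group {g} has fewer than 2 values")
    f, p = stats.f_oneway(*split)
    if not np.isfinite(f):
        f, p = 0.0, 1.0
    n_pairs = len(levels) * (len(levels) - 1) // 2
    pairwise = {}
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            _, p_ij = stats.ttest_ind(split[i], split[j], equal_var=True)
            pairwise[(levels[i], levels[j])] = min(1.0, float(p_ij) * n_pairs)
    dfb = len(levels) - 1
    dfw = len(values) - len(levels)
    return AnovaResult(float(f), (dfb, dfw), float(p), pairwise)


def anova_from_summary(means, sds, ns) -> float:
    """One-way ANOVA F reconstructed from per-group summary statistics.

    SSB = sum n_i (m_i - grand_mean)^2, SSW = sum (n_i - 1) s_i^2,
    F = (SSB / (k-1)) / (SSW / (N-k)).  Lets published group means/SDs be
    cross-checked against a published omnibus F (agreement is limited by the
    rounding of the printed summaries).
    """
    means = np.asarray(means, dtype=np.float64)
    sds = np.asarray(sds, dtype=np.float64)
    ns = np.asarray(ns, dtype=np.float64)
    if len(means) < 2:
        raise ValueError("need at least 2 groups")
    if (ns < 2).any():
        raise ValueError("every group must have n >= 2")
    N = ns.sum()
    k = len(means)
    grand = (ns * means).sum() / N
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds**2).sum()
    if ssw == 0:
        return float("inf") if ssb > 0 else 0.0
    return float((ssb / (k - 1)) / (ssw / (N - k)))
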