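"""Group summaries and significance tests for score comparisons.

Mirrors the reporting style of the study design this package serves: mean
and sample SD (n−1) per group for every score dimension, a one-way ANOVA
across plan sources, and an independent two-sample t-test between sexes.
Because raw per-plan data are often unpublished while summary tables are
printed, the ANOVA is also exposed as a summary-statistics entry point
(:func:`anova_from_summary`) that is exactly equivalent to the raw-data
computation:

    SS_between = Σ nᵢ (x̄ᵢ − x̄)²,   SS_within = Σ (nᵢ − 1) sᵢ²,
    F = MS_between / MS_within,     df = (k − 1, N − k).

No multiple-testing correction is applied; each dimension is tested at the
configured α on its own, which matches the reporting convention this package
reproduces and is flagged as a caveat in the package documentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, DQIIError
from .dqi_scorer import SCORE_COLUMNS

__all__ = [
    "GroupSummary",
    "TestResult",
    "summarize",
    "anova_oneway",
    "anova_from_summary",
    "ttest_two_sample",
    "compare_table",
]


@dataclass(frozen=True)
class GroupSummary:
    """Label, size, mean and sample SD (n−1 denominator) of one group."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DQIIError(f"group {self.label!r}: n must be >= 1, got {self.n}")
        if self.sd < 0:
            raise DQIIError(f"group {self.label!r}: sd must be >= 0")
        if self.n == 1 and self.sd != 0:
            raise DQIIError(f"group {self.label!r}: sd must be 0 when n = 1")

    @classmethod
    def from_values(cls, label: str, values: Sequence[float]) -> "GroupSummary":
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise DQIIError(f"group {label!r} is empty")
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return cls(label=label, n=int(arr.size), mean=float(arr.mean()), sd=sd)


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its degrees of freedom and two-sided p-value."""

    statistic: float
    df: tuple[float, float] | float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise DQIIError(f"p-value out of [0, 1]: {self.p_value}")


def summarize(
    scores: pd.DataFrame,
    factor: str,
    dimensions: Sequence[str] = SCORE_COLUMNS,
) -> pd.DataFrame:
    """Mean/SD per group and overall, for every score dimension.

    ``scores`` holds one row per plan with a ``factor`` column (``source``
    or ``sex``) and one column per score dimension.  Returns a tidy frame
    with columns [dimension, group, n, mean, sd]; the pooled sample appears
    as group "overall".
    """
    if scores.empty:
        raise DQIIError("summarize requires at least one scored plan")
    if factor not in scores.columns:
        raise DQIIError(f"factor column {factor!r} not present in scores")
    rows = []
    for dim in dimensions:
        for label, grp in scores.groupby(factor, sort=False):
            s = GroupSummary.from_values(str(label), grp[dim].to_numpy())
            rows.append({"dimension": dim, "group": s.label, "n": s.n, "mean": s.mean, "sd": s.sd})
        s = GroupSummary.from_values("overall", scores[dim].to_numpy())
        rows.append({"dimension": dim, "group": s.label, "n": s.n, "mean": s.mean, "sd": s.sd})
    return pd.DataFrame(rows)


def anova_from_summary(summaries: Sequence[GroupSummary]) -> TestResult:
    """One-way ANOVA from per-group (n, mean, sd) summaries.

    Exactly equivalent to :func:`anova_oneway` on the raw groups the
    summaries were computed from.  Every group needs n ≥ 2 so that its SD
    carries within-group information.
    """
    if len(summaries) < 2:
        raise DQIIError("ANOVA needs at least two groups")
    for s in summaries:
        if s.n < 2:
            raise DQIIError(f"group {s.label!r}: ANOVA needs n >= 2 per group")
    ns = np.array([s.n for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries], dtype=float)
    sds = np.array([s.sd for s in summaries], dtype=float)
    n_total = ns.sum()
    k = len(summaries)
    grand_mean = float((ns * means).sum() / n_total)
    ss_between = float((ns * (means - grand_mean) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df_between = k - 1
    df_within = n_total - k
    if ss_within <= 0 and ss_between <= 0:
        raise DegenerateDataError("no variance within or between groups")
    if ss_within <= 0:
        return TestResult(math.inf, (df_between, df_within), 0.0, "oneway_anova")
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f_stat, df_between, df_within))
    return TestResult(f_stat, (float(df_between), float(df_within)), p, "oneway_anova")


def anova_oneway(groups: Sequence[Sequence[float]]) -> TestResult:
    """Classical one-way ANOVA on raw per-group values."""
    if len(groups) < 2:
        raise DQIIError("ANOVA needs at least two groups")
    summaries = [GroupSummary.from_values(f"group{i}", g) for i, g in enumerate(groups)]
    return anova_from_summary(summaries)


def ttest_two_sample(
    a: Sequence[float], b: Sequence[float], variance_mode: str = "pooled"
) -> TestResult:
    """Independent two-sample t-test, two-sided.

    ``variance_mode="pooled"`` assumes equal variances (the default,
    matching common statistical-package reporting); ``"welch"`` drops that
    assumption.
    """
    if variance_mode not in ("pooled", "welch"):
        raise DQIIError(f"unknown variance_mode {variance_mode!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DQIIError("t-test needs n >= 2 in each sample")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        raise DegenerateDataError("both samples constant and equal")
    res = stats.ttest_ind(a, b, equal_var=(variance_mode == "pooled"))
    method = "t_pooled" if variance_mode == "pooled" else "t_welch"
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue), method)


def compare_table(
    scores: pd.DataFrame,
    factor: str,
    variance_mode: str = "pooled",
    alpha: float = 0.05,
    dimensions: Sequence[str] = SCORE_COLUMNS,
) -> pd.DataFrame:
    """Per-dimension group summaries with the appropriate significance test.

    One-way ANOVA for a multi-level factor (plan source), a two-sample
    t-test for a two-level factor (sex).  Returns a wide frame: one row per
    dimension with ``<group>_mean``/``<group>_sd`` columns, the test
    statistic, df, p-value and a significance flag at ``alpha``.
    """
    if factor not in scores.columns:
        raise DQIIError(f"factor column {factor!r} not present in scores")
    levels = list(dict.fromkeys(scores[factor]))
    if len(levels) < 2:
        raise DQIIError(f"factor {factor!r} needs at least two levels")
    rows = []
    for dim in dimensions:
        groups = [scores.loc[scores[factor] == lvl, dim].to_numpy() for lvl in levels]
        row: dict = {"dimension": dim}
        for lvl, g in zip(levels, groups):
            s = GroupSummary.from_values(str(lvl), g)
            row[f"{lvl}_n"] = s.n
            row[f"{lvl}_mean"] = s.mean
            row[f"{lvl}_sd"] = s.sd
        try:
            if len(levels) == 2:
                res = ttest_two_sample(groups[0], groups[1], variance_mode)
            else:
                res = anova_oneway(groups)
            row.update(
                statistic=res.statistic,
                df=str(res.df),
                p_value=res.p_value,
                method=res.method,
                significant=bool(res.p_value < alpha),
            )
        except DegenerateDataError:
            row.update(statistic=np.nan, df="", p_value=np.nan, method="degenerate", significant=False)
        rows.append(row)
    return pd.DataFrame(rows)
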