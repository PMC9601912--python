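"""Two-group inferential layer: group summaries, Levene's test, and
independent-samples t-tests (pooled and Welch) with 95% confidence
intervals, mirroring the classic SPSS "Group Statistics" /
"Independent Samples Test" paired output.

Both t-test variants are computed from summary statistics (n, mean, sample
SD) alone, because published studies typically print summaries rather than
raw data.  Levene's test, by contrast, genuinely requires raw per-subject
values (it is a one-way ANOVA on absolute deviations from each group's
mean), and is honestly reported as unavailable when only summaries exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    GroupingError,
    InsufficientDataError,
    SummaryInputError,
    UndefinedTTestError,
)


@dataclass(frozen=True)
class GroupSummary:
    """n, mean, sample SD (n-1 denominator), and SEM = sd/sqrt(n)."""

    n: int
    mean: float
    sd: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InsufficientDataError(f"need n >= 2, got n = {self.n}")
        if self.sd < 0:
            raise InsufficientDataError("standard deviation must be nonnegative")

    @property
    def sem(self) -> float:
        return self.sd / math.sqrt(self.n)

    @property
    def var(self) -> float:
        return self.sd * self.sd


def group_summary(values: Iterable[float], label: str = "") -> GroupSummary:
    """Summarize raw values: n, mean, sample (n-1) SD."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(f"need at least 2 values, got {arr.size}")
    return GroupSummary(n=int(arr.size), mean=float(arr.mean()),
                        sd=float(arr.std(ddof=1)), label=label)


@dataclass(frozen=True)
class TTestResult:
    """One row of the 'T-Test for Equality of Means' block."""

    variant: str  # "pooled" or "welch"
    t: float
    df: float
    p_two_tailed: float
    mean_diff: float
    se_diff: float
    ci_low: float
    ci_high: float
    conf: float = 0.95


@dataclass(frozen=True)
class LeveneResult:
    """Levene's test for equality of variances (mean-centered)."""

    F: float
    p: float
    center: str = "mean"


def two_tailed_p(t: float, df: float) -> float:
    """Two-sided p-value from the central t distribution."""
    if df <= 0:
        raise InsufficientDataError(f"degrees of freedom must be positive, got {df}")
    return float(2.0 * sps.t.sf(abs(t), df))


def _finish(variant: str, mean_diff: float, se: float, df: float, conf: float) -> TTestResult:
    if se == 0.0:
        if mean_diff == 0.0:
            raise UndefinedTTestError(
                "zero standard error and zero mean difference: t undefined"
            )
        t = math.inf if mean_diff > 0 else -math.inf
        return TTestResult(variant, t, df, 0.0, mean_diff, se, mean_diff, mean_diff, conf)
    t = mean_diff / se
    p = two_tailed_p(t, df)
    half = float(sps.t.ppf(0.5 + conf / 2.0, df)) * se
    return TTestResult(variant, t, df, p, mean_diff, se,
                       mean_diff - half, mean_diff + half, conf)


def pooled_t_test(s1: GroupSummary, s2: GroupSummary, conf: float = 0.95) -> TTestResult:
    """Equal-variances-assumed t-test from summaries (df = n1 + n2 - 2)."""
    df = s1.n + s2.n - 2
    sp2 = ((s1.n - 1) * s1.var + (s2.n - 1) * s2.var) / df
    se = math.sqrt(sp2 * (1.0 / s1.n + 1.0 / s2.n))
    return _finish("pooled", s1.mean - s2.mean, se, float(df), conf)


def welch_t_test(s1: GroupSummary, s2: GroupSummary, conf: float = 0.95) -> TTestResult:
    """Unequal-variances t-test with Welch-Satterthwaite degrees of freedom."""
    v1, v2 = s1.var / s1.n, s2.var / s2.n
    se = math.sqrt(v1 + v2)
    if se == 0.0:
        return _finish("welch", s1.mean - s2.mean, se, float(s1.n + s2.n - 2), conf)
    df = (v1 + v2) ** 2 / (v1 * v1 / (s1.n - 1) + v2 * v2 / (s2.n - 1))
    return _finish("welch", s1.mean - s2.mean, se, float(df), conf)


def levene_test(group1, group2, center: str = "mean") -> LeveneResult:
    """Levene's test on two groups of RAW values (mean-centered).

    Equivalent to a one-way ANOVA on absolute deviations from each group's
    mean.  Raises :class:`SummaryInputError` when given summaries instead of
    raw data — the statistic is not computable from n/mean/SD alone.
    """
    if isinstance(group1, GroupSummary) or isinstance(group2, GroupSummary):
        raise SummaryInputError(
            "Levene's test needs raw per-subject values; it cannot be computed "
            "from n/mean/SD summaries"
        )
    if center != "mean":
        raise SummaryInputError(f"only mean-centered Levene is supported, got {center!r}")
    g1 = np.asarray(list(group1), dtype=float)
    g2 = np.asarray(list(group2), dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise InsufficientDataError("each group needs at least 2 raw values")
    if np.ptp(g1) == 0.0 and np.ptp(g2) == 0.0:
        # both groups constant: variances are 0 in both, trivially equal
        return LeveneResult(F=0.0, p=1.0, center="mean")
    F, p = sps.levene(g1, g2, center="mean")
    return LeveneResult(F=float(F), p=float(p), center="mean")


@dataclass(frozen=True)
class MeasureComparison:
    """All inferential output for one measure: summaries, Levene, both t-tests.

    ``pooled``/``welch`` are None for the degenerate case where both groups
    are identical constants (t = 0/0 undefined); ``levene`` is None when only
    summaries were available.
    """

    measure: str
    summary1: GroupSummary
    summary2: GroupSummary
    pooled: TTestResult | None
    welch: TTestResult | None
    levene: LeveneResult | None


def compare_from_summaries(
    measure: str, s1: GroupSummary, s2: GroupSummary, conf: float = 0.95
) -> MeasureComparison:
    """Summaries-only path: both t-tests; Levene honestly unavailable."""
    return MeasureComparison(
        measure=measure,
        summary1=s1,
        summary2=s2,
        pooled=pooled_t_test(s1, s2, conf),
        welch=welch_t_test(s1, s2, conf),
        levene=None,
    )


def compare_groups(
    measure: str,
    values1: Iterable[float],
    values2: Iterable[float],
    label1: str = "",
    label2: str = "",
    conf: float = 0.95,
) -> MeasureComparison:
    """Raw-data path: summaries, Levene, and both t-tests."""
    v1 = list(values1)
    v2 = list(values2)
    s1 = group_summary(v1, label1)
    s2 = group_summary(v2, label2)
    try:
        pooled = pooled_t_test(s1, s2, conf)
        welch = welch_t_test(s1, s2, conf)
    except UndefinedTTestError:
        pooled = welch = None  # both groups identical constants
    return MeasureComparison(
        measure=measure,
        summary1=s1,
        summary2=s2,
        pooled=pooled,
        welch=welch,
        levene=levene_test(v1, v2),
    )


def independent_samples_table(
    cohort,
    score_columns: Sequence[str],
    grouping_column: str,
    conf: float = 0.95,
) -> list[MeasureComparison]:
    """Run every measure of a cohort table through the two-group comparison.

    ``cohort`` may be a pandas DataFrame or an iterable of objects with the
    named attributes (e.g. :class:`~spiraldst.trace_io.CohortRecord`).  The
    grouping column must have exactly two levels; levels are ordered by
    first appearance so "group 1 minus group 2" is well defined.
    """
    if not isinstance(cohort, pd.DataFrame):
        cohort = pd.DataFrame([vars(r) for r in cohort])
    if grouping_column not in cohort.columns:
        raise GroupingError(f"no such grouping column {grouping_column!r}")
    levels = list(dict.fromkeys(cohort[grouping_column]))
    if len(levels) != 2:
        raise GroupingError(
            f"grouping column {grouping_column!r} has {len(levels)} level(s); "
            "exactly 2 required"
        )
    l1, l2 = levels
    out = []
    for col in score_columns:
        v1 = cohort.loc[cohort[grouping_column] == l1, col].to_numpy(dtype=float)
        v2 = cohort.loc[cohort[grouping_column] == l2, col].to_numpy(dtype=float)
        out.append(compare_groups(col, v1, v2, str(l1), str(l2), conf))
    return out


# ---------------------------------------------------------------------------
# Report formatting: the classic paired-table layout, at the display
# precisions of the published tables (means/SDs 4 dp, t/df 3 dp, Sig. 3 dp).
# ---------------------------------------------------------------------------

def _fmt(x: float, nd: int) -> str:
    return f"{x:.{nd}f}"


def format_group_statistics(comparisons: Sequence[MeasureComparison]) -> str:
    lines = ["Group Statistics", ""]
    header = f"{'Measure':<10}{'Group':<12}{'N':>4}{'Mean':>16}{'Std. Deviation':>16}{'SEM':>12}"
    lines.append(header)
    lines.append("-" * len(header))
    for c in comparisons:
        for s in (c.summary1, c.summary2):
            lines.append(
                f"{c.measure:<10}{s.label:<12}{s.n:>4}"
                f"{_fmt(s.mean, 4):>16}{_fmt(s.sd, 4):>16}{_fmt(s.sem, 4):>12}"
            )
    return "\n".join(lines) + "\n"


def format_independent_samples(comparisons: Sequence[MeasureComparison]) -> str:
    lines = ["Independent Samples Test", ""]
    header = (
        f"{'Measure':<10}{'Variances':<14}{'Levene F':>10}{'Sig.':>8}"
        f"{'t':>10}{'df':>10}{'Sig.(2)':>9}{'Mean Diff':>16}{'SE Diff':>14}"
        f"{'CI low':>16}{'CI high':>16}"
    )
    lines.append(header)
    lines.append("-" * len(header))
    for c in comparisons:
        lev_f = _fmt(c.levene.F, 3) if c.levene else "n/a"
        lev_p = _fmt(c.levene.p, 3) if c.levene else "n/a"
        for tag, row, lf, lp in (
            ("equal", c.pooled, lev_f, lev_p),
            ("unequal", c.welch, "", ""),
        ):
            if row is None:
                lines.append(
                    f"{c.measure:<10}{tag:<14}{lf:>10}{lp:>8}"
                    "  t undefined (both groups identical constants)"
                )
                continue
            lines.append(
                f"{c.measure:<10}{tag:<14}{lf:>10}{lp:>8}"
                f"{_fmt(row.t, 3):>10}{_fmt(row.df, 3):>10}{_fmt(row.p_two_tailed, 3):>9}"
                f"{_fmt(row.mean_diff, 4):>16}{_fmt(row.se_diff, 4):>14}"
                f"{_fmt(row.ci_low, 4):>16}{_fmt(row.ci_high, 4):>16}"
            )
    return "\n".join(lines) + "\n"


def comparisons_to_dataframe(comparisons: Sequence[MeasureComparison]) -> pd.DataFrame:
    """Flatten comparisons to one row per (measure, variant) for CSV export."""
    rows = []
    for c in comparisons:
        for row in (c.pooled, c.welch):
            if row is None:
                rows.append(
                    {"measure": c.measure, "variant": "undefined",
                     "group1": c.summary1.label, "n1": c.summary1.n,
                     "mean1": c.summary1.mean, "sd1": c.summary1.sd,
                     "group2": c.summary2.label, "n2": c.summary2.n,
                     "mean2": c.summary2.mean, "sd2": c.summary2.sd,
                     "levene_F": c.levene.F if c.levene else np.nan,
                     "levene_p": c.levene.p if c.levene else np.nan,
                     "t": np.nan, "df": np.nan, "p_two_tailed": np.nan,
                     "mean_diff": np.nan, "se_diff": np.nan,
                     "ci_low": np.nan, "ci_high": np.nan}
                )
                continue
            rows.append(
                {
                    "measure": c.measure,
                    "variant": row.variant,
                    "group1": c.summary1.label,
                    "n1": c.summary1.n,
                    "mean1": c.summary1.mean,
                    "sd1": c.summary1.sd,
                    "group2": c.summary2.label,
                    "n2": c.summary2.n,
                    "mean2": c.summary2.mean,
                    "sd2": c.summary2.sd,
                    "levene_F": c.levene.F if c.levene else np.nan,
                    "levene_p": c.levene.p if c.levene else np.nan,
                    "t": row.t,
                    "df": row.df,
                    "p_two_tailed": row.p_two_tailed,
                    "mean_diff": row.mean_diff,
                    "se_diff": row.se_diff,
                    "ci_low": row.ci_low,
                    "ci_high": row.ci_high,
                }
            )
    return pd.DataFrame(rows)
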