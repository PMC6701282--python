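"""Demographic group comparisons: Welch t-tests and Monte-Carlo chi-square.

Continuous variables (age, MADRS total, NIHSS) are compared between the
low and high symptom groups with the unequal-variance (Welch) two-sample
t-test, which can be computed from published summary statistics alone.
Binary variables (sex, depression history, antidepressant use, item-level
symptom flags) are compared with the Pearson chi-square statistic on the
2x2 table, without continuity correction, and a Monte-Carlo p-value
obtained by reshuffling group labels with fixed margins (the
hypergeometric null), using the (1+b)/(1+m) estimator so p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from falffpipe.cohort import CohortTable


@dataclass(frozen=True)
class TwoSampleSummary:
    """Summary statistics (n, mean, SD) for two independent groups."""

    n1: int
    mean1: float
    sd1: float
    n2: int
    mean2: float
    sd2: float

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("Welch t-test needs at least 2 observations per group")
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 count table; rows are outcomes, columns are groups."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def welch_t(summary: TwoSampleSummary) -> tuple[float, float, float]:
    """Welch two-sample t-test from summary statistics.

    Returns ``(t, df, p)`` with ``t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2)``,
    Welch-Satterthwaite degrees of freedom, and a two-sided p-value.
    """
    v1 = summary.sd1**2 / summary.n1
    v2 = summary.sd2**2 / summary.n2
    if v1 + v2 == 0:
        raise ValueError("zero variance in both groups: t undefined")
    t = (summary.mean1 - summary.mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (summary.n1 - 1) + v2**2 / (summary.n2 - 1))
    p = 2.0 * sp_stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def chisq_2x2(table: ContingencyTable2x2) -> float:
    """Pearson chi-square statistic of a 2x2 table, no continuity correction."""
    arr = table.to_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("table has a zero marginal")
    statistic, _, _, _ = sp_stats.chi2_contingency(arr, correction=False)
    return float(statistic)


def simulate_p(
    table: ContingencyTable2x2,
    n_reshuffles: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Monte-Carlo p-value for the chi-square statistic with fixed margins.

    Group labels are reshuffled ``n_reshuffles`` times, equivalent to
    drawing the (1,1) cell from the hypergeometric distribution implied by
    the margins; ``p = (1 + #{chi2* >= chi2_obs}) / (1 + n_reshuffles)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = chisq_2x2(table)
    row1 = table.a + table.b
    col1 = table.a + table.c
    total = table.a + table.b + table.c + table.d
    a_sim = rng.hypergeometric(col1, total - col1, row1, size=n_reshuffles).astype(float)
    b_sim = row1 - a_sim
    c_sim = col1 - a_sim
    d_sim = total - row1 - c_sim
    expected = np.outer([row1, total - row1], [col1, total - col1]) / total
    with np.errstate(invalid="ignore", divide="ignore"):
        chi_sim = (
            (a_sim - expected[0, 0]) ** 2 / expected[0, 0]
            + (b_sim - expected[0, 1]) ** 2 / expected[0, 1]
            + (c_sim - expected[1, 0]) ** 2 / expected[1, 0]
            + (d_sim - expected[1, 1]) ** 2 / expected[1, 1]
        )
    exceed = int(np.sum(chi_sim >= observed - 1e-12))
    return (1 + exceed) / (1 + n_reshuffles)


def _group_summary(frame: pd.DataFrame, column: str) -> TwoSampleSummary:
    low = frame.loc[frame["group"] == "low", column]
    high = frame.loc[frame["group"] == "high", column]
    return TwoSampleSummary(
        n1=len(low), mean1=float(low.mean()), sd1=float(low.std(ddof=1)),
        n2=len(high), mean2=float(high.mean()), sd2=float(high.std(ddof=1)),
    )


def _group_counts(frame: pd.DataFrame, column: str) -> ContingencyTable2x2:
    sub = frame.dropna(subset=[column])
    low = sub[sub["group"] == "low"][column].astype(bool)
    high = sub[sub["group"] == "high"][column].astype(bool)
    return ContingencyTable2x2(
        a=int(low.sum()), b=int(high.sum()),
        c=int((~low).sum()), d=int((~high).sum()),
    )


def cohort_report(
    cohort: CohortTable,
    n_reshuffles: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Demographic comparison table for a loaded cohort.

    One row per variable: per-group n and mean(SD) or yes-counts, the
    Welch t (continuous) or chi-square (binary) statistic, and its
    p-value (Monte-Carlo with fixed margins for the binary rows).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frame = cohort.to_frame()
    if frame["group"].nunique() < 2:
        raise ValueError("cohort report needs both groups present")
    rows = []
    for column in ("age", "madrs_total", "nihss"):
        s = _group_summary(frame, column)
        t, df, p = welch_t(s)
        rows.append(
            {
                "variable": column,
                "low": f"{s.mean1:.2f} ({s.sd1:.2f})",
                "high": f"{s.mean2:.2f} ({s.sd2:.2f})",
                "test": "welch_t",
                "statistic": t,
                "df": df,
                "p": p,
            }
        )
    binary_columns = ["history_depression", "antidepressant"]
    if (frame["sex"].nunique()) > 1:
        frame = frame.assign(is_female=frame["sex"] == "female")
        binary_columns = ["is_female"] + binary_columns
    for column in (
        "reported_sadness",
        "reported_discouragement",
        "reported_loss_of_interest",
    ):
        if column in frame.columns and frame[column].notna().any():
            binary_columns.append(column)
    for column in binary_columns:
        table = _group_counts(frame, column)
        try:
            statistic = chisq_2x2(table)
            p = simulate_p(table, n_reshuffles=n_reshuffles, seed=rng)
        except ValueError:
            statistic, p = 0.0, 1.0
        rows.append(
            {
                "variable": column,
                "low": f"{table.a}/{table.a + table.c}",
                "high": f"{table.b}/{table.b + table.d}",
                "test": "chisq_mc",
                "statistic": statistic,
                "df": np.nan,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def render_report(report: pd.DataFrame) -> str:
    """Aligned plain-text rendering of a :func:`cohort_report` table."""
    lines = [f"{'variable':<28}{'low':>16}{'high':>16}{'test':>10}{'stat':>8}{'p':>8}"]
    for _, row in report.iterrows():
        lines.append(
            f"{row['variable']:<28}{row['low']:>16}{row['high']:>16}"
            f"{row['test']:>10}{row['statistic']:>8.2f}{row['p']:>8.3f}"
        )
    return "\n".join(lines)
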