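"""Cohort-level descriptive statistics and power analysis.

Two-sample tests from printed summary statistics (mean +/- SD per class),
exact/chi-square tests on 2x2 count tables, and the two-proportion
sample-size formula used to judge how large a confirmatory cohort would
need to be.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryStats",
    "PowerParams",
    "Table2x2",
    "ttest_from_summary",
    "exact_test_2x2",
    "required_sample_size",
    "demographic_report",
]


@dataclass(frozen=True)
class SummaryStats:
    """Mean, sample standard deviation and group size of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("summary statistics require n >= 2")
        if not self.sd > 0:
            raise ValueError("sd must be positive")


@dataclass(frozen=True)
class PowerParams:
    """Inputs of the two-proportion sample-size formula.

    p1, p2
        Expected proportions in the two groups.
    E
        Margin of error (half-width of the confidence interval).
    Z
        Z-score of the confidence level (1.96 for 95%).
    """

    p1: float
    p2: float
    E: float
    Z: float = 1.96

    def __post_init__(self) -> None:
        for p in (self.p1, self.p2):
            if not 0.0 <= p <= 1.0:
                raise ValueError("proportions must be in [0, 1]")
        if not self.E > 0:
            raise ValueError("margin of error E must be positive")
        if not self.Z > 0:
            raise ValueError("Z must be positive")


@dataclass(frozen=True)
class Table2x2:
    """2x2 contingency table of counts [[a, b], [c, d]]."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is all zero")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def ttest_from_summary(
    g1: SummaryStats, g2: SummaryStats, variant: str = "student"
) -> tuple[float, float, float]:
    """Two-sample t-test from per-group summary statistics.

    Parameters
    ----------
    g1, g2
        Group summaries (mean, sample SD, n).
    variant
        ``"student"`` for the pooled-variance test, ``"welch"`` for the
        unequal-variance test.

    Returns
    -------
    (t, df, p)
        Test statistic, degrees of freedom and two-sided p-value.
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant: {variant!r}")
    res = stats.ttest_ind_from_stats(
        mean1=g1.mean,
        std1=g1.sd,
        nobs1=g1.n,
        mean2=g2.mean,
        std2=g2.sd,
        nobs2=g2.n,
        equal_var=(variant == "student"),
    )
    t = float(res.statistic)
    p = float(res.pvalue)
    if variant == "student":
        df = float(g1.n + g2.n - 2)
    else:
        v1 = g1.sd**2 / g1.n
        v2 = g2.sd**2 / g2.n
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    return t, df, p


def exact_test_2x2(t: Table2x2, method: str = "fisher") -> float:
    """Two-sided p-value for independence in a 2x2 table.

    The default is Fisher's exact test (the sum of hypergeometric
    probabilities no larger than that of the observed table); a
    chi-square variant without continuity correction is available via
    ``method="chi2"``.
    """
    if method == "fisher":
        return float(stats.fisher_exact(t.as_array(), alternative="two-sided")[1])
    if method == "chi2":
        res = stats.chi2_contingency(t.as_array(), correction=False)
        return float(res.pvalue)
    raise ValueError(f"unknown method: {method!r}")


def required_sample_size(pp: PowerParams) -> tuple[float, int, int]:
    """Per-group and total sample size for comparing two proportions.

    Ni = (p1 (1 - p1) + p2 (1 - p2)) / E^2 * Z^2

    Returns the raw per-group value, its floor, and the total over both
    groups (2 * floor(per-group)).
    """
    per_group = (pp.p1 * (1 - pp.p1) + pp.p2 * (1 - pp.p2)) / pp.E**2 * pp.Z**2
    per_group_int = math.floor(per_group)
    return per_group, per_group_int, 2 * per_group_int


def demographic_report(
    demographics: pd.DataFrame,
    label_col: str = "label",
    variant: str = "student",
    gender_method: str = "fisher",
) -> dict:
    """Per-class demographic summary with between-class p-values.

    Expects columns ``age``, ``tumour_size_cm``, ``sex`` (category with
    values "M"/"F") and a binary class column. Returns per-class
    mean +/- sd for the continuous variables, sex counts with
    percentages, and p-values from :func:`ttest_from_summary` and
    :func:`exact_test_2x2`.
    """
    labels = sorted(demographics[label_col].unique().tolist())
    if len(labels) != 2:
        raise ValueError("demographic report requires exactly two classes")
    groups = {lab: demographics[demographics[label_col] == lab] for lab in labels}
    for lab, g in groups.items():
        if len(g) < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 patients")

    report: dict = {"classes": labels, "n": {lab: int(len(g)) for lab, g in groups.items()}}
    for col in ("age", "tumour_size_cm"):
        summaries = {
            lab: SummaryStats(float(g[col].mean()), float(g[col].std(ddof=1)), len(g))
            for lab, g in groups.items()
        }
        _, _, p = ttest_from_summary(summaries[labels[0]], summaries[labels[1]], variant)
        report[col] = {
            lab: {"mean": s.mean, "sd": s.sd} for lab, s in summaries.items()
        }
        report[col]["p_value"] = p

    sex_counts = {
        lab: {
            "M": int((g["sex"] == "M").sum()),
            "F": int((g["sex"] == "F").sum()),
        }
        for lab, g in groups.items()
    }
    table = Table2x2(
        sex_counts[labels[0]]["M"],
        sex_counts[labels[0]]["F"],
        sex_counts[labels[1]]["M"],
        sex_counts[labels[1]]["F"],
    )
    sex_report = {}
    for lab in labels:
        n = report["n"][lab]
        sex_report[lab] = {
            s: {"count": c, "percent": round(100.0 * c / n, 2)}
            for s, c in sex_counts[lab].items()
        }
    sex_report["p_value"] = exact_test_2x2(table, gender_method)
    report["sex"] = sex_report
    return report
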