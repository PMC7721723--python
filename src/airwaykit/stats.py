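"""Welch's unequal-variance t-test from raw samples or printed summary statistics.

Group comparisons in small-animal morphometry are routinely reported as
(mean, SD, n) per group with a Welch P value; this module computes the test
both from raw per-animal values and directly from such printed summaries so
published tables can be re-analyzed without the raw data.

The statistic and Welch–Satterthwaite degrees of freedom are

    t  = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2)
    df = (s1^2/n1 + s2^2/n2)^2 /
         [ (s1^2/n1)^2/(n1-1) + (s2^2/n2)^2/(n2-1) ]

with a two-sided P value from the t distribution with df (real-valued)
degrees of freedom.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError

__all__ = [
    "GroupSummary",
    "WelchResult",
    "welch_from_summary",
    "welch_from_samples",
    "comparison_report",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Per-group summary statistics as printed in a results table."""

    mean: float
    sd: float
    n: int
    units: str | None = None

    def __post_init__(self):
        if self.sd < 0:
            raise InputError("standard deviation must be non-negative")
        if int(self.n) != self.n or self.n < 2:
            raise InputError("group size must be an integer >= 2")


@dataclass(frozen=True)
class WelchResult:
    """Welch test outcome: statistic, Satterthwaite df, two-sided P."""

    t_statistic: float
    df: float
    p_two_sided: float

    @property
    def significant_at_0_05(self) -> bool:
        return self.p_two_sided < ALPHA


def welch_from_summary(g1: GroupSummary, g2: GroupSummary) -> WelchResult:
    """Welch's t-test computed from (mean, sd, n) of each group.

    Degenerate inputs: if both SDs are zero the test is decided by the means
    alone — equal means give ``t = 0, p = 1``; unequal means give ``p = 0``
    with a degenerate-variance warning.
    """
    v1 = g1.sd**2 / g1.n
    v2 = g2.sd**2 / g2.n
    se2 = v1 + v2
    if se2 == 0.0:
        if g1.mean == g2.mean:
            return WelchResult(0.0, float(g1.n + g2.n - 2), 1.0)
        warnings.warn("both groups have zero variance but unequal means; p = 0")
        t = np.inf if g1.mean > g2.mean else -np.inf
        return WelchResult(float(t), float(g1.n + g2.n - 2), 0.0)
    t = (g1.mean - g2.mean) / np.sqrt(se2)
    df = se2**2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(min(p, 1.0)))


def summarize_sample(x) -> GroupSummary:
    """(mean, SD, n) of a raw sample; SD uses the n-1 denominator."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InputError("sample must be 1-D with at least 2 observations")
    return GroupSummary(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=int(x.size))


def welch_from_samples(x, y) -> WelchResult:
    """Welch's t-test from raw samples; identical to the summary route."""
    return welch_from_summary(summarize_sample(x), summarize_sample(y))


def welch_from_summary_arrays(m1, s1, n1, m2, s2, n2):
    """Vectorized Welch test over aligned arrays; returns (t, df, p).

    Used by simulation studies (type-I error / power over thousands of
    replicate cohorts) where per-replicate object construction would dominate.
    """
    m1, s1, m2, s2 = (np.asarray(a, dtype=float) for a in (m1, s1, m2, s2))
    v1 = s1**2 / n1
    v2 = s2**2 / n2
    se2 = v1 + v2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, df, p


def comparison_report(metric_table, alpha: float = ALPHA, holm: bool = False) -> pd.DataFrame:
    """Per-metric Welch comparison rows from a summary table.

    Parameters
    ----------
    metric_table
        Mapping ``metric -> (mean1, sd1, n1, mean2, sd2, n2)`` or a DataFrame
        with columns ``metric, mean1, sd1, n1, mean2, sd2, n2``.
    holm
        Optionally append Holm-adjusted P values (off by default: published
        small-cohort tables of this kind report unadjusted P).
    """
    if isinstance(metric_table, pd.DataFrame):
        rows = [
            (r["metric"], r["mean1"], r["sd1"], r["n1"], r["mean2"], r["sd2"], r["n2"])
            for _, r in metric_table.iterrows()
        ]
    else:
        rows = [(k, *v) for k, v in metric_table.items()]
    out = []
    for metric, m1, s1, n1, m2, s2, n2 in rows:
        res = welch_from_summary(GroupSummary(m1, s1, int(n1)), GroupSummary(m2, s2, int(n2)))
        out.append(
            dict(
                metric=metric,
                mean1=m1, sd1=s1, n1=int(n1),
                mean2=m2, sd2=s2, n2=int(n2),
                t=res.t_statistic, df=res.df, p=res.p_two_sided,
                significant=res.p_two_sided < alpha,
            )
        )
    report = pd.DataFrame(out)
    if holm and len(report):
        from statsmodels.stats.multitest import multipletests

        report["p_holm"] = multipletests(report["p"].to_numpy(), method="holm")[1]
        report["significant_holm"] = report["p_holm"] < alpha
    return report
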