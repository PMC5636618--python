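"""Group-comparison statistics: t-tests from summary data and one-way ANOVA.

Published group results are often available only as mean +/- SD with n; the
two-sample t-test here is computed directly from those summaries (pooled
Student by default, Welch selectable).  No multiple-testing adjustment is
applied, matching the unadjusted pairwise reporting convention of the source
study design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["GroupSummary", "TTestResult", "AnovaResult", "t_test_from_summary", "anova_oneway"]


@dataclass(frozen=True)
class GroupSummary:
    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    @classmethod
    def from_sample(cls, label: str, values) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        return cls(label, float(np.mean(v)), float(np.std(v, ddof=1)), len(v))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    variant: str


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float


def t_test_from_summary(
    a: GroupSummary, b: GroupSummary, variant: str = "pooled"
) -> TTestResult:
    """Two-sided two-sample t-test from means/SDs/n alone.

    Degenerate convention (documented): if both SDs are zero the p-value is 1
    for equal means and 0 otherwise.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if a.sd == 0 and b.sd == 0:
        equal = a.mean == b.mean
        df = a.n + b.n - 2
        return TTestResult(0.0 if equal else np.inf, df, 1.0 if equal else 0.0, variant)
    res = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = float(a.n + b.n - 2)
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return TTestResult(float(res.statistic), float(df), float(res.pvalue), variant)


def anova_oneway(groups) -> AnovaResult:
    """One-way ANOVA F-test across a list of raw samples."""
    samples = [np.asarray(g, dtype=float) for g in groups]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in samples):
        raise ValueError("each group needs n >= 2")
    k = len(samples)
    n_total = sum(len(g) for g in samples)
    if np.ptp(np.concatenate(samples)) == 0:
        return AnovaResult(0.0, k - 1, n_total - k, 1.0)
    res = sps.f_oneway(*samples)
    f = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(f):  # zero within-group variance with equal means
        f, p = 0.0, 1.0
    return AnovaResult(f, k - 1, n_total - k, p)
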