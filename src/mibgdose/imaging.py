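"""DCE-MRI enhancement quantification and slice-stack tumour volumes.

Normalised enhancement expresses the T1 signal relative to the pre-injection
baseline, n(t) = (S(t) - S_pre) / S_pre with S_pre the mean of all
pre-injection samples; the per-session summary is the mean (optionally peak)
of n(t) over the post-injection window.  Session contrasts (e.g. baseline vs
24 h after external-beam irradiation) are tested with a paired t-test by
default, since the same animals are imaged longitudinally.

Tumour volume follows the slice-summation rule: sum of per-slice delineated
areas times the slice thickness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "EnhancementCurve",
    "NormalizedEnhancement",
    "SliceStack",
    "ContrastResult",
    "normalize_enhancement",
    "permeability_contrast",
    "volume_from_slices",
]


@dataclass(frozen=True)
class EnhancementCurve:
    """Raw DCE signal series; ``injection_index`` is the first post-injection frame."""

    times_s: tuple[float, ...]
    signal: tuple[float, ...]
    injection_index: int
    region: str = "tumour"
    animal_id: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s)
        if len(t) != len(self.signal):
            raise ValueError("times and signal differ in length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not 0 < self.injection_index < len(t):
            raise ValueError("injection index must lie inside the series")
        if np.any(np.asarray(self.signal) < 0):
            raise ValueError("signal must be nonnegative")

    @classmethod
    def from_arrays(cls, times_s, signal, injection_index, **kw) -> "EnhancementCurve":
        return cls(tuple(map(float, times_s)), tuple(map(float, signal)), int(injection_index), **kw)


@dataclass(frozen=True)
class NormalizedEnhancement:
    times_s: tuple[float, ...]
    normalized: tuple[float, ...]
    injection_index: int
    summary: float
    summary_statistic: str = "mean"


@dataclass(frozen=True)
class SliceStack:
    """Per-slice tumour areas (mm^2) at a common slice thickness (mm)."""

    areas_mm2: tuple[float, ...]
    slice_thickness_mm: float

    def __post_init__(self) -> None:
        if len(self.areas_mm2) < 1:
            raise ValueError("need at least one slice")
        if any(a < 0 for a in self.areas_mm2):
            raise ValueError("slice areas must be nonnegative")
        if not self.slice_thickness_mm > 0:
            raise ValueError("slice thickness must be positive")


def normalize_enhancement(
    curve: EnhancementCurve,
    method: str = "relative",
    summary_statistic: str = "mean",
) -> NormalizedEnhancement:
    """Baseline-normalise a DCE series and summarise the post-injection window.

    ``method="relative"`` gives (S - S_pre)/S_pre (zero at baseline, scale
    free); ``method="ratio"`` gives S/S_pre.  The summary is the mean (or
    ``"peak"``) of the normalised values from the injection frame to the end
    of the series.
    """
    if method not in ("relative", "ratio"):
        raise ValueError("method must be 'relative' or 'ratio'")
    if summary_statistic not in ("mean", "peak"):
        raise ValueError("summary_statistic must be 'mean' or 'peak'")
    s = np.asarray(curve.signal, dtype=float)
    i0 = curve.injection_index
    if i0 < 2:
        raise ValueError("need at least 2 pre-injection samples")
    baseline = float(np.mean(s[:i0]))
    if baseline == 0:
        raise ZeroDivisionError("pre-injection baseline mean is zero")
    norm = (s - baseline) / baseline if method == "relative" else s / baseline
    post = norm[i0:]
    summary = float(np.max(post)) if summary_statistic == "peak" else float(np.mean(post))
    return NormalizedEnhancement(
        curve.times_s, tuple(norm), i0, summary, summary_statistic
    )


@dataclass(frozen=True)
class ContrastResult:
    mean_difference: float
    t: float
    df: float
    p: float
    paired: bool


def permeability_contrast(
    summaries_a, summaries_b, paired: bool = True
) -> ContrastResult:
    """Compare per-animal enhancement summaries between two sessions.

    Paired two-sided t-test by default (same animals imaged longitudinally);
    set ``paired=False`` for independent groups.  Returns the mean difference
    (b - a) and the p-value.
    """
    a = np.asarray(summaries_a, dtype=float)
    b = np.asarray(summaries_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each session needs at least 2 summaries")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires matched lengths")
        diff = b - a
        if np.allclose(diff, 0.0):
            return ContrastResult(0.0, 0.0, len(a) - 1, 1.0, True)
        res = sps.ttest_rel(b, a)
        return ContrastResult(float(np.mean(diff)), float(res.statistic), float(len(a) - 1), float(res.pvalue), True)
    res = sps.ttest_ind(b, a, equal_var=True)
    return ContrastResult(
        float(np.mean(b) - np.mean(a)),
        float(res.statistic),
        float(len(a) + len(b) - 2),
        float(res.pvalue),
        False,
    )


def volume_from_slices(stack: SliceStack) -> float:
    """Tumour volume (mm^3) = sum of slice areas x slice thickness."""
    return float(np.sum(stack.areas_mm2) * stack.slice_thickness_mm)
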