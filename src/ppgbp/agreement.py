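"""Method-comparison statistics for paired measurements.

Three classical tools for comparing two measurement methods (or two
conditions) without designating either as ground truth:

* **Geometric mean regression** (reduced major axis): the symmetric
  regression line with slope sign(r) * SD(y) / SD(x), appropriate when
  both variables carry measurement error. Swapping x and y inverts the
  slope, a symmetry ordinary least squares lacks.
* **Bland-Altman analysis**: differences (second minus first argument)
  against pairwise averages; fixed bias = mean difference, with agreement
  limits at bias +/- k * SD(differences). The default multiplier is 1
  (the convention used in pulse-app validation figures); pass
  ``limit_multiplier=1.96`` for the conventional 95% limits.
* **Paired comparison**: two-sided paired t-test plus Cohen's d in the
  pooled-SD form d = (mean(b) - mean(a)) / sqrt((SD(a)^2 + SD(b)^2) / 2),
  also available directly from summary statistics.

Sample SDs use the n-1 denominator throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInput, UnpairedData

__all__ = [
    "AgreementReport",
    "EffectSizeReport",
    "geometric_mean_regression",
    "bland_altman",
    "agreement_report",
    "paired_comparison",
    "d_from_summary",
    "residual_normality",
]


@dataclass(frozen=True)
class AgreementReport:
    """Geometric-mean-regression line plus Bland-Altman agreement numbers."""

    slope: float
    intercept: float
    r: float
    bias: float
    sd_diff: float
    limits: tuple[float, float]
    n: int


@dataclass(frozen=True)
class EffectSizeReport:
    """Paired t-test and Cohen's d for a two-condition comparison.

    ``t`` and ``p`` are NaN ("not applicable") when the differences have
    zero variance and zero mean.
    """

    t: float
    df: int
    p: float
    d: float


def _paired(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UnpairedData("unpaired data: x and y must be 1-D vectors of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {x.size}")
    return x, y


def geometric_mean_regression(x, y) -> tuple[float, float, float]:
    """Reduced-major-axis line through paired data.

    Returns ``(slope, intercept, r)`` with slope = sign(r) * SD(y)/SD(x)
    and intercept = mean(y) - slope * mean(x).
    """
    x, y = _paired(x, y, 3)
    sx = float(np.std(x, ddof=1))
    sy = float(np.std(y, ddof=1))
    if sx == 0 or sy == 0:
        raise DegenerateInput("degenerate input: zero-variance vector")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = math.copysign(sy / sx, r) if r != 0 else sy / sx
    intercept = float(np.mean(y)) - slope * float(np.mean(x))
    return slope, intercept, r


def bland_altman(x, y, limit_multiplier: float = 1.0):
    """Bland-Altman agreement of paired measurements.

    Differences are ``y - x`` (second argument minus first) and averages
    ``(x + y) / 2``. Returns a dict with ``bias`` (mean difference),
    ``sd_diff``, ``limits`` (bias +/- limit_multiplier * SD), and the
    ``averages``/``differences`` vectors for plotting.
    """
    x, y = _paired(x, y, 3)
    diff = y - x
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    half = limit_multiplier * sd
    return {
        "bias": bias,
        "sd_diff": sd,
        "limits": (bias - half, bias + half),
        "averages": (x + y) / 2.0,
        "differences": diff,
        "n": int(x.size),
    }


def agreement_report(x, y, limit_multiplier: float = 1.0) -> AgreementReport:
    """Combined GMR + Bland-Altman report for one pair of methods."""
    slope, intercept, r = geometric_mean_regression(x, y)
    ba = bland_altman(x, y, limit_multiplier=limit_multiplier)
    return AgreementReport(
        slope=slope,
        intercept=intercept,
        r=r,
        bias=ba["bias"],
        sd_diff=ba["sd_diff"],
        limits=ba["limits"],
        n=ba["n"],
    )


def d_from_summary(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> float:
    """Cohen's d from group summary statistics (pooled-SD form)."""
    pooled = math.sqrt((sd_a**2 + sd_b**2) / 2.0)
    if pooled == 0:
        return 0.0 if mean_b == mean_a else math.inf
    return (mean_b - mean_a) / pooled


def paired_comparison(a, b) -> EffectSizeReport:
    """Two-sided paired t-test of b vs a with Cohen's d effect size."""
    a, b = _paired(a, b, 2)
    diff = b - a
    df = a.size - 1
    if np.std(diff, ddof=1) == 0:
        # t undefined; p "not applicable" unless means differ infinitely
        t = float("nan") if np.mean(diff) == 0 else math.inf * np.sign(np.mean(diff))
        p = float("nan")
    else:
        t_res = stats.ttest_rel(b, a)
        t, p = float(t_res.statistic), float(t_res.pvalue)
    d = d_from_summary(
        float(np.mean(a)), float(np.std(a, ddof=1)), float(np.mean(b)), float(np.std(b, ddof=1))
    )
    return EffectSizeReport(t=t, df=df, p=p, d=d)


def residual_normality(residuals, alpha: float = 0.05) -> tuple[bool, float]:
    """Shapiro-Wilk screen of residuals; returns (passes, p-value)."""
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size < 3 or np.std(residuals) == 0:
        return True, float("nan")
    stat = stats.shapiro(residuals)
    return bool(stat.pvalue > alpha), float(stat.pvalue)
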