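"""Agreement and dispersion statistics on paired applicability scores.

The central statistic is Lin's concordance correlation coefficient,

    CCC = 2 * s12 / (s1^2 + s2^2 + (m1 - m2)^2),

with means ``m`` and biased (1/n) second moments ``s``. Unlike Pearson's r,
the CCC penalizes deviations from the 45-degree identity line — a slope or
location shift between two populations' scores lowers it even when the
relationship is perfectly linear. It always satisfies |CCC| <= |r| <= 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .scoring import PairedScores, ScoreTable


def _as_xy(paired, y=None) -> tuple[np.ndarray, np.ndarray]:
    if y is None:
        x = np.asarray(paired.score_1, dtype=float)
        y_ = np.asarray(paired.score_2, dtype=float)
    else:
        x = np.asarray(paired, dtype=float)
        y_ = np.asarray(y, dtype=float)
    if x.shape != y_.shape or x.ndim != 1:
        raise ValueError("paired score vectors must be 1-D and of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 paired scores")
    return x, y_


def ccc(paired: PairedScores | Sequence[float], y: Sequence[float] | None = None) -> float:
    """Lin's concordance correlation coefficient of two paired score vectors.

    Conventions for degenerate input: two equal constant vectors -> 1.0
    (perfect agreement); two unequal constant vectors -> 0.0 (zero covariance
    over a positive denominator).
    """
    x, y_ = _as_xy(paired, y)
    m1, m2 = x.mean(), y_.mean()
    s1 = float(np.mean((x - m1) ** 2))
    s2 = float(np.mean((y_ - m2) ** 2))
    s12 = float(np.mean((x - m1) * (y_ - m2)))
    denom = s1 + s2 + (m1 - m2) ** 2
    if denom == 0.0:
        return 1.0  # both constant and equal
    return 2.0 * s12 / denom


def pearson(paired: PairedScores | Sequence[float], y: Sequence[float] | None = None) -> float:
    """Pearson product-moment correlation; NaN (with a warning) if a vector is constant."""
    x, y_ = _as_xy(paired, y)
    if np.ptp(x) == 0.0 or np.ptp(y_) == 0.0:
        warnings.warn("Pearson correlation undefined for a constant vector", stacklevel=2)
        return math.nan
    return float(stats.pearsonr(x, y_).statistic)


def ccc_confidence_interval(
    paired: PairedScores | Sequence[float],
    y: Sequence[float] | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Asymptotic confidence interval for the CCC via Lin's z-transformation.

    The CCC is mapped through atanh, its asymptotic standard error on the z
    scale is computed from Lin's variance formula, and the normal interval is
    mapped back through tanh; the result always lies in [-1, 1]. Degenerate
    cases (|CCC| == 1) return the point interval.
    """
    x, y_ = _as_xy(paired, y)
    n = x.size
    c = ccc(x, y_)
    if abs(c) >= 1.0:
        return (c, c)
    if n < 4:
        raise ValueError("need at least 4 pairs for the asymptotic interval")
    r = pearson(x, y_)
    if math.isnan(r) or r == 0.0:
        raise ValueError("CCC interval undefined for constant or uncorrelated-degenerate input")
    m1, m2 = x.mean(), y_.mean()
    s1 = float(np.mean((x - m1) ** 2))
    s2 = float(np.mean((y_ - m2) ** 2))
    u2 = (m1 - m2) ** 2 / math.sqrt(s1 * s2)
    one_minus_c2 = 1.0 - c * c
    var_z = (
        (1.0 - r * r) * c * c / (one_minus_c2 * r * r)
        + 4.0 * c**3 * (1.0 - c) * u2 / (r * one_minus_c2**2)
        - 2.0 * c**4 * u2 * u2 / (r * r * one_minus_c2**2)
    ) / (n - 2)
    var_z = max(var_z, 0.0)
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    z = math.atanh(c)
    half = zcrit * math.sqrt(var_z)
    return (math.tanh(z - half), math.tanh(z + half))


def ols_line(
    paired: PairedScores | Sequence[float], y: Sequence[float] | None = None
) -> tuple[float, float]:
    """Least-squares (slope, intercept) of the second score vector on the first."""
    x, y_ = _as_xy(paired, y)
    if np.ptp(x) == 0.0:
        raise ValueError("OLS line undefined for a constant regressor")
    fit = stats.linregress(x, y_)
    return (float(fit.slope), float(fit.intercept))


class VarianceRatio(NamedTuple):
    var_1: float
    var_2: float
    ratio: float  # var_2 / var_1; NaN if var_1 == 0


def variance_ratio(paired: PairedScores, by_concern: bool = True) -> dict[str, VarianceRatio]:
    """Biased (1/n) variances of each population's scores across opinions and
    their ratio var_2/var_1, per concern (or pooled under key "all")."""
    groups: Mapping[str, list[tuple[float, float]]]
    if by_concern:
        groups = {}
        for e in paired.entries:
            groups.setdefault(e.concern, []).append((e.score_1, e.score_2))
    else:
        groups = {"all": [(e.score_1, e.score_2) for e in paired.entries]}
    out: dict[str, VarianceRatio] = {}
    for key, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"need at least 2 pairs per group; {key!r} has {len(vals)}")
        arr = np.array(vals, dtype=float)
        v1 = float(np.var(arr[:, 0]))
        v2 = float(np.var(arr[:, 1]))
        out[key] = VarianceRatio(v1, v2, v2 / v1 if v1 > 0 else math.nan)
    return out


@dataclass(frozen=True)
class AgreementResult:
    """CCC with its CI, Pearson, and the fitted regression-line diagnostics."""

    ccc: float
    pearson: float
    ccc_ci_lower: float
    ccc_ci_upper: float
    n_pairs: int
    ols_slope: float
    ols_intercept: float
    label_1: str = ""
    label_2: str = ""


def agreement_result(paired: PairedScores, level: float = 0.95) -> AgreementResult:
    """Compute the full agreement summary for a paired score vector."""
    x, y_ = _as_xy(paired)
    c = ccc(x, y_)
    r = pearson(x, y_)
    lo, hi = ccc_confidence_interval(x, y_, level=level)
    slope, intercept = ols_line(x, y_)
    return AgreementResult(
        ccc=c,
        pearson=r,
        ccc_ci_lower=lo,
        ccc_ci_upper=hi,
        n_pairs=x.size,
        ols_slope=slope,
        ols_intercept=intercept,
        label_1=paired.label_1,
        label_2=paired.label_2,
    )


class ConcernBox(NamedTuple):
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]
    extreme_outliers: tuple[float, ...]


@dataclass
class BoxplotSummary:
    """Per-concern five-number summaries of applicability scores across opinions.

    Quartiles use linear interpolation between order statistics. Whiskers
    reach the most extreme values within 1.5 IQR of the box edges; values
    between 1.5 and 3 IQR beyond a box edge are outliers, beyond 3 IQR
    extreme outliers.
    """

    concerns: dict[str, ConcernBox]


def boxplot_summary(
    table: ScoreTable, concern_order: Sequence[str] | None = None
) -> BoxplotSummary:
    by_concern: dict[str, list[float]] = {}
    for (op, concern), cell in table.cells.items():
        by_concern.setdefault(concern, []).append(float(cell.score))
    order = list(concern_order) if concern_order is not None else sorted(by_concern)
    out: dict[str, ConcernBox] = {}
    for concern in order:
        vals = np.sort(np.array(by_concern[concern], dtype=float))
        if vals.size < 5:
            raise ValueError(f"need at least 5 scores per concern; {concern!r} has {vals.size}")
        q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear interpolation
        iqr = q3 - q1
        inner_lo, inner_hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        outer_lo, outer_hi = q1 - 3.0 * iqr, q3 + 3.0 * iqr
        inside = vals[(vals >= inner_lo) & (vals <= inner_hi)]
        outliers = vals[((vals < inner_lo) & (vals >= outer_lo)) | ((vals > inner_hi) & (vals <= outer_hi))]
        extreme = vals[(vals < outer_lo) | (vals > outer_hi)]
        out[concern] = ConcernBox(
            median=float(med),
            q1=float(q1),
            q3=float(q3),
            whisker_low=float(inside.min()),
            whisker_high=float(inside.max()),
            outliers=tuple(float(v) for v in outliers),
            extreme_outliers=tuple(float(v) for v in extreme),
        )
    return BoxplotSummary(concerns=out)
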