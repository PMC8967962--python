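"""Cohort-level statistics: correlation, t-tests, summaries, calibration.

These wrap the standard scipy routines behind a validated interface:
degenerate inputs (constant series, zero-variance differences) raise
:class:`~etecim.errors.DegenerateVarianceError` instead of returning NaN,
so cohort tables can never silently contain invalid tests.  All p-values
are two-sided; the Pearson p uses the t-distribution with n-2 degrees of
freedom, the t-tests n-1.

The calibration line regresses predicted GTV (y) on ground-truth GTV (x)
by ordinary least squares; inverting it algebraically recovers a
ground-truth estimate from a predicted value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateVarianceError

__all__ = [
    "PairedSeries",
    "CohortStats",
    "CalibrationLine",
    "pearson",
    "paired_t",
    "one_sample_t",
    "summarize",
    "calibrate",
    "invert_calibration",
]


@dataclass(frozen=True)
class PairedSeries:
    """Per-patient paired values, e.g. ground-truth (x) vs predicted (y) GTV."""

    labels: list[str]
    x: np.ndarray
    y: np.ndarray
    fold: np.ndarray | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError(f"x and y must be 1-D of equal length, got {x.shape} vs {y.shape}")
        if len(self.labels) != len(x):
            raise ValueError("labels length must match series length")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("paired series must not contain non-finite values")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class CohortStats:
    """One statistic block: test results and/or descriptive summary."""

    pearson_r: float | None = None
    r_squared: float | None = None
    t_statistic: float | None = None
    p_value: float | None = None
    mean: float | None = None
    sd: float | None = None
    median: float | None = None
    q1: float | None = None
    q3: float | None = None


@dataclass(frozen=True)
class CalibrationLine:
    """OLS fit y = slope * x + intercept with x = ground truth."""

    slope: float
    intercept: float
    fit_direction: str = "y-on-x (x = ground truth)"


def _as_array(values, min_len: int, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if len(arr) < min_len:
        raise ValueError(f"{what} needs at least {min_len} values, got {len(arr)}")
    if not np.isfinite(arr).all():
        raise ValueError(f"{what} must not contain non-finite values")
    return arr


def pearson(series: PairedSeries) -> tuple[float, float, float]:
    """Sample Pearson correlation: returns (r, r^2, two-sided p)."""
    if len(series) < 3:
        raise ValueError(f"Pearson correlation needs n >= 3, got {len(series)}")
    for name, v in (("x", series.x), ("y", series.y)):
        if np.ptp(v) == 0:
            raise DegenerateVarianceError(f"{name} is constant; correlation undefined")
    r, p = sps.pearsonr(series.x, series.y)
    return float(r), float(r) ** 2, float(p)


def paired_t(series: PairedSeries) -> tuple[float, float]:
    """Paired-sample t-test on the differences y - x (two-sided, df = n-1)."""
    if len(series) < 2:
        raise ValueError(f"paired t-test needs n >= 2, got {len(series)}")
    diffs = series.y - series.x
    if np.ptp(diffs) == 0:
        raise DegenerateVarianceError("paired differences have zero variance")
    res = sps.ttest_rel(series.y, series.x)
    return float(res.statistic), float(res.pvalue)


def one_sample_t(values, mu0: float = 0.0) -> tuple[float, float]:
    """One-sample t-test of the mean against mu0 (two-sided, df = n-1)."""
    arr = _as_array(values, 2, "one-sample t-test")
    if np.ptp(arr) == 0:
        raise DegenerateVarianceError("values have zero variance")
    res = sps.ttest_1samp(arr, popmean=mu0)
    return float(res.statistic), float(res.pvalue)


def summarize(values) -> CohortStats:
    """Descriptive summary: mean, sample SD (n-1), median and quartiles.

    Quartiles use linear interpolation between order statistics (numpy's
    default), one fixed documented convention.
    """
    arr = _as_array(values, 1, "summary")
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    return CohortStats(mean=float(arr.mean()), sd=sd, median=float(med), q1=float(q1), q3=float(q3))


def calibrate(series: PairedSeries) -> CalibrationLine:
    """Least-squares line of predicted (y) on ground truth (x)."""
    if len(series) < 2:
        raise ValueError(f"calibration needs n >= 2, got {len(series)}")
    if np.ptp(series.x) == 0:
        raise DegenerateVarianceError("x is constant; calibration line undefined")
    slope, intercept = np.polyfit(series.x, series.y, deg=1)
    return CalibrationLine(slope=float(slope), intercept=float(intercept))


def invert_calibration(line: CalibrationLine, predicted: float) -> float:
    """Solve the calibration line for the ground-truth value.

    Given a predicted GTV, returns (predicted - intercept) / slope.
    """
    if line.slope == 0:
        raise ZeroDivisionError("calibration line with zero slope is not invertible")
    return (predicted - line.intercept) / line.slope
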