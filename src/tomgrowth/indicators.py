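"""Moving-window transition indicators: skewness, variability, growth rate.

A developmental transition driven by heterogeneity in timing leaves three
cross-sectional fingerprints as age increases through the transition: the
score distribution first skews positive (a minority of early movers), then
negative (a minority of laggards); the between-child variability peaks
mid-transition; and the growth rate (first derivative of the mean curve)
peaks.  These are computed over sliding windows of children sorted by age
and then Loess-smoothed with a 30% window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import skew

from tomgrowth.data_model import Cohort
from tomgrowth.smoothing import SmoothedCurve, differentiate, loess_fit


@dataclass(frozen=True)
class IndicatorSeries:
    """A moving-window statistic (or derivative) as a function of age."""

    center_ages: np.ndarray   # months, increasing
    values: np.ndarray
    statistic: str            # "skewness" | "sd" | "FD" | ...
    window_frac: float | None = None
    step: int | None = None
    smoothed: bool = False

    def __post_init__(self) -> None:
        ages = np.asarray(self.center_ages, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "center_ages", ages)
        object.__setattr__(self, "values", values)
        if ages.shape != values.shape or ages.ndim != 1:
            raise ValueError("center_ages and values must be 1-D, equal length")
        if np.any(np.diff(ages) < 0):
            raise ValueError("center_ages must be non-decreasing")


def moving_statistic(
    cohort: Cohort,
    score_column: str = "sum_score",
    statistic: str = "skewness",
    window_frac: float = 0.20,
    step: int = 1,
) -> IndicatorSeries:
    """Sliding-window skewness or SD of scores over age-sorted children.

    The window holds ``ceil(window_frac * N)`` children and advances ``step``
    children at a time; the window's center age is the median age inside it.
    Skewness is the adjusted Fisher-Pearson estimator (the
    ``sqrt(n(n-1))/(n-2)`` small-sample correction); SD uses ``ddof=1``.
    """
    frame = cohort.to_frame().sort_values("age_months", kind="stable")
    ages = frame["age_months"].to_numpy(dtype=float)
    scores = frame[score_column].to_numpy(dtype=float)
    n = scores.size
    k = int(np.ceil(window_frac * n))
    min_k = 8 if statistic == "skewness" else 3
    if k < min_k:
        raise ValueError(
            f"window of {k} children too small for {statistic} (need >= {min_k})"
        )
    starts = np.arange(0, n - k + 1, step)
    windows = np.lib.stride_tricks.sliding_window_view(scores, k)[starts]
    age_windows = np.lib.stride_tricks.sliding_window_view(ages, k)[starts]
    centers = np.median(age_windows, axis=1)
    if statistic == "skewness":
        values = skew(windows, axis=1, bias=False)
        values = np.nan_to_num(values, nan=0.0)  # constant windows: no skew
    elif statistic == "sd":
        values = windows.std(axis=1, ddof=1)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    # ties in age can make centers locally non-monotone; enforce ordering
    order = np.argsort(centers, kind="stable")
    return IndicatorSeries(
        center_ages=centers[order],
        values=values[order],
        statistic=statistic,
        window_frac=window_frac,
        step=step,
    )


def growth_rate_series(curve: SmoothedCurve) -> IndicatorSeries:
    """First derivative of a smoothed developmental curve (the growth rate)."""
    if curve.deriv_order != 0:
        raise ValueError("growth_rate_series expects an underived curve")
    d1 = differentiate(curve)
    return IndicatorSeries(
        center_ages=d1.grid, values=d1.values, statistic="FD"
    )


def smooth_indicator(series: IndicatorSeries, span: float = 0.30,
                     degree: int = 2) -> IndicatorSeries:
    """Loess-smooth an indicator series onto its own center-age grid."""
    # collapse duplicate center ages to their mean value for a valid fit grid
    ages, inv = np.unique(series.center_ages, return_inverse=True)
    values = np.zeros_like(ages, dtype=float)
    counts = np.zeros_like(ages, dtype=float)
    np.add.at(values, inv, series.values)
    np.add.at(counts, inv, 1.0)
    values /= counts
    curve = loess_fit(ages, values, span=span, degree=degree, grid=ages)
    return IndicatorSeries(
        center_ages=ages,
        values=curve.values,
        statistic=series.statistic,
        window_frac=series.window_frac,
        step=series.step,
        smoothed=True,
    )


def series_association(a: IndicatorSeries, b: IndicatorSeries,
                       grid_step: float = 1.0) -> dict[str, float]:
    """Covariance and Pearson correlation of two series on a common age grid.

    Both series are linearly interpolated onto a shared grid spanning the
    overlap of their age ranges.
    """
    lo = max(a.center_ages[0], b.center_ages[0])
    hi = min(a.center_ages[-1], b.center_ages[-1])
    if lo >= hi:
        raise ValueError("series age ranges do not overlap")
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    va = np.interp(grid, a.center_ages, a.values)
    vb = np.interp(grid, b.center_ages, b.values)
    cov = float(np.cov(va, vb, ddof=1)[0, 1])
    sa, sb = va.std(ddof=1), vb.std(ddof=1)
    corr = float(cov / (sa * sb)) if sa > 0 and sb > 0 else float("nan")
    return {"covariance": cov, "correlation": corr}


def peak_ordering(a: IndicatorSeries, b: IndicatorSeries, n_peaks: int = 2
                  ) -> list[tuple[float, float, float]]:
    """Match the ``n_peaks`` largest local maxima of two smoothed series.

    Peaks are matched in age order after keeping the ``n_peaks`` highest
    local maxima of each series; each triple is ``(age_a, age_b, lag)`` with
    ``lag = age_b - age_a``.  If a series has fewer peaks than requested, the
    available pairs are returned (the caller can see the shortfall from the
    list length).
    """
    from scipy.signal import find_peaks

    def top_peaks(s: IndicatorSeries) -> list[float]:
        idx, _ = find_peaks(s.values)
        if idx.size == 0:
            return []
        order = np.argsort(-s.values[idx])[:n_peaks]
        return sorted(float(s.center_ages[i]) for i in idx[order])

    pa, pb = top_peaks(a), top_peaks(b)
    return [(x, y, y - x) for x, y in zip(pa, pb)]
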