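"""Loess smoothing of score-vs-age scatter, derivatives, inflections and dips.

The smoother is classical Loess: at each grid age a polynomial of low degree
is fitted by weighted least squares to the ``span * N`` nearest observations,
with tricube weights on the distance scaled by the neighbourhood radius.  The
span is a fraction of the sample ("20% window size"), i.e. a nearest-neighbour
bandwidth, and no robustness iterations are applied.  Local degree 2 is the
default: the developmental readings downstream (plateau and dip timing) are
taken from the second derivative, which a locally quadratic fit estimates far
more stably than a locally linear one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

#: Monthly evaluation grid spanning the study's age range.
DEFAULT_GRID = np.arange(36, 144)


@dataclass(frozen=True)
class SmoothedCurve:
    """A Loess fit (or one of its derivatives) evaluated on an age grid."""

    grid: np.ndarray          # ascending ages, months
    values: np.ndarray        # points (or points/month per derivative order)
    span: float               # fraction of the sample in each local fit
    degree: int               # local polynomial degree
    deriv_order: int = 0
    source: str = ""
    #: nearest-neighbour bandwidth (months) of the local fit at the first and
    #: last grid point; derivative readings within one bandwidth of an end
    #: are boundary-biased
    edge_bandwidths: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)
        if grid.ndim != 1 or grid.shape != values.shape:
            raise ValueError("grid and values must be 1-D and equally long")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite fitted values")
        if not (0 < self.span <= 1):
            raise ValueError(f"span={self.span} outside (0, 1]")

    def __call__(self, ages) -> np.ndarray:
        """Linear interpolation of the fitted values at arbitrary ages."""
        return np.interp(np.asarray(ages, dtype=float), self.grid, self.values)


@dataclass(frozen=True)
class DipDescriptor:
    """A temporary regression: local maximum, trough, and recovery of a curve."""

    onset_age: float     # local max preceding the trough, months
    trough_age: float    # local min, months
    recovery_age: float  # first age at which the curve regains the onset level
    depth: float         # onset value - trough value, points

    def __post_init__(self) -> None:
        if not (self.onset_age < self.trough_age < self.recovery_age):
            raise ValueError("dip must satisfy onset < trough < recovery")
        if self.depth < 0:
            raise ValueError("dip depth must be non-negative")


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def loess_fit(
    x: Sequence[float],
    y: Sequence[float],
    span: float = 0.20,
    degree: int = 2,
    grid: np.ndarray | None = None,
    source: str = "",
) -> SmoothedCurve:
    """Locally weighted polynomial regression on an evaluation grid.

    At each grid point the ``ceil(span * N)`` nearest observations (ties at
    the boundary distance all included) are fitted with a degree-``degree``
    polynomial under tricube weights; the fitted value at the grid point is
    returned.  Deterministic; no robustness iterations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    n_distinct = np.unique(x).size
    if n_distinct < degree + 2:
        raise ValueError(
            f"need at least {degree + 2} distinct ages, got {n_distinct}"
        )
    k = int(np.ceil(span * n))
    if k < degree + 2:
        raise ValueError(
            f"span*N = {k} too small for degree {degree} (need >= {degree + 2})"
        )
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)

    # All pairwise offsets: G x N.
    d = x[None, :] - grid[:, None]
    absd = np.abs(d)
    # Radius of the k-nearest neighbourhood at each grid point; ties at the
    # boundary distance are all included.
    radius = np.sort(absd, axis=1)[:, k - 1]
    radius = np.maximum(radius, 1e-12)
    w = _tricube(d / radius[:, None])
    w[absd > radius[:, None] * (1 + 1e-12)] = 0.0
    # Points exactly at the neighbourhood edge get weight 0 from tricube;
    # guard against all-zero rows (e.g. all neighbours at one distance).
    zero_rows = w.sum(axis=1) <= 0
    if np.any(zero_rows):
        w[zero_rows] = (absd[zero_rows] <= radius[zero_rows, None]).astype(float)

    # Weighted least squares via local moment matrices, solved per grid point.
    p = degree + 1
    powers = [w * d**i for i in range(2 * degree + 1)]
    moments = np.stack(powers, axis=0).sum(axis=2)          # (2deg+1, G)
    rhs_pow = [w * d**i for i in range(p)]
    rhs = np.stack([(t * y[None, :]).sum(axis=1) for t in rhs_pow], axis=1)  # G x p
    A = np.empty((grid.size, p, p))
    for i in range(p):
        for j in range(p):
            A[:, i, j] = moments[i + j]
    fitted = np.empty(grid.size)
    # Batch solve; fall back per point on singular neighbourhoods.
    try:
        coef = np.linalg.solve(A, rhs[:, :, None])[:, :, 0]
        fitted[:] = coef[:, 0]
        bad = ~np.isfinite(fitted)
    except np.linalg.LinAlgError:
        bad = np.ones(grid.size, dtype=bool)
    if np.any(bad):
        for g in np.nonzero(bad)[0]:
            ww = w[g]
            X = np.vander(d[g], p, increasing=True)
            sw = np.sqrt(ww)
            coef_g, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
            fitted[g] = coef_g[0]
    return SmoothedCurve(
        grid=grid, values=fitted, span=span, degree=degree, deriv_order=0,
        source=source,
        edge_bandwidths=(float(radius[0]), float(radius[-1])),
    )


def differentiate(curve: SmoothedCurve) -> SmoothedCurve:
    """Numerical derivative on the grid (central differences, one-sided ends)."""
    if curve.deriv_order >= 2:
        raise ValueError("derivative order above 2 not supported")
    if curve.grid.size < 3:
        raise ValueError("grid too short to differentiate")
    deriv = np.gradient(curve.values, curve.grid)
    return replace(curve, values=deriv, deriv_order=curve.deriv_order + 1)


def _local_extrema(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict interior local maxima and minima (plateaus collapse
    to their first point)."""
    from scipy.signal import argrelextrema

    maxima = argrelextrema(values, np.greater_equal, order=1)[0]
    minima = argrelextrema(values, np.less_equal, order=1)[0]
    # drop flat runs duplicating the same extremum, and the grid endpoints
    def _clean(idx):
        idx = idx[(idx > 0) & (idx < values.size - 1)]
        keep = []
        for i in idx:
            if keep and i == keep[-1] + 1 and values[i] == values[keep[-1]]:
                continue
            keep.append(i)
        return np.asarray(keep, dtype=int)

    return _clean(maxima), _clean(minima)


def inflection_points(
    curve: SmoothedCurve,
    min_prominence: float | None = None,
    d2_span: float = 0.30,
    edge_margin: tuple[float, float] | None = None,
) -> list[tuple[float, str]]:
    """Ages of marked extrema of the second derivative, ordered by age.

    Double-differencing a scatter smooth on a monthly grid amplifies sampling
    wiggles, so the raw second derivative is itself Loess-smoothed (span
    ``d2_span``, the same 30% window used for derivative indicator curves)
    before extrema are read.  Second-derivative estimates within one
    smoothing bandwidth of a grid end are boundary-biased, so that zone is
    excluded from both the prominence normalization and the peak search;
    the default margin is the curve's recorded edge bandwidth (falling back
    to 12.5% of the grid range).  A "marked" extremum has peak prominence at
    least ``min_prominence``; the default threshold is 10% of the maximum
    absolute smoothed second derivative on the interior.  Each age is tagged
    ``"max"`` or ``"min"``.
    """
    if curve.deriv_order != 0:
        raise ValueError("inflection_points expects an underived curve")
    d2 = differentiate(differentiate(curve))
    if d2_span:
        d2 = loess_fit(d2.grid, d2.values, span=d2_span, degree=2,
                       grid=d2.grid, source=curve.source)
    grid = d2.grid
    if edge_margin is None:
        span_months = 0.125 * (grid[-1] - grid[0])
        if curve.edge_bandwidths is not None:
            edge_margin = curve.edge_bandwidths
        else:
            edge_margin = (span_months, span_months)
    interior = (grid >= grid[0] + edge_margin[0]) & (
        grid <= grid[-1] - edge_margin[1]
    )
    v = np.where(interior, d2.values, np.nan)
    lo_idx = int(np.argmax(interior))
    v_int = d2.values[interior]
    if min_prominence is None:
        vmax = np.max(np.abs(v_int)) if v_int.size and np.any(v_int != 0) else 0
        min_prominence = 0.10 * vmax if vmax else np.inf

    from scipy.signal import find_peaks

    out: list[tuple[float, str]] = []
    for sign, tag in ((1.0, "max"), (-1.0, "min")):
        peaks, _ = find_peaks(sign * v_int, prominence=min_prominence)
        out.extend((float(grid[lo_idx + i]), tag) for i in peaks)
    out.sort(key=lambda t: t[0])
    return out


def detect_dip(
    curve: SmoothedCurve,
    search_range: tuple[float, float] = (60.0, 96.0),
) -> DipDescriptor | None:
    """Find the deepest temporary regression of a smoothed curve.

    Each interior local minimum whose trough lies inside ``search_range`` is
    paired with the highest preceding local maximum; the pair with maximal
    depth wins.  Returns ``None`` when the curve is monotone non-decreasing
    over the search range.  The recovery age is the first grid age after the
    trough at which the curve regains the onset level (the end of the grid if
    it never does).
    """
    if curve.deriv_order != 0:
        raise ValueError("detect_dip expects an underived curve")
    lo, hi = search_range
    if lo >= hi:
        raise ValueError("empty search range")
    grid, v = curve.grid, curve.values
    maxima, minima = _local_extrema(v)
    best: DipDescriptor | None = None
    for m in minima:
        if not (lo <= grid[m] <= hi):
            continue
        preceding = maxima[maxima < m]
        if preceding.size == 0:
            continue
        onset = preceding[np.argmax(v[preceding])]
        depth = float(v[onset] - v[m])
        if depth <= 0:
            continue
        after = np.nonzero((grid > grid[m]) & (v >= v[onset]))[0]
        recovery = float(grid[after[0]]) if after.size else float(grid[-1])
        dip = DipDescriptor(
            onset_age=float(grid[onset]),
            trough_age=float(grid[m]),
            recovery_age=recovery,
            depth=depth,
        )
        if best is None or dip.depth > best.depth:
            best = dip
    return best


def rescale_to_ceiling(y: Sequence[float], ceiling: float) -> np.ndarray:
    """Divide scores by their ceiling, mapping them to [0, 1] for sub-score
    comparisons."""
    return np.asarray(y, dtype=float) / float(ceiling)
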