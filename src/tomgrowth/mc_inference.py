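"""Monte-Carlo tests of developmental non-linearities against a monotone null.

The null hypothesis is that the true mean curve rises monotonically with age
and any apparent temporary regression is sampling noise.  The null model is
fitted from the data itself — an isotonic (pool-adjacent-violators) mean,
lightly smoothed while preserving monotonicity, plus an age-varying residual
SD — and synthetic cohorts drawn from it calibrate the distribution of dip
statistics.  Because neither the location nor the length of a regression is
known a priori, dip depth and most-negative slope are scanned over windows
of several lengths anywhere along the age range, and p-values are reported
per window length plus a family-wise value for the max-over-windows
statistic.  All p-values use the add-one convention
``p = (1 + #{null >= observed}) / (1 + n_reps)`` and can therefore never be
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.isotonic import IsotonicRegression

from tomgrowth.data_model import ChildRecord, Cohort, SUBSCORE_COLUMNS, SUM_SCORE_MAX
from tomgrowth.indicators import (
    growth_rate_series,
    moving_statistic,
    series_association,
    smooth_indicator,
)
from tomgrowth.smoothing import DEFAULT_GRID, SmoothedCurve, detect_dip, loess_fit


@dataclass(frozen=True)
class NullModel:
    """Monotone mean plus residual-SD function on a monthly age grid."""

    grid: np.ndarray
    mean: np.ndarray        # non-decreasing
    sd: np.ndarray          # > 0
    fitted_from: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.mean) < -1e-9):
            raise ValueError("null mean must be non-decreasing")
        if np.any(self.sd <= 0):
            raise ValueError("null SD must be positive")

    def mean_at(self, ages) -> np.ndarray:
        return np.interp(np.asarray(ages, dtype=float), self.grid, self.mean)

    def sd_at(self, ages) -> np.ndarray:
        return np.interp(np.asarray(ages, dtype=float), self.grid, self.sd)


@dataclass(frozen=True)
class MCResult:
    """Outcome of a Monte-Carlo test."""

    statistic: str
    observed: Mapping[float, float]      # per window length
    p_values: Mapping[float, float]      # per window length, add-one
    headline_p: float                    # max-over-windows statistic
    n_reps: int
    seed: int
    null_quantiles: Mapping[float, tuple[float, float, float]] = field(
        default_factory=dict
    )  # per window: (50%, 90%, 95%)

    @property
    def min_p(self) -> float:
        return min(self.p_values.values())


def fit_null(cohort: Cohort, score_column: str = "sum_score",
             grid: np.ndarray | None = None, sd_span: float = 0.30,
             sd_floor: float = 1.0) -> NullModel:
    """Best-fitting monotone growth curve plus a residual-SD model.

    The mean is the isotonic regression of score on age, evaluated on the
    grid, passed through a centered moving average of width 3 grid steps and
    re-projected onto the monotone cone (a second isotonic pass) so smoothing
    cannot break monotonicity.  The SD function is a Loess fit (span
    ``sd_span``) of absolute residuals scaled by sqrt(pi/2) — the
    normal-consistency factor for mean absolute deviation — floored at
    ``sd_floor`` points.
    """
    if len(cohort) < 30:
        raise ValueError("need at least 30 children to fit the null model")
    frame = cohort.to_frame()
    ages = frame["age_months"].to_numpy(dtype=float)
    scores = frame[score_column].to_numpy(dtype=float)
    if np.unique(ages).size < 3:
        raise ValueError("degenerate ages")
    if grid is None:
        grid = DEFAULT_GRID.astype(float)

    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    iso.fit(ages, scores)
    mean = iso.predict(grid)
    # light smoothing, then re-projection onto the monotone cone
    kernel = np.ones(3) / 3
    padded = np.concatenate([mean[:1], mean, mean[-1:]])
    smoothed = np.convolve(padded, kernel, mode="valid")
    iso2 = IsotonicRegression(increasing=True)
    mean = iso2.fit_transform(grid, smoothed)

    resid = scores - np.interp(ages, grid, mean)
    sd_curve = loess_fit(ages, np.abs(resid), span=sd_span, degree=1, grid=grid)
    sd = np.maximum(sd_curve.values * np.sqrt(np.pi / 2), sd_floor)
    return NullModel(grid=grid, mean=mean, sd=sd, fitted_from=cohort.label)


def simulate_null(null_model: NullModel, template: Cohort, seed: int) -> Cohort:
    """Draw one cohort from the monotone null on the template's ages.

    Ages, genders, administrators and ids are copied from the template;
    scores are ``clamp(round(mean(age) + Normal(0, sd(age))), 0, 110)``.
    Sub-scores are re-allocated proportionally so records stay valid.
    """
    from tomgrowth.synthetic import allocate_subscores_flat

    rng = np.random.default_rng(seed)
    ages = np.array([r.age_months for r in template], dtype=float)
    mu = null_model.mean_at(ages)
    sd = null_model.sd_at(ages)
    noise = rng.normal(0.0, 1.0, ages.size) * sd
    scores = np.clip(np.round(mu + noise), 0, SUM_SCORE_MAX).astype(int)
    records = []
    for rec, total in zip(template, scores):
        subs = allocate_subscores_flat(int(total))
        records.append(
            ChildRecord(
                child_id=rec.child_id,
                age_months=rec.age_months,
                gender=rec.gender,
                administrator_id=rec.administrator_id,
                sum_score=int(total),
                **dict(zip(SUBSCORE_COLUMNS, subs)),
            )
        )
    return Cohort(records=records, label=f"{template.label}/null",
                  provenance="null-simulated", seed=seed)


# ---------------------------------------------------------------------------
# Dip statistics on smoothed curves
# ---------------------------------------------------------------------------

def _smoothed_values(cohort_or_curve, span: float,
                     score_column: str = "sum_score") -> SmoothedCurve:
    if isinstance(cohort_or_curve, SmoothedCurve):
        return cohort_or_curve
    frame = cohort_or_curve.to_frame()
    return loess_fit(
        frame["age_months"].to_numpy(dtype=float),
        frame[score_column].to_numpy(dtype=float),
        span=span, degree=2,
    )


def dip_depth_from_curve(curve: SmoothedCurve, window_len: float) -> float:
    """Max over window placements t0 of value(t0) minus the minimum value on
    (t0, t0 + window_len]; 0 for a non-decreasing curve."""
    if window_len < 3:
        raise ValueError("window length must be at least 3 months")
    grid, v = curve.grid, curve.values
    if window_len >= grid[-1] - grid[0]:
        raise ValueError("window longer than the age range")
    best = 0.0
    for i in range(grid.size):
        in_window = (grid > grid[i]) & (grid <= grid[i] + window_len)
        if not np.any(in_window):
            continue
        drop = v[i] - v[in_window].min()
        if drop > best:
            best = float(drop)
    return best


def negative_slope_from_curve(curve: SmoothedCurve, interval_len: float
                              ) -> float:
    """Most negative average slope over any interval of the given length
    (points/month); non-negative curves give >= 0 values of the minimum
    slope."""
    grid, v = curve.grid, curve.values
    if interval_len >= grid[-1] - grid[0]:
        raise ValueError("interval longer than the age range")
    worst = np.inf
    for i in range(grid.size):
        j = np.searchsorted(grid, grid[i] + interval_len)
        if j >= grid.size:
            break
        slope = (v[j] - v[i]) / (grid[j] - grid[i])
        worst = min(worst, slope)
    return float(worst)


def dip_depth_stat(cohort: Cohort, span: float = 0.20,
                   window_len: float = 6.0,
                   score_column: str = "sum_score") -> float:
    """Dip-depth statistic of a cohort's Loess-smoothed score curve."""
    return dip_depth_from_curve(
        _smoothed_values(cohort, span, score_column), window_len
    )


def negative_slope_stat(cohort: Cohort, span: float = 0.20,
                        interval_lens: Sequence[float] = (4, 6, 8, 10),
                        score_column: str = "sum_score") -> dict[float, float]:
    """Most negative smoothed slope per interval length (points/month)."""
    curve = _smoothed_values(cohort, span, score_column)
    return {float(w): negative_slope_from_curve(curve, w)
            for w in interval_lens}


_STAT_FNS = {
    # each maps (curve, window) -> value where LARGER means more dip-like
    "dip_depth": dip_depth_from_curve,
    "negative_slope": lambda curve, w: -negative_slope_from_curve(curve, w),
}


def mc_test(cohort: Cohort, stat: str = "dip_depth",
            window_lens: Sequence[float] = (4, 6, 8, 10),
            n_reps: int = 1000, seed: int = 0, span: float = 0.20,
            score_column: str = "sum_score") -> MCResult:
    """Monte-Carlo test of a dip statistic against the monotone-growth null.

    Fits the null to the cohort, simulates ``n_reps`` null cohorts on the
    same ages, and reports the add-one p-value per window length plus a
    family-wise p for the max-over-windows statistic.  For the
    ``negative_slope`` statistic the magnitude of the most negative slope is
    used, so larger is always more extreme.
    """
    if n_reps < 99:
        raise ValueError("use at least 99 replicates")
    if stat not in _STAT_FNS:
        raise ValueError(f"unknown statistic {stat!r}")
    fn = _STAT_FNS[stat]
    window_lens = [float(w) for w in window_lens]

    curve = _smoothed_values(cohort, span, score_column)
    observed = {w: fn(curve, w) for w in window_lens}
    obs_max = max(observed.values())

    null = fit_null(cohort, score_column)
    rng = np.random.SeedSequence(seed)
    child_seeds = rng.generate_state(n_reps)
    exceed = {w: 0 for w in window_lens}
    exceed_max = 0
    null_vals = {w: np.empty(n_reps) for w in window_lens}
    for rep in range(n_reps):
        sim = simulate_null(null, cohort, int(child_seeds[rep]))
        sim_curve = _smoothed_values(sim, span, score_column)
        rep_vals = {w: fn(sim_curve, w) for w in window_lens}
        for w in window_lens:
            null_vals[w][rep] = rep_vals[w]
            if rep_vals[w] >= observed[w]:
                exceed[w] += 1
        if max(rep_vals.values()) >= obs_max:
            exceed_max += 1
    p_values = {w: (1 + exceed[w]) / (1 + n_reps) for w in window_lens}
    quantiles = {
        w: tuple(float(q) for q in np.quantile(null_vals[w], (0.5, 0.9, 0.95)))
        for w in window_lens
    }
    return MCResult(
        statistic=stat,
        observed=observed,
        p_values=p_values,
        headline_p=(1 + exceed_max) / (1 + n_reps),
        n_reps=n_reps,
        seed=seed,
        null_quantiles=quantiles,
    )


def leave_one_out_admin(cohort: Cohort, stat: str = "dip_depth",
                        window_lens: Sequence[float] = (4, 6, 8, 10),
                        n_reps: int = 1000, seed: int = 0,
                        span: float = 0.20) -> dict[int, MCResult]:
    """Re-run the Monte-Carlo dip test once per left-out administrator.

    If the dip is an artifact of one administrator it disappears from the
    reduced dataset lacking that administrator's children.
    """
    admins = cohort.administrators()
    if len(admins) < 2:
        raise ValueError("need at least two administrators to leave one out")
    results: dict[int, MCResult] = {}
    for i, admin in enumerate(admins):
        reduced = cohort.drop_administrator(admin)
        if len(reduced) == 0:
            raise ValueError(f"administrator {admin} owns all the data")
        results[admin] = mc_test(
            reduced, stat=stat, window_lens=window_lens, n_reps=n_reps,
            seed=seed + i, span=span,
        )
    return results


def covariance_null_test(cohort: Cohort, n_series: int = 200, seed: int = 0,
                         span: float = 0.20, window_frac: float = 0.20,
                         smooth_span: float = 0.30,
                         measure: str = "correlation") -> MCResult:
    """Null test of the skewness / growth-rate co-variation.

    Observed statistic: the association between the smoothed moving-skewness
    series and the smoothed first derivative of the score curve.  The null
    draws score sets with means equal to the cohort's own (non-monotone)
    Loess curve and a constant residual SD under symmetric normal noise — a
    world where any skewness structure is accidental — and recomputes the
    association per draw.  ``measure`` selects ``"correlation"``
    (scale-free, default) or ``"covariance"``.
    """
    if measure not in ("correlation", "covariance"):
        raise ValueError("measure must be correlation or covariance")

    def association(c: Cohort) -> float:
        sk = smooth_indicator(
            moving_statistic(c, statistic="skewness", window_frac=window_frac),
            span=smooth_span,
        )
        fd = smooth_indicator(
            growth_rate_series(_smoothed_values(c, span)), span=smooth_span
        )
        return series_association(sk, fd)[measure]

    observed = association(cohort)
    frame = cohort.to_frame()
    ages = frame["age_months"].to_numpy(dtype=float)
    scores = frame["sum_score"].to_numpy(dtype=float)
    mean_curve = loess_fit(ages, scores, span=span, degree=2)
    resid_sd = float(np.std(scores - mean_curve(ages), ddof=1))

    rng = np.random.SeedSequence(seed)
    rep_seeds = rng.generate_state(n_series)
    exceed = 0
    for rep in range(n_series):
        rep_rng = np.random.default_rng(int(rep_seeds[rep]))
        sim_scores = np.clip(
            np.round(mean_curve(ages) + rep_rng.normal(0, resid_sd, ages.size)),
            0, SUM_SCORE_MAX,
        ).astype(int)
        sim = _replace_scores(cohort, sim_scores)
        if association(sim) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_series)
    return MCResult(
        statistic=f"skew-FD {measure}",
        observed={0.0: observed},
        p_values={0.0: p},
        headline_p=p,
        n_reps=n_series,
        seed=seed,
    )


def _replace_scores(cohort: Cohort, scores: np.ndarray) -> Cohort:
    from tomgrowth.synthetic import allocate_subscores_flat

    records = []
    for rec, total in zip(cohort, scores):
        subs = allocate_subscores_flat(int(total))
        records.append(
            ChildRecord(
                child_id=rec.child_id, age_months=rec.age_months,
                gender=rec.gender, administrator_id=rec.administrator_id,
                sum_score=int(total), **dict(zip(SUBSCORE_COLUMNS, subs)),
            )
        )
    return Cohort(records=records, label=cohort.label + "/sim",
                  provenance="null-simulated", seed=cohort.seed)


def gender_lead_test(girls: Cohort, boys: Cohort, max_lead: float = 3.0,
                     n_reps: int = 1000, seed: int = 0, span: float = 0.20,
                     search_range: tuple[float, float] = (60.0, 96.0)
                     ) -> MCResult:
    """Is a girls' dip of the observed magnitude, up to ``max_lead`` months
    before the boys' trough but not after it, explicable by chance?

    The joint event — girls' dip depth at least as large as observed AND
    girls' trough inside ``[boys' trough - max_lead, boys' trough]`` — is
    evaluated under the girls' monotone null.  Raises if no dip is
    detectable in the boys' smoothed curve (the reference trough is then
    undefined).
    """
    girls_curve = _smoothed_values(girls, span)
    boys_curve = _smoothed_values(boys, span)
    boys_dip = detect_dip(boys_curve, search_range)
    if boys_dip is None:
        raise ValueError("no detectable dip in the boys' curve; "
                         "the lead test is undefined")
    girls_dip = detect_dip(girls_curve, search_range)
    if girls_dip is None:
        raise ValueError("no detectable dip in the girls' curve")
    lo, hi = boys_dip.trough_age - max_lead, boys_dip.trough_age
    if not (lo <= girls_dip.trough_age <= hi):
        # the lead pattern is not present in the observed data at all
        return MCResult(
            statistic="girls-lead dip (not observed)",
            observed={0.0: girls_dip.depth},
            p_values={0.0: 1.0},
            headline_p=1.0,
            n_reps=0,
            seed=seed,
        )

    null = fit_null(girls)
    rng = np.random.SeedSequence(seed)
    rep_seeds = rng.generate_state(n_reps)
    exceed = 0
    for rep in range(n_reps):
        sim = simulate_null(null, girls, int(rep_seeds[rep]))
        sim_dip = detect_dip(_smoothed_values(sim, span), search_range)
        if (
            sim_dip is not None
            and sim_dip.depth >= girls_dip.depth
            and lo <= sim_dip.trough_age <= hi
        ):
            exceed += 1
    p = (1 + exceed) / (1 + n_reps)
    return MCResult(
        statistic="girls-lead dip",
        observed={0.0: girls_dip.depth},
        p_values={0.0: p},
        headline_p=p,
        n_reps=n_reps,
        seed=seed,
    )
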