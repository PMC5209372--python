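"""Synthetic cross-sectional cohorts with planted developmental structure.

The generator stands in for the (undeposited) study data.  Each child follows
their gender's coupled-growers mean trajectory, time-shifted by a personal
``Normal(0, onset_sd)`` delay in transition timing and displaced by a personal
level offset; an age-constant residual is added on top and the result is
rounded and clamped to the 0–110 score range.  The single time-shift device
is what produces the three cross-sectional transition signatures — moving
skewness that changes sign across each growth spurt, moving-SD peaks near the
spurts, and growth-rate peaks — without scripting any of them directly.

Sub-scores are allocated deterministically from the total with an
age-dependent tilt so that every rescaled sub-score curve dips near the same
ages and the beliefs sub-score dips steepest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from tomgrowth.data_model import (
    AgeGenderDesign,
    ChildRecord,
    Cohort,
    SUBSCORE_COLUMNS,
    SUBSCORE_MAXIMA,
    SUM_SCORE_MAX,
)
from tomgrowth.growth_model import (
    BOYS_PARAMS,
    GIRLS_PARAMS,
    GrowthParams,
    SupporterSpec,
    Trajectory,
    simulate,
    supporter_level,
)

#: Expected share of the total carried by each sub-score, away from the dip:
#: the sub-score ceilings as fractions of the 110-point total.
DEFAULT_SUBSCORE_WEIGHTS: dict[str, float] = {
    name: maximum / SUM_SCORE_MAX for name, maximum in SUBSCORE_MAXIMA.items()
}

#: Relative extra steepness of each sub-score's dip (beliefs steepest;
#: the three-item seeing-knowing scale is too coarse to carry a tilt).
DEFAULT_DIP_SHARPNESS: dict[str, float] = {
    "sub_er": 0.05,
    "sub_mp": 0.10,
    "sub_sk": 0.00,
    "sub_des": 0.15,
    "sub_bel": 0.30,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Full configuration of the synthetic cohort generator.

    Defaults encode the reference study design (N=324, the age-by-gender
    table) and the per-gender growth parameters; ``onset_sd`` is the
    between-child SD of transition timing (months), ``level_offset_sd`` a
    stable per-child ability offset and ``residual_sd`` age-constant
    measurement noise (both in points).
    """

    design: AgeGenderDesign = field(default_factory=AgeGenderDesign)
    gender_params: Mapping[str, GrowthParams] = field(
        default_factory=lambda: {"F": GIRLS_PARAMS, "M": BOYS_PARAMS}
    )
    onset_centers: tuple[float, float] = (56.0, 72.0)
    onset_rates: tuple[float, float] = (1.0, 1.0)
    consolidation_rates: tuple[float, float] = (1.0, 0.2)
    consolidation_lags: tuple[float, float] = (0.0, 14.0)
    onset_sd: float = 3.0
    level_offset_sd: float = 4.0
    residual_sd: float = 5.0
    subscore_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBSCORE_WEIGHTS)
    )
    dip_sharpness: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIP_SHARPNESS)
    )
    admin_count: int = 8
    admin_block_size: int = 4
    #: Optional planted anomalous administrator: their children inside the age
    #: window get deflated by ``anomalous_deflation`` points (positive control
    #: for the leave-one-out procedure).
    anomalous_admin: int | None = None
    anomalous_deflation: float = 0.0
    anomalous_window: tuple[float, float] = (70.0, 86.0)
    seed: int = 0

    def __post_init__(self) -> None:
        total_weight = sum(self.subscore_weights.values())
        if abs(total_weight - 1.0) > 1e-9:
            raise ValueError(f"subscore weights sum to {total_weight}, not 1")
        if self.onset_sd < 0 or self.residual_sd < 0 or self.level_offset_sd < 0:
            raise ValueError("noise SDs must be non-negative")

    def supporters(self) -> tuple[SupporterSpec, SupporterSpec]:
        return (
            SupporterSpec(onset_age=self.onset_centers[0],
                          rate=self.onset_rates[0],
                          consolidation_rate=self.consolidation_rates[0],
                          consolidation_lag=self.consolidation_lags[0]),
            SupporterSpec(onset_age=self.onset_centers[1],
                          rate=self.onset_rates[1],
                          consolidation_rate=self.consolidation_rates[1],
                          consolidation_lag=self.consolidation_lags[1]),
        )


# Trajectories are evaluated on an extended grid so personal time-shifts near
# the age-range edges stay on the curve.
_EXTENDED_LO, _EXTENDED_HI = 24.0, 160.0
_trajectory_cache: dict[tuple, Trajectory] = {}


def _extended_trajectory(params: GrowthParams,
                         supporters: tuple[SupporterSpec, SupporterSpec]
                         ) -> Trajectory:
    """Gender mean trajectory on [24, 160] months.

    The grower is started at 24 months from the level that places it at
    ``params.L0`` by 36 months under the baseline (pre-supporter) logistic.
    """
    key = (params, supporters)
    if key not in _trajectory_cache:
        cap0 = params.K * params.kappa_0
        x36 = params.L0 / cap0
        x24 = x36 / (x36 + (1 - x36) * np.exp(params.r * (36.0 - _EXTENDED_LO)))
        start = dataclasses.replace(params, L0=x24 * cap0)
        grid = np.arange(_EXTENDED_LO, _EXTENDED_HI + 1.0)
        _trajectory_cache[key] = simulate(start, *supporters, t_grid=grid)
    return _trajectory_cache[key]


def expected_score(age_months, gender: str, config: GeneratorConfig) -> np.ndarray:
    """Deterministic mean sum-score at an age (months) for one gender.

    This is the coupled-growers trajectory of that gender's parameters — the
    same code path as :func:`tomgrowth.growth_model.simulate` — interpolated
    at the requested ages.
    """
    ages = np.asarray(age_months, dtype=float)
    if np.any((ages < 36) | (ages > 143)):
        raise ValueError("age out of the 36-143 month range")
    traj = _extended_trajectory(config.gender_params[gender], config.supporters())
    return traj(ages)


def sample_ages(design: AgeGenderDesign, seed: int) -> list[tuple[int, str]]:
    """Exact per-bin, per-gender ages: month-of-age uniform within each bin."""
    rng = np.random.default_rng(seed)
    pairs: list[tuple[int, str]] = []
    for (lo, hi), boys, girls in design.bins:
        for count, gender in ((boys, "M"), (girls, "F")):
            ages = rng.integers(lo, hi + 1, size=count)
            pairs.extend((int(a), gender) for a in ages)
    return pairs


def _dip_shape(ages, config: GeneratorConfig) -> np.ndarray:
    """Normalized emergence-change bump of supporter B: 1 at the steepest
    point of B's rise (where the planted dip is deepest), 0 far away."""
    spec = config.supporters()[1]
    t = np.asarray(ages, dtype=float)
    level = supporter_level(spec, t)
    change = spec.rate * level * (1 - level / spec.ceiling)
    peak = spec.rate * spec.ceiling / 4.0
    return change / peak


def allocate_subscores(total: int, age_months: float,
                       config: GeneratorConfig | None = None) -> tuple[int, ...]:
    """Split a total into the five sub-scores (exact sum, ceilings respected).

    Expected proportions follow ``subscore_weights`` with an age-dependent
    tilt: inside the dip window each sub-score's share is reduced in
    proportion to its ``dip_sharpness``, so rescaled sub-score curves dip
    together and beliefs dips steepest.  Largest-remainder rounding.
    """
    if config is None:
        config = _default_config()
    if not (0 <= total <= SUM_SCORE_MAX):
        raise ValueError(f"total {total} outside [0, {SUM_SCORE_MAX}]")
    shape = float(_dip_shape(age_months, config))
    weights = np.array([
        config.subscore_weights[c] * (1 - config.dip_sharpness[c] * shape)
        for c in SUBSCORE_COLUMNS
    ])
    weights = weights / weights.sum()
    maxima = np.array([SUBSCORE_MAXIMA[c] for c in SUBSCORE_COLUMNS], dtype=float)
    return _largest_remainder(total, weights, maxima)


def allocate_subscores_flat(total: int) -> tuple[int, ...]:
    """Ceiling-proportional allocation without any age tilt."""
    weights = np.array([DEFAULT_SUBSCORE_WEIGHTS[c] for c in SUBSCORE_COLUMNS])
    maxima = np.array([SUBSCORE_MAXIMA[c] for c in SUBSCORE_COLUMNS], dtype=float)
    if not (0 <= total <= SUM_SCORE_MAX):
        raise ValueError(f"total {total} outside [0, {SUM_SCORE_MAX}]")
    return _largest_remainder(total, weights, maxima)


def _largest_remainder(total: int, weights: np.ndarray, maxima: np.ndarray
                       ) -> tuple[int, ...]:
    """Integer apportionment of ``total`` by weight, capped at per-cell maxima."""
    target = weights * total
    # Redistribute any excess above a ceiling among unsaturated cells.
    for _ in range(len(weights)):
        over = target > maxima
        if not np.any(over):
            break
        excess = float(np.sum(target[over] - maxima[over]))
        target[over] = maxima[over]
        room = ~over & (target < maxima)
        if not np.any(room):
            break
        target[room] += excess * weights[room] / weights[room].sum()
    floors = np.floor(target).astype(int)
    floors = np.minimum(floors, maxima.astype(int))
    remainder = int(total - floors.sum())
    frac = target - floors
    order = np.argsort(-frac, kind="stable")
    out = floors.copy()
    i = 0
    while remainder > 0:
        idx = order[i % len(order)]
        if out[idx] < maxima[idx]:
            out[idx] += 1
            remainder -= 1
        i += 1
        if i > 10 * len(order) and remainder > 0:  # all saturated
            raise ValueError("total exceeds the sum of sub-score ceilings")
    return tuple(int(v) for v in out)


_DEFAULT_CONFIG: GeneratorConfig | None = None


def _default_config() -> GeneratorConfig:
    global _DEFAULT_CONFIG
    if _DEFAULT_CONFIG is None:
        _DEFAULT_CONFIG = GeneratorConfig()
    return _DEFAULT_CONFIG


def generate_cohort(config: GeneratorConfig | None = None,
                    seed: int | None = None) -> Cohort:
    """Generate one synthetic cross-sectional cohort.

    Deterministic in ``(config, seed)``; ``seed`` overrides ``config.seed``.
    """
    if config is None:
        config = _default_config()
    if seed is None:
        seed = config.seed
    age_seed, noise_seed = np.random.SeedSequence(seed).spawn(2)
    pairs = sample_ages(config.design, np.random.default_rng(age_seed)
                        .integers(0, 2**31))
    # Sort by age (stable) so administrator blocks are contiguous in age but
    # every administrator still covers the whole range via round-robin deals.
    pairs.sort(key=lambda p: p[0])
    n = len(pairs)
    rng = np.random.default_rng(noise_seed)
    shifts = rng.normal(0.0, config.onset_sd, n) if config.onset_sd > 0 else \
        np.zeros(n)
    offsets = rng.normal(0.0, config.level_offset_sd, n) \
        if config.level_offset_sd > 0 else np.zeros(n)
    noise = rng.normal(0.0, config.residual_sd, n) if config.residual_sd > 0 \
        else np.zeros(n)

    supporters = config.supporters()
    trajs = {
        g: _extended_trajectory(p, supporters)
        for g, p in config.gender_params.items()
    }

    records: list[ChildRecord] = []
    for i, (age, gender) in enumerate(pairs):
        shifted = float(np.clip(age + shifts[i], _EXTENDED_LO, _EXTENDED_HI))
        expected = float(trajs[gender](shifted))
        admin = 1 + (i // config.admin_block_size) % config.admin_count
        total = expected + offsets[i] + noise[i]
        if (
            config.anomalous_admin is not None
            and admin == config.anomalous_admin
            and config.anomalous_window[0] <= age <= config.anomalous_window[1]
        ):
            total -= config.anomalous_deflation
        total = int(np.clip(np.round(total), 0, SUM_SCORE_MAX))
        subs = allocate_subscores(total, age, config)
        records.append(
            ChildRecord(
                child_id=f"C{i:04d}",
                age_months=int(age),
                gender=gender,
                administrator_id=admin,
                sum_score=total,
                **dict(zip(SUBSCORE_COLUMNS, subs)),
            )
        )
    return Cohort(records=records, label=f"synthetic-seed{seed}",
                  provenance="synthetic", seed=seed)
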