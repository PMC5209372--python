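"""Monotone-growth null: fitting, simulation, dip statistics, MC tests."""

import numpy as np
import pytest

from tomgrowth.data_model import ChildRecord, Cohort
from tomgrowth.mc_inference import (
    NullModel,
    dip_depth_from_curve,
    dip_depth_stat,
    fit_null,
    gender_lead_test,
    leave_one_out_admin,
    mc_test,
    negative_slope_from_curve,
    negative_slope_stat,
    simulate_null,
)
from tomgrowth.smoothing import SmoothedCurve
from tomgrowth.synthetic import (
    GeneratorConfig,
    allocate_subscores_flat,
    generate_cohort,
)


def cohort_from_scores(ages, scores):
    records = [
        ChildRecord(f"c{i}", int(a), "F" if i % 2 else "M", 1 + i % 4,
                    int(s), *allocate_subscores_flat(int(s)))
        for i, (a, s) in enumerate(zip(ages, scores))
    ]
    return Cohort(records=records, label="fixture")


def monotone_cohort(rng, n=120, noise=4.0):
    ages = np.sort(rng.integers(36, 144, n))
    mean = 30 + 0.55 * (ages - 36)
    scores = np.clip(np.round(mean + rng.normal(0, noise, n)), 0, 110)
    return cohort_from_scores(ages, scores)


class TestFitNull:
    def test_pava_pools_adjacent_violators_on_toy_vector(self):
        """The hand-computed pool-adjacent-violators solution for
        {1,3,2,4,6,5} is {1,2.5,2.5,4,5.5,5.5}."""
        from sklearn.isotonic import IsotonicRegression

        fitted = IsotonicRegression(increasing=True).fit_transform(
            np.arange(6), np.array([1.0, 3.0, 2.0, 4.0, 6.0, 5.0])
        )
        np.testing.assert_allclose(fitted, [1, 2.5, 2.5, 4, 5.5, 5.5])

    def test_monotone_means_recovered_on_noise_free_input(self):
        ages = np.repeat(np.arange(40, 100, 4), 4)
        scores = np.repeat(np.arange(30, 90, 4), 4)
        null = fit_null(cohort_from_scores(ages, scores))
        predicted = null.mean_at(np.arange(44, 96, 4))
        np.testing.assert_allclose(predicted, np.arange(34, 86, 4), atol=1.0)

    def test_mean_is_always_non_decreasing(self, default_cohort):
        null = fit_null(default_cohort)
        assert np.all(np.diff(null.mean) >= -1e-9)
        assert np.all(null.sd > 0)

    def test_small_cohort_rejected(self):
        tiny = cohort_from_scores(range(40, 50), range(10))
        with pytest.raises(ValueError):
            fit_null(tiny)


class TestSimulateNull:
    def test_vanishing_sd_reproduces_rounded_mean(self, default_cohort):
        null = fit_null(default_cohort)
        degenerate = NullModel(grid=null.grid, mean=null.mean,
                               sd=np.full_like(null.sd, 1e-12))
        sim = simulate_null(degenerate, default_cohort, seed=0)
        for rec in sim:
            # within half a point of the monotone mean (exact .5 boundaries
            # may round either way under vanishing noise)
            mean = float(degenerate.mean_at(rec.age_months))
            assert abs(rec.sum_score - np.clip(mean, 0, 110)) <= 0.5 + 1e-9

    def test_same_seed_same_cohort(self, default_cohort):
        null = fit_null(default_cohort)
        a = simulate_null(null, default_cohort, seed=5)
        b = simulate_null(null, default_cohort, seed=5)
        assert a.records == b.records

    def test_replicate_means_unbiased_away_from_clamps(self, default_cohort):
        null = fit_null(default_cohort)
        age = 70
        draws = [
            simulate_null(null, default_cohort, seed=s)
            for s in range(300)
        ]
        values = np.array([
            np.mean([r.sum_score for r in sim if r.age_months == age])
            for sim in draws
        ])
        se = null.sd_at(age) / np.sqrt(
            sum(1 for r in default_cohort if r.age_months == age) * 300
        )
        assert abs(values.mean() - null.mean_at(age)) < 3 * se + 0.5

    def test_template_metadata_copied(self, default_cohort):
        null = fit_null(default_cohort)
        sim = simulate_null(null, default_cohort, seed=1)
        for a, b in zip(default_cohort, sim):
            assert (a.child_id, a.age_months, a.gender, a.administrator_id) \
                == (b.child_id, b.age_months, b.gender, b.administrator_id)
        assert sim.provenance == "null-simulated"


def brute_force_dip(curve, window_len):
    grid, v = curve.grid, curve.values
    best = 0.0
    for i in range(grid.size):
        for j in range(i + 1, grid.size):
            if grid[j] - grid[i] > window_len:
                break
            best = max(best, v[i] - v[j])
    return best


def brute_force_slope(curve, interval_len):
    grid, v = curve.grid, curve.values
    worst = np.inf
    for i in range(grid.size):
        for j in range(i + 1, grid.size):
            if abs((grid[j] - grid[i]) - interval_len) < 1e-9:
                worst = min(worst, (v[j] - v[i]) / (grid[j] - grid[i]))
    return worst


class TestDipStatistics:
    def crafted_curves(self):
        grid = np.arange(36.0, 144.0)
        flat_v = np.full(grid.size, 50.0)
        trough = np.searchsorted(grid, 78)
        flat_v[trough - 5:trough + 6] -= 5.0 * (
            1 - np.abs(np.arange(-5, 6)) / 5.0
        )
        rising = SmoothedCurve(grid=grid, values=0.7 * grid, span=0.2,
                               degree=2)
        notched = SmoothedCurve(grid=grid, values=flat_v, span=0.2, degree=2)
        return rising, notched

    def test_monotone_curve_has_zero_dip_depth(self):
        rising, _ = self.crafted_curves()
        assert dip_depth_from_curve(rising, 8) == 0.0

    def test_crafted_notch_depth_recovered(self):
        _, notched = self.crafted_curves()
        assert dip_depth_from_curve(notched, 6) == pytest.approx(5.0)

    def test_linear_decline_slope_recovered(self):
        grid = np.arange(36.0, 144.0)
        v = np.where(grid < 80, 60.0, 60.0 - 0.5 * (grid - 80))
        curve = SmoothedCurve(grid=grid, values=v, span=0.2, degree=2)
        assert negative_slope_from_curve(curve, 10) == pytest.approx(-0.5)

    @pytest.mark.parametrize("window", [4.0, 6.0, 10.0])
    def test_dip_depth_equals_brute_force(self, default_curve, window):
        assert dip_depth_from_curve(default_curve, window) == pytest.approx(
            brute_force_dip(default_curve, window), abs=1e-12
        )

    @pytest.mark.parametrize("window", [4.0, 8.0])
    def test_negative_slope_equals_brute_force(self, default_curve, window):
        assert negative_slope_from_curve(
            default_curve, window
        ) == pytest.approx(brute_force_slope(default_curve, window),
                           abs=1e-12)

    def test_cohort_level_wrappers(self, default_cohort):
        depth = dip_depth_stat(default_cohort, window_len=6)
        slopes = negative_slope_stat(default_cohort, interval_lens=(4, 6))
        assert depth > 0
        assert set(slopes) == {4.0, 6.0}

    def test_window_longer_than_range_rejected(self, default_curve):
        with pytest.raises(ValueError):
            dip_depth_from_curve(default_curve, 200)


class TestMcTest:
    def test_p_values_respect_add_one_floor(self, default_cohort):
        res = mc_test(default_cohort, n_reps=99, seed=3)
        for p in res.p_values.values():
            assert 1 / 100 <= p <= 1.0
        assert res.min_p == min(res.p_values.values())

    def test_deterministic_given_seed(self, default_cohort):
        a = mc_test(default_cohort, n_reps=99, seed=7)
        b = mc_test(default_cohort, n_reps=99, seed=7)
        assert a.p_values == b.p_values

    def test_null_drawn_cohort_is_not_significant(self, rng):
        cohort = monotone_cohort(rng, n=200)
        res = mc_test(cohort, n_reps=99, seed=1)
        assert res.min_p > 0.05

    def test_detection_rate_grows_with_planted_depth(self):
        """Power is monotone in the size of the planted regression."""
        rates = []
        for depth in (0.0, 4.0, 10.0):
            hits = 0
            for seed in range(6):
                rng = np.random.default_rng(100 + seed)
                ages = np.sort(rng.integers(36, 144, 250))
                mean = 30 + 0.55 * (ages - 36)
                bump = depth * np.exp(-((ages - 78) / 4.0) ** 2)
                scores = np.clip(
                    np.round(mean - bump + rng.normal(0, 5, ages.size)),
                    0, 110)
                cohort = cohort_from_scores(ages, scores)
                res = mc_test(cohort, n_reps=99, seed=seed,
                              window_lens=(6, 10))
                hits += res.min_p <= 0.05
            rates.append(hits / 6)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > rates[0]

    def test_too_few_reps_rejected(self, default_cohort):
        with pytest.raises(ValueError):
            mc_test(default_cohort, n_reps=50)


class TestLeaveOneOut:
    def test_single_administrator_rejected(self):
        ages = range(40, 100)
        records = [
            ChildRecord(f"c{i}", a, "F", 1, 50,
                        *allocate_subscores_flat(50))
            for i, a in enumerate(ages)
        ]
        with pytest.raises(ValueError, match="two administrators"):
            leave_one_out_admin(Cohort(records=records))

    def test_returns_one_result_per_administrator(self, default_cohort):
        results = leave_one_out_admin(default_cohort, n_reps=99, seed=2)
        assert sorted(results) == default_cohort.administrators()


class TestGenderLeadTest:
    def test_identical_cohorts_satisfy_the_lead_event(self, default_cohort):
        girls = default_cohort.by_gender("F")
        res = gender_lead_test(girls, girls, n_reps=99, seed=0)
        assert 0 < res.headline_p <= 1

    @staticmethod
    def pooled_gender(config, gender, seeds=range(1, 4)):
        """Several generator replicates merged, to stabilise the per-gender
        trough location (a single gender subsample is only ~160 children)."""
        import dataclasses as dc

        records = []
        for s in seeds:
            part = generate_cohort(config, seed=s).by_gender(gender)
            records.extend(
                dc.replace(r, child_id=f"s{s}-{r.child_id}") for r in part
            )
        return Cohort(records=records, label=f"pooled-{gender}",
                      provenance="synthetic")

    def test_girls_dip_planted_earlier_is_detected(self):
        early = GeneratorConfig(onset_centers=(56.0, 70.0))
        girls = self.pooled_gender(early, "F")
        boys = self.pooled_gender(GeneratorConfig(), "M")
        res = gender_lead_test(girls, boys, n_reps=199, seed=5)
        assert res.headline_p <= 0.05

    def test_girls_dip_planted_later_is_not(self):
        late = GeneratorConfig(onset_centers=(56.0, 78.0))
        girls = self.pooled_gender(late, "F")
        boys = self.pooled_gender(GeneratorConfig(), "M")
        res = gender_lead_test(girls, boys, n_reps=199, seed=5)
        assert res.headline_p > 0.05

    def test_undetectable_boys_dip_raises(self, rng):
        flat = monotone_cohort(rng, n=200)
        with pytest.raises(ValueError, match="boys"):
            gender_lead_test(flat, flat, n_reps=99, seed=0)
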