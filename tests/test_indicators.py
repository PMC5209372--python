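"""Moving-window statistics, growth rate, association and peak ordering."""

import numpy as np
import pytest

from tomgrowth.data_model import ChildRecord, Cohort
from tomgrowth.indicators import (
    IndicatorSeries,
    growth_rate_series,
    moving_statistic,
    peak_ordering,
    series_association,
    smooth_indicator,
)
from tomgrowth.smoothing import SmoothedCurve, differentiate
from tomgrowth.synthetic import allocate_subscores_flat


def cohort_from_scores(ages, scores):
    records = [
        ChildRecord(f"c{i}", int(a), "F" if i % 2 else "M", 1 + i % 8,
                    int(s), *allocate_subscores_flat(int(s)))
        for i, (a, s) in enumerate(zip(ages, scores))
    ]
    return Cohort(records=records, label="fixture")


class TestMovingStatistic:
    def test_constant_scores_have_zero_sd(self):
        cohort = cohort_from_scores(range(36, 96), [50] * 60)
        series = moving_statistic(cohort, statistic="sd", window_frac=0.2)
        assert np.all(series.values == 0)

    def test_symmetric_window_has_zero_skewness(self):
        cohort = cohort_from_scores(range(40, 48), [1, 2, 3, 4, 5, 6, 7, 8])
        series = moving_statistic(cohort, statistic="skewness",
                                  window_frac=1.0)
        assert series.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_skewness_matches_three_pass_formula(self):
        """Adjusted Fisher-Pearson on an asymmetric window against a
        from-scratch three-pass computation."""
        data = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 100.0])
        n = data.size
        mean = data.sum() / n
        m2 = ((data - mean) ** 2).sum() / n
        m3 = ((data - mean) ** 3).sum() / n
        expected = (m3 / m2**1.5) * np.sqrt(n * (n - 1)) / (n - 2)

        cohort = cohort_from_scores(range(60, 68), data)
        series = moving_statistic(cohort, statistic="skewness",
                                  window_frac=1.0)
        assert series.values[0] == pytest.approx(expected, rel=1e-12)

    def test_window_too_small_rejected(self):
        cohort = cohort_from_scores(range(36, 46), range(10))
        with pytest.raises(ValueError, match="too small"):
            moving_statistic(cohort, statistic="skewness", window_frac=0.2)

    def test_center_age_is_window_median(self):
        cohort = cohort_from_scores([40, 41, 42, 50, 60], [1, 2, 3, 4, 5])
        series = moving_statistic(cohort, statistic="sd", window_frac=0.6)
        assert series.center_ages[0] == 41.0


class TestGrowthRate:
    def test_logistic_curve_gives_single_positive_peak(self):
        grid = np.arange(36.0, 144.0)
        curve = SmoothedCurve(grid=grid,
                              values=100 / (1 + np.exp(-(grid - 80) / 9)),
                              span=0.2, degree=2)
        fd = growth_rate_series(curve)
        assert fd.statistic == "FD"
        assert np.all(fd.values > 0)
        peak_age = fd.center_ages[np.argmax(fd.values)]
        assert abs(peak_age - 80) <= 1

    def test_equals_differentiate_exactly(self, default_curve):
        fd = growth_rate_series(default_curve)
        np.testing.assert_array_equal(
            fd.values, differentiate(default_curve).values
        )

    def test_dip_pushes_growth_rate_negative(self):
        grid = np.arange(36.0, 144.0)
        values = np.full(grid.size, 60.0)
        values[40:47] -= np.array([2, 4, 6, 6, 6, 4, 2], dtype=float)
        curve = SmoothedCurve(grid=grid, values=values, span=0.2, degree=2)
        assert growth_rate_series(curve).values.min() < 0


class TestSmoothIndicator:
    def test_constant_series_unchanged(self):
        series = IndicatorSeries(center_ages=np.arange(40.0, 100.0),
                                 values=np.full(60, 3.3), statistic="sd")
        out = smooth_indicator(series)
        np.testing.assert_allclose(out.values, 3.3, atol=1e-9)

    def test_linear_series_unchanged(self):
        ages = np.arange(40.0, 100.0)
        series = IndicatorSeries(center_ages=ages, values=0.1 * ages - 2,
                                 statistic="sd")
        out = smooth_indicator(series)
        np.testing.assert_allclose(out.values, 0.1 * ages - 2, atol=1e-9)

    def test_smoothing_reduces_roughness(self, rng):
        ages = np.arange(40.0, 120.0)
        noisy = np.sin(ages / 8) + rng.normal(0, 0.5, ages.size)
        series = IndicatorSeries(center_ages=ages, values=noisy,
                                 statistic="skewness")
        out = smooth_indicator(series)
        rough = lambda v: np.sum(np.diff(v, 2) ** 2)
        assert rough(out.values) < rough(noisy)


class TestSeriesAssociation:
    def test_self_correlation_is_one(self):
        ages = np.arange(40.0, 90.0)
        s = IndicatorSeries(center_ages=ages, values=np.sin(ages / 7),
                            statistic="x")
        out = series_association(s, s)
        assert out["correlation"] == pytest.approx(1.0)

    def test_negated_series_correlate_minus_one(self):
        ages = np.arange(40.0, 90.0)
        s = IndicatorSeries(center_ages=ages, values=np.sin(ages / 7),
                            statistic="x")
        t = IndicatorSeries(center_ages=ages, values=-np.sin(ages / 7),
                            statistic="y")
        assert series_association(s, t)["correlation"] == pytest.approx(-1.0)

    def test_covariance_matches_hand_formula(self):
        xa = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        xb = np.array([2.0, 3.0, 7.0, 6.0, 4.0])
        ages = np.arange(60.0, 65.0)
        out = series_association(
            IndicatorSeries(center_ages=ages, values=xa, statistic="a"),
            IndicatorSeries(center_ages=ages, values=xb, statistic="b"),
        )
        hand = np.sum((xa - xa.mean()) * (xb - xb.mean())) / (xa.size - 1)
        assert out["covariance"] == pytest.approx(hand, rel=1e-12)

    def test_symmetric_and_affine_invariant_correlation(self):
        ages = np.arange(40.0, 90.0)
        a = IndicatorSeries(center_ages=ages, values=np.cos(ages / 9),
                            statistic="a")
        b = IndicatorSeries(center_ages=ages,
                            values=np.cos(ages / 9) + 0.3 * ages,
                            statistic="b")
        ab = series_association(a, b)
        ba = series_association(b, a)
        assert ab["correlation"] == pytest.approx(ba["correlation"])
        b2 = IndicatorSeries(center_ages=ages, values=5 * b.values - 7,
                             statistic="b2")
        assert series_association(a, b2)["correlation"] == pytest.approx(
            ab["correlation"]
        )

    def test_disjoint_ranges_rejected(self):
        a = IndicatorSeries(center_ages=np.arange(40.0, 50.0),
                            values=np.ones(10), statistic="a")
        b = IndicatorSeries(center_ages=np.arange(60.0, 70.0),
                            values=np.ones(10), statistic="b")
        with pytest.raises(ValueError):
            series_association(a, b)


class TestPeakOrdering:
    @staticmethod
    def double_bump(ages, centers):
        return sum(np.exp(-((ages - c) / 6.0) ** 2) for c in centers)

    def test_identical_series_have_zero_lags(self):
        ages = np.arange(36.0, 144.0)
        v = self.double_bump(ages, (60, 90))
        s = IndicatorSeries(center_ages=ages, values=v, statistic="x")
        pairs = peak_ordering(s, s, n_peaks=2)
        assert len(pairs) == 2
        assert all(lag == 0 for _, _, lag in pairs)

    def test_shifted_series_recovers_the_shift(self):
        ages = np.arange(36.0, 144.0)
        a = IndicatorSeries(center_ages=ages,
                            values=self.double_bump(ages, (60, 90)),
                            statistic="a")
        b = IndicatorSeries(center_ages=ages,
                            values=self.double_bump(ages, (64, 94)),
                            statistic="b")
        for _, _, lag in peak_ordering(a, b, n_peaks=2):
            assert lag == pytest.approx(4.0, abs=0.5)

    def test_fewer_peaks_than_requested_returns_what_exists(self):
        ages = np.arange(36.0, 144.0)
        a = IndicatorSeries(center_ages=ages,
                            values=self.double_bump(ages, (70,)),
                            statistic="a")
        b = IndicatorSeries(center_ages=ages,
                            values=self.double_bump(ages, (60, 90)),
                            statistic="b")
        assert len(peak_ordering(a, b, n_peaks=2)) == 1
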