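"""Two-phase decay, microbial growth, TMA accumulation and pH drift."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qimshelf.kinetics import (
    AssaySeries,
    GrowthFit,
    crossing_from_growth,
    crossing_from_two_phase,
    fit_growth,
    fit_two_phase,
    ph_trend,
    read_assay_series,
    tma_crossing,
    write_assay_series,
)

from .conftest import two_phase_series


class TestAssaySeries:
    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            AssaySeries("tma", [0.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_unknown_assay_rejected(self):
        with pytest.raises(ValueError, match="unknown assay"):
            AssaySeries("colour", [0.0], [1.0])

    def test_csv_roundtrip(self, tmp_path):
        series = {"tma": AssaySeries("tma", [0.0, 7.0], [5.6, 9.0])}
        path = tmp_path / "assays.csv"
        write_assay_series(series, path)
        back = read_assay_series(path)
        assert np.allclose(back["tma"].times, [0.0, 7.0])
        assert np.allclose(back["tma"].values, [5.6, 9.0])


class TestTwoPhase:
    def test_noiseless_recovery_is_exact(self):
        fit = fit_two_phase(two_phase_series())
        assert fit.slope1 == pytest.approx(-0.809, abs=1e-9)
        assert fit.slope2 == pytest.approx(-0.375, abs=1e-9)
        assert 11 < fit.breakpoint_day < 12
        assert fit.r2_1 == pytest.approx(1.0)
        assert fit.r2_2 == pytest.approx(1.0)

    def test_single_line_degenerate_tie_goes_earliest(self):
        t = np.arange(8, dtype=float)
        series = AssaySeries("torrymeter", t, 16.0 - 0.5 * t)
        fit = fit_two_phase(series)
        assert fit.slope1 == pytest.approx(-0.5)
        assert fit.slope2 == pytest.approx(-0.5)
        assert fit.breakpoint_day == pytest.approx(2.5)  # between 3rd and 4th point

    def test_five_points_error(self):
        t = np.arange(5, dtype=float)
        with pytest.raises(ValueError, match=">=6"):
            fit_two_phase(AssaySeries("torrymeter", t, 16.0 - t))

    def test_segmented_sse_never_worse_than_single_line(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            series = two_phase_series(noise_sd=0.4, rng=rng)
            fit = fit_two_phase(series)
            res = np.polyfit(series.times, series.values, 1)
            single_sse = float(
                np.sum((series.values - np.polyval(res, series.times)) ** 2)
            )
            assert fit.total_sse <= single_sse + 1e-9


class TestTwoPhaseCrossing:
    def test_limit_value_crossed_in_first_phase(self):
        fit = fit_two_phase(two_phase_series())
        est = crossing_from_two_phase(fit, 8.0)
        assert est.crossing_day == pytest.approx((16.8 - 8.0) / 0.809, abs=1e-6)
        assert est.interval == (10, 11)
        assert est.status == "crossed"

    def test_threshold_above_initial_value(self):
        fit = fit_two_phase(two_phase_series())
        assert crossing_from_two_phase(fit, 17.0).status == "before_window"

    def test_threshold_below_final_value(self):
        fit = fit_two_phase(two_phase_series())
        assert crossing_from_two_phase(fit, 0.5).status == "beyond_window"

    def test_threshold_at_breakpoint_value(self):
        fit = fit_two_phase(two_phase_series())
        v_bp = fit.intercept1 + fit.slope1 * fit.breakpoint_day
        est = crossing_from_two_phase(fit, v_bp)
        assert est.crossing_day == pytest.approx(fit.breakpoint_day)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(min_value=3.0, max_value=15.0))
    def test_crossing_monotone_in_threshold(self, threshold):
        # stricter (lower) limit on a falling indicator is reached later
        fit = fit_two_phase(two_phase_series())
        a = crossing_from_two_phase(fit, threshold)
        b = crossing_from_two_phase(fit, threshold - 1.0)
        if a.status == "crossed" and b.status == "crossed":
            assert b.crossing_day >= a.crossing_day - 1e-9


class TestGrowth:
    def test_two_point_line(self):
        series = AssaySeries("tvc_nt", [0.0, 7.0], [3.0, 6.0])
        fit = fit_growth(series)
        assert fit.slope == pytest.approx(3 / 7)
        assert fit.intercept == pytest.approx(3.0)

    def test_decreasing_series_warns(self):
        series = AssaySeries("tvc_nt", [0.0, 3.0, 6.0], [5.0, 4.0, 3.0])
        with pytest.warns(UserWarning, match="negative"):
            fit = fit_growth(series)
        assert fit.slope < 0

    def test_recovery_within_ci(self):
        rng = np.random.default_rng(11)
        t = np.linspace(0, 15, 10)
        series = AssaySeries("tvc_nt", t, 3.0 + 0.5 * t + rng.normal(0, 0.2, 10))
        fit = fit_growth(series)
        from scipy import stats

        res = stats.linregress(t, series.values)
        half = stats.t.ppf(0.975, 8) * res.stderr
        assert abs(fit.slope - 0.5) < half

    def test_window_restricts_fit(self):
        t = np.array([0.0, 3, 6, 9, 12, 15])
        v = np.where(t < 9, 3.0, 3.0 + 0.5 * (t - 9))  # lag then growth
        fit = fit_growth(AssaySeries("h2s", t, v), window=(9, 15))
        assert fit.slope == pytest.approx(0.5)


class TestGrowthCrossing:
    def test_analytic_crossing(self):
        fit = GrowthFit(slope=3 / 7, intercept=3.0, r2=1.0, t_min=0, t_max=15)
        est = crossing_from_growth(fit, 8.0)
        assert est.crossing_day == pytest.approx((8 - 3) / (3 / 7))
        assert est.interval == (11, 12)

    def test_threshold_at_intercept_is_day_zero(self):
        fit = GrowthFit(slope=0.5, intercept=3.0, r2=1.0, t_min=0, t_max=15)
        assert crossing_from_growth(fit, 3.0).crossing_day == pytest.approx(0.0)

    def test_flat_growth_never_crosses(self):
        fit = GrowthFit(slope=0.0, intercept=3.0, r2=0.0, t_min=0, t_max=15)
        assert crossing_from_growth(fit, 8.0).status == "beyond_window"

    def test_monotone_in_threshold(self):
        fit = GrowthFit(slope=0.45, intercept=3.0, r2=1.0, t_min=0, t_max=15)
        days = [
            crossing_from_growth(fit, th).crossing_day for th in np.linspace(4, 9, 11)
        ]
        assert all(a <= b for a, b in zip(days, days[1:]))


class TestTMACrossing:
    def test_regulatory_limit_crossed_between_days_12_and_13(self, tma_printed_series):
        est = tma_crossing(tma_printed_series, 12.0)
        expected = 12 + 3 * (12 - 11.1) / (20.7 - 11.1)
        assert est.crossing_day == pytest.approx(expected)
        assert est.interval == (12, 13)

    def test_rejection_value_slightly_later(self, tma_printed_series):
        est = tma_crossing(tma_printed_series, 12.5)
        assert est.crossing_day == pytest.approx(12 + 3 * (12.5 - 11.1) / (20.7 - 11.1))
        assert est.interval == (12, 13)

    def test_threshold_below_initial_content(self, tma_printed_series):
        assert tma_crossing(tma_printed_series, 5.0).status == "before_window"

    def test_threshold_beyond_window(self, tma_printed_series):
        assert tma_crossing(tma_printed_series, 25.0).status == "beyond_window"

    def test_empty_series_errors(self):
        with pytest.raises(ValueError, match="empty"):
            tma_crossing(AssaySeries("tma", [], []), 12.0)

    def test_non_monotone_dip_first_crossing_returned(self):
        series = AssaySeries("tma", [0, 5, 8, 10], [5.0, 13.0, 11.0, 15.0])
        est = tma_crossing(series, 12.0)
        assert est.crossing_day < 5.0

    def test_monotone_in_threshold(self, tma_printed_series):
        days = [
            tma_crossing(tma_printed_series, th).crossing_day
            for th in np.linspace(6, 20, 15)
        ]
        assert all(a <= b for a, b in zip(days, days[1:]))


class TestPHTrend:
    def test_flat_series_not_significant(self):
        trend = ph_trend(AssaySeries("ph", [0.0, 5.0, 10.0], [6.5, 6.5, 6.5]))
        assert trend.slope == 0.0
        assert trend.p_value == 1.0
        assert not trend.significant

    def test_exact_line_degenerate_minimal_p(self):
        t = np.array([0.0, 5, 10, 15])
        trend = ph_trend(AssaySeries("ph", t, 6.4 + 0.02 * t))
        assert trend.degenerate
        assert trend.p_value < 1e-12
        assert trend.significant

    def test_too_few_points(self):
        with pytest.raises(ValueError, match=">=3"):
            ph_trend(AssaySeries("ph", [0.0, 1.0], [6.4, 6.5]))

    def test_weak_drift_usually_not_significant(self):
        # the trial-scale pH drift should rarely reach significance
        from qimshelf.simulate import TrialConfig, generate_assay_series

        hits = 0
        for seed in range(1, 201):
            series, _ = generate_assay_series(TrialConfig(seed=seed), "ph")
            hits += ph_trend(series).significant
        assert hits / 200 < 0.5
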