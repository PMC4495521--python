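"""Calibration: consensus scoring, pairing, polynomial fits, median filter."""

from datetime import date, datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest

from moundwatch import (
    ActivitySample,
    ActivitySeries,
    AnnotationRecord,
    aggregate_operator_scores,
    apply_calibration,
    calibrate_series,
    count_activity_peaks,
    fit_calibration,
    median_filter_series,
    pair_samples,
    schedule_manual_windows,
)
from moundwatch.calibration import CalibrationError, CalibrationModel

UTC = timezone.utc
T0 = datetime(2010, 6, 1, tzinfo=UTC)


def normal_equations_fit(x, y, degree):
    """Independent least-squares oracle via explicit normal equations."""
    X = np.vander(np.asarray(x, float), degree + 1)
    beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(y, float))
    rms = float(np.sqrt(np.mean((X @ beta - y) ** 2)))
    return beta, rms


def samples_at(raws, start=T0, step=10, mode="day", flags=None):
    flags = flags or [True] * len(raws)
    return ActivitySeries(
        [
            ActivitySample(start + timedelta(seconds=i * step), r, mode, 0.0, ok)
            for i, (r, ok) in enumerate(zip(raws, flags))
        ]
    )


class TestConsensus:
    @pytest.mark.parametrize(
        "scores,expected",
        [((4, 4, 4), 4), ((3, 4, 5), 4), ((2, 3, 3), 3), ((0, 0, 1), 0), ((6, 7, 7), 7)],
    )
    def test_rounded_mean_half_up(self, scores, expected):
        assert aggregate_operator_scores(scores) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(CalibrationError, match="invalid category"):
            aggregate_operator_scores((1, 2, 8))

    def test_result_always_a_valid_category(self):
        for a in range(8):
            for b in range(8):
                for c in range(8):
                    assert 0 <= aggregate_operator_scores((a, b, c)) <= 7


class TestSchedule:
    def test_full_day_has_144_windows(self):
        windows = schedule_manual_windows(date(2010, 6, 1))
        assert len(windows) == 144
        assert windows[0][0] == T0
        assert windows[-1][0] == T0 + timedelta(hours=23, minutes=50)

    def test_half_day_has_72_windows(self):
        assert len(schedule_manual_windows(date(2010, 6, 1), span_hours=12)) == 72

    def test_hourly_cadence_has_24_windows(self):
        assert len(schedule_manual_windows(date(2010, 6, 1), cadence_minutes=60)) == 24

    def test_invalid_cadence_rejected(self):
        with pytest.raises(CalibrationError, match="invalid cadence"):
            schedule_manual_windows(date(2010, 6, 1), cadence_minutes=0)


class TestPairing:
    def test_flagged_samples_excluded_from_window_median(self):
        series = samples_at([10, 12, 900], flags=[True, True, False])
        ann = [AnnotationRecord(T0, (2, 2, 2))]
        s_d, s_n = pair_samples(series, ann, window_seconds=600)
        assert s_d == [(11.0, 2)] and s_n == []

    def test_window_without_samples_emits_no_pair(self):
        series = samples_at([5, 5])
        ann = [
            AnnotationRecord(T0, (1, 1, 1)),
            AnnotationRecord(T0 + timedelta(hours=2), (3, 3, 3)),
        ]
        s_d, _ = pair_samples(series, ann, window_seconds=600)
        assert len(s_d) == 1

    def test_full_day_coverage_yields_144_pairs(self):
        series = samples_at(range(8640), step=10)
        windows = schedule_manual_windows(date(2010, 6, 1))
        ann = [AnnotationRecord(t, (1, 1, 1)) for t, _ in windows]
        s_d, s_n = pair_samples(series, ann, window_seconds=600)
        assert len(s_d) + len(s_n) == 144

    def test_empty_inputs_rejected(self):
        with pytest.raises(CalibrationError, match="no pairs"):
            pair_samples(ActivitySeries([]), [])


class TestFit:
    def test_exact_line_recovered_for_day(self):
        s_d = [(a, 0.01 * a + 1) for a in (0, 100, 300, 600)]
        model = fit_calibration(s_d, [])
        assert model.day_coeffs == pytest.approx((0.01, 1.0), abs=1e-12)
        assert model.rms_day == pytest.approx(0.0, abs=1e-12)

    def test_exact_quadratic_recovered_for_night(self):
        s_n = [(a, 1e-6 * a**2) for a in (0, 500, 1000, 1500, 2000)]
        model = fit_calibration([], s_n)
        assert model.night_coeffs == pytest.approx((1e-6, 0.0, 0.0), abs=1e-10)
        assert model.rms_night == pytest.approx(0.0, abs=1e-10)

    def test_noisy_fit_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 5000, 100)
        c_day = 0.001 * a + 0.5 + rng.normal(0, 0.3, 100)
        c_night = 2e-7 * a**2 + 0.2 + rng.normal(0, 0.3, 100)
        model = fit_calibration(list(zip(a, c_day)), list(zip(a, c_night)))
        beta_d, rms_d = normal_equations_fit(a, c_day, 1)
        beta_n, rms_n = normal_equations_fit(a, c_night, 2)
        assert model.day_coeffs == pytest.approx(tuple(beta_d), abs=1e-8)
        assert model.night_coeffs == pytest.approx(tuple(beta_n), abs=1e-8)
        assert model.rms_day == pytest.approx(rms_d, abs=1e-8)
        assert model.rms_night == pytest.approx(rms_n, abs=1e-8)

    def test_degenerate_design_rejected(self):
        with pytest.raises(CalibrationError, match="rank deficient"):
            fit_calibration([(5, 1), (5, 2), (5, 3)], [])

    def test_rms_never_worse_than_best_constant(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = rng.uniform(0, 1000, 30)
            c = rng.integers(0, 8, 30).astype(float)
            model = fit_calibration(list(zip(a, c)), [])
            const_rms = float(np.sqrt(np.mean((c - c.mean()) ** 2)))
            assert model.rms_day <= const_rms + 1e-12

    @pytest.mark.parametrize("n", [30, 300])
    def test_parameter_recovery_improves_with_n(self, n):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 6000, n)
        truth = (0.001, 0.5)
        c = np.polyval(truth, a) + rng.normal(0, 0.3, n)
        model = fit_calibration(list(zip(a, c)), [])
        rel = np.abs((np.array(model.day_coeffs) - truth) / truth)
        assert rel.max() < (0.25 if n == 30 else 0.05)


class TestApply:
    DAY_MODEL = CalibrationModel(day_coeffs=(0.01, 1.0), night_coeffs=None)

    def sample(self, raw, mode="day"):
        return ActivitySample(T0, raw, mode, 0.0, True)

    def test_polynomial_evaluation(self):
        assert apply_calibration(self.DAY_MODEL, self.sample(100)) == 2.0

    def test_lower_clamp(self):
        model = CalibrationModel((0.01, -0.4), None)
        assert apply_calibration(model, self.sample(0)) == 0.0

    def test_upper_clamp(self):
        model = CalibrationModel((0.01, 9.3), None)
        assert apply_calibration(model, self.sample(0)) == 7.0

    def test_unfitted_mode_rejected(self):
        with pytest.raises(CalibrationError, match="no model for mode"):
            apply_calibration(self.DAY_MODEL, self.sample(0, mode="night"))

    def test_calibrated_series_stays_in_category_range(self):
        series = samples_at(np.linspace(0, 10_000, 50))
        out = calibrate_series(self.DAY_MODEL, series)
        assert ((out >= 0) & (out <= 7)).all()

    def test_model_json_round_trip(self, tmp_path):
        model = CalibrationModel(
            (0.01, 1.0), (1e-6, 0.0, 0.2), (T0, T0 + timedelta(days=14)), 0.3, 0.4, 80, 60
        )
        model.to_json(tmp_path / "m.json")
        back = CalibrationModel.from_json(tmp_path / "m.json")
        assert back == model


class TestMedianFilter:
    def series(self, values, step=10):
        idx = pd.date_range(T0, periods=len(values), freq=f"{step}s", tz="UTC")
        return pd.Series(np.asarray(values, float), index=idx)

    def test_constant_series_unchanged(self):
        s = self.series([3.0] * 100)
        assert median_filter_series(s).equals(s)

    def test_single_spike_removed_entirely(self):
        v = np.zeros(120)
        v[60] = 7.0
        out = median_filter_series(self.series(v), window_minutes=10)
        assert (out == 0).all()

    def test_idempotent_on_step_signal(self):
        v = np.concatenate([np.zeros(90), np.ones(90) * 4])
        once = median_filter_series(self.series(v))
        twice = median_filter_series(once)
        assert np.array_equal(once.to_numpy(), twice.to_numpy())

    def test_empty_series_passes_through(self):
        s = pd.Series(dtype=float, index=pd.DatetimeIndex([], tz="UTC"))
        assert len(median_filter_series(s)) == 0


class TestPeakCounting:
    def series(self, values):
        idx = pd.date_range(T0, periods=len(values), freq="10s", tz="UTC")
        return pd.Series(np.asarray(values, float), index=idx)

    def test_two_prominent_peaks_counted(self):
        assert count_activity_peaks(self.series([0, 5, 2, 4, 0]), 1.0) == 2

    def test_shallow_wiggle_screened(self):
        assert count_activity_peaks(self.series([0, 5, 4.8, 5, 0]), 1.0) == 1

    def test_flat_curve_has_no_peaks(self):
        assert count_activity_peaks(self.series([3, 3, 3, 3]), 1.0) == 0

    def test_clamped_plateau_with_micro_dips_is_one_peak(self):
        v = [0, 7, 6.99998, 7, 7, 6.99999, 7, 3, 6.4, 0]
        assert count_activity_peaks(self.series(v), 1.0) == 2
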