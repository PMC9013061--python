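import numpy as np
import pytest
from scipy import stats

from msirecal.drift import (
    MAD_SCALE,
    MaximaCurve,
    ReferenceDiscarded,
    TrackDiagnostics,
    accept_reference,
    fit_gam_trend,
    fit_ridge_spline,
    flag_outliers,
    mad,
    trace_ridge,
)
from msirecal.kde import AxisScaler, KDEstimate, fit_fft_kde
from msirecal.references import ReferenceMatchTable


def matches_from(pixels, masses):
    t = ReferenceMatchTable(float(np.median(masses)))
    t.pixels = np.asarray(pixels, dtype=np.intp)
    t.masses = np.asarray(masses, dtype=float)
    t.intensities = np.ones(len(masses))
    return t


class _Line:
    """Stand-in spline: a fixed callable trend."""

    def __init__(self, fn):
        self.fn = fn

    def __call__(self, x):
        return self.fn(np.asarray(x, float))


class TestRidge:
    def test_denser_track_wins_every_column(self, rng):
        # track A at 400.000 with 10x the points of track B at 400.006
        x = np.tile(np.arange(100.0), 10)
        a = np.column_stack([x, np.full(x.size, 400.000) + rng.normal(0, 1e-4, x.size)])
        xb = np.arange(100.0)
        b = np.column_stack([xb, np.full(100, 400.006) + rng.normal(0, 1e-4, 100)])
        est = fit_fft_kde(np.vstack([a, b]), G=256)
        curve = trace_ridge(est)
        assert len(curve) > 0
        assert (np.abs(curve.masses - 400.000) < 0.002).all()

    def test_single_noiseless_track_within_a_cell(self):
        # with no measurement scatter the ridge tracks the line to grid
        # resolution (a straight track is unbiased under a symmetric kernel)
        x = np.arange(200.0)
        # a second faint parallel track fixes the y-range without moving the argmax
        pts = np.vstack(
            [
                np.column_stack([x, 500.0 + 4e-6 * x]),
                np.column_stack([x[::10], np.full(20, 500.002)]),
            ]
        )
        est = fit_fft_kde(pts, G=256)
        curve = trace_ridge(est)
        cell = est.y_scaler.span / 255
        truth = 500.0 + 4e-6 * curve.pixels
        assert np.median(np.abs(curve.masses - truth)) < 1.5 * cell

    def test_zero_density_columns_skipped(self):
        grid = np.zeros((64, 64))
        grid[10, 20] = 1.0
        est = KDEstimate(grid, 0.1, AxisScaler(0, 63), AxisScaler(100.0, 101.0))
        curve = trace_ridge(est)
        assert len(curve) == 1

    def test_empty_density_empty_curve(self):
        est = KDEstimate(np.zeros((32, 32)), 0.1, AxisScaler(0, 1), AxisScaler(0, 1))
        assert len(trace_ridge(est)) == 0


class TestRidgeSpline:
    def test_line_reproduced(self):
        x = np.arange(50.0)
        curve = MaximaCurve(x, 400.0 + 1e-5 * x)
        sp = fit_ridge_spline(curve, seed=0)
        np.testing.assert_allclose(sp(x), 400.0 + 1e-5 * x, atol=1e-6)

    def test_sine_recovered_below_noise(self, rng):
        x = np.arange(300.0)
        truth = 400.0 + 0.005 * np.sin(2 * np.pi * x / 300)
        noise_sd = 2e-4
        curve = MaximaCurve(x, truth + rng.normal(0, noise_sd, x.size))
        sp = fit_ridge_spline(curve, seed=0)
        rmse = np.sqrt(np.mean((sp(x) - truth) ** 2))
        assert rmse < noise_sd

    def test_too_few_maxima_discarded(self):
        with pytest.raises(ReferenceDiscarded, match="< 5"):
            fit_ridge_spline(MaximaCurve(np.arange(4.0), np.full(4, 400.0)), seed=0)


class TestOutlierRule:
    def test_mad_normal_consistency_factor(self):
        assert MAD_SCALE == pytest.approx(1.4826, abs=5e-5)
        assert MAD_SCALE == pytest.approx(1.0 / stats.norm.ppf(0.75))

    def test_rule_matches_brute_force(self, rng):
        spline = _Line(lambda x: 400.0 + 1e-5 * x)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            pixels = rng.integers(0, 100, n)
            masses = spline(pixels) + rng.normal(0, 1e-4, n) * rng.choice([1, 30], n, p=[0.9, 0.1])
            t = matches_from(pixels, masses)
            diag = flag_outliers(t, spline)
            r = np.abs(masses - spline(pixels))
            m = 1.4826 * np.median(r)
            expected_out = r >= 2 * m if m > 0 else r > np.median(r)
            np.testing.assert_array_equal(~diag.inlier, expected_out)

    def test_single_deviant_among_perfect_points(self):
        spline = _Line(lambda x: np.full_like(x, 400.0))
        masses = np.full(20, 400.0)
        masses[-1] = 401.0
        diag = flag_outliers(matches_from(np.arange(20), masses), spline)
        assert diag.mad_r == 0
        assert not diag.inlier[-1]
        assert diag.inlier[:-1].all()

    def test_all_points_on_spline(self):
        spline = _Line(lambda x: 400.0 + 1e-5 * x)
        pixels = np.arange(30)
        diag = flag_outliers(matches_from(pixels, spline(pixels)), spline)
        assert diag.inlier.all()
        assert (diag.dispersion == 0).all()


class TestAcceptance:
    @staticmethod
    def diag(n_inlier_pixels, max_disp):
        disp = np.array([max_disp / 2, max_disp])
        return TrackDiagnostics(np.zeros(1), np.ones(1, bool), 0.0, disp, n_inlier_pixels)

    def test_both_criteria_met(self):
        assert accept_reference(self.diag(76, 9.0), n_roi=100)

    def test_dispersion_over_threshold_rejected(self):
        assert not accept_reference(self.diag(76, 11.0), n_roi=100)

    def test_coverage_below_threshold_rejected(self):
        assert not accept_reference(self.diag(74, 1.0), n_roi=100)

    def test_monotone_in_dispersion(self, rng):
        # adding dispersion can never turn a reject into an accept
        for _ in range(100):
            pixels = int(rng.integers(1, 101))
            d1 = float(rng.uniform(0, 20))
            d2 = d1 + float(rng.uniform(0, 10))
            a1 = accept_reference(self.diag(pixels, d1), n_roi=100)
            a2 = accept_reference(self.diag(pixels, d2), n_roi=100)
            assert a2 <= a1

    def test_customizable_dispersion_threshold(self):
        assert accept_reference(self.diag(80, 11.0), n_roi=100, max_dispersion_ppm=15.0)


class TestGamTrend:
    def test_constant_data_recovered(self, rng):
        pixels = np.arange(400.0)
        masses = 400.0 + rng.normal(0, 2e-4, 400)
        trend = fit_gam_trend(pixels, masses, 400.0)
        se = 2e-4 / np.sqrt(400 / 21)
        assert np.abs(trend.predict(pixels) - 400.0).max() < 2 * 3 * se

    def test_sinusoidal_drift_recovered(self, rng):
        pixels = np.arange(2000.0)
        drift_ppm = 10.0 * np.sin(2 * np.pi * pixels / 2000)
        truth = 400.0 * (1 + drift_ppm * 1e-6)
        masses = truth * (1 + rng.normal(0, 1.0, 2000) * 1e-6)
        trend = fit_gam_trend(pixels, masses, 400.0)
        err_ppm = (trend.predict(pixels) - truth) / truth * 1e6
        assert np.sqrt(np.mean(err_ppm**2)) < 1.0

    def test_interpolates_without_nan_at_unseen_pixels(self, rng):
        pixels = np.arange(0.0, 500.0, 2.0)  # odd pixels unseen
        masses = 400.0 + rng.normal(0, 2e-4, pixels.size)
        trend = fit_gam_trend(pixels, masses, 400.0, domain=(0.0, 499.0))
        pred = trend.predict(np.arange(500.0))
        assert np.isfinite(pred).all()

    def test_too_few_points_discarded(self):
        with pytest.raises(ReferenceDiscarded):
            fit_gam_trend(np.arange(10.0), np.full(10, 400.0), 400.0)
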