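"""Facet length measurement, two-stage growth fits, face rates, habit."""

import numpy as np
import pytest

from crystallokin.growth_kinetics import (aspect_ratio_series, face_rates,
                                          fit_growth, measure_lengths)
from crystallokin.synthetic_data import (LengthSeries, SimGrowthConfig,
                                         growth_condition_config,
                                         render_frames,
                                         simulate_length_series)


def make_series(t, M, LA, m_cens=None, la_cens=None, px=250.0, limit=2):
    t = np.asarray(t, float)
    n = len(t)
    return LengthSeries(
        t, np.asarray(M, float), np.asarray(LA, float),
        np.zeros(n, bool) if m_cens is None else np.asarray(m_cens, bool),
        np.zeros(n, bool) if la_cens is None else np.asarray(la_cens, bool),
        px, limit)


class TestMeasureLengths:
    def test_rendered_rectangle_measured_exactly(self):
        series = make_series([0.0], [5.0], [2.0])
        frames = render_frames(series, 250.0, (32, 48), noise_sd=0.0)
        out = measure_lengths(frames, 250.0)
        assert out.M[0] == pytest.approx(5.0)
        assert out.L_A[0] == pytest.approx(2.0)
        assert not out.M_censored[0] and not out.LA_censored[0]

    def test_blank_frame_censored(self):
        out = measure_lengths(np.zeros((1, 32, 48)), 250.0)
        assert out.M_censored[0] and out.LA_censored[0]

    def test_noisy_round_trip_within_one_pixel(self):
        cfg = SimGrowthConfig(stage_rates_M=[(4000.0, 2.0)],
                              stage_rates_LA=[(4000.0, 1.0)],
                              frame_interval=200.0, length_noise_sd=0.0,
                              quantize=False, seed=0)
        series, _ = simulate_length_series(cfg)
        frames = render_frames(series, 250.0, (64, 96), noise_sd=0.08,
                               seed=1)
        out = measure_lengths(frames, 250.0)
        ok = ~out.M_censored
        err_M = np.abs(out.M[ok] - series.M[ok])
        err_LA = np.abs(out.L_A[ok] - series.L_A[ok])
        within = (err_M <= 0.250) & (err_LA <= 0.250)
        assert within.mean() >= 0.95

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            measure_lengths(np.zeros((0, 8, 8)), 250.0)


class TestFitGrowth:
    def test_single_slope_noise_free_exact(self):
        t = np.arange(0, 4000.0, 100.0)
        series = make_series(t, 1.0 + 0.002 * t, 0.6 + 0.001 * t)
        fit = fit_growth(series)
        assert fit.fit_M.n_breakpoints == 0
        assert fit.slopes_nm_per_s("M") == pytest.approx([2.0], rel=1e-9)
        assert fit.slopes_nm_per_s("LA") == pytest.approx([1.0], rel=1e-9)
        assert not fit.M_flagged.any() and not fit.LA_flagged.any()

    def test_two_stage_quantized_recovery_within_ten_percent(self):
        cfg = SimGrowthConfig(stage_rates_M=[(5400.0, 0.5), (9000.0, 1.1)],
                              stage_rates_LA=[(5400.0, 0.5), (9000.0, 1.1)],
                              seed=3)
        series, _ = simulate_length_series(cfg)
        fit = fit_growth(series)
        assert fit.fit_M.n_breakpoints == 1
        assert fit.slopes_nm_per_s("M") == pytest.approx([0.5, 1.1], rel=0.1)

    def test_breakpoint_count_bounded_by_max_stages(self):
        series, _ = simulate_length_series(SimGrowthConfig(seed=8))
        for max_stages in (1, 2):
            fit = fit_growth(series, max_stages=max_stages)
            assert fit.fit_M.n_breakpoints <= max_stages - 1
            assert fit.fit_LA.n_breakpoints <= max_stages - 1

    def test_all_censored_rejected(self):
        t = np.arange(0.0, 300.0, 60.0)
        series = make_series(t, np.full(5, 0.25), np.full(5, 0.25),
                             m_cens=np.ones(5, bool),
                             la_cens=np.ones(5, bool))
        with pytest.raises(ValueError):
            fit_growth(series)

    @pytest.mark.parametrize("slope_nm_s", [0.3, 0.7, 1.3, 2.3])
    def test_zero_noise_quantization_slope_error_bound(self, slope_nm_s):
        """Pure pixel quantization biases the slope by < pixel / time-span."""
        cfg = SimGrowthConfig(stage_rates_M=[(9000.0, slope_nm_s)],
                              stage_rates_LA=[(9000.0, slope_nm_s)],
                              length_noise_sd=0.0, seed=0)
        series, _ = simulate_length_series(cfg)
        fit = fit_growth(series, max_stages=1)
        keep = ~series.M_censored
        span = np.ptp(series.time[keep])
        bound = cfg.pixel_size / span
        err = abs(fit.slopes_nm_per_s("M")[0] - slope_nm_s)
        assert err <= bound


class TestFaceRates:
    def test_half_factor_arithmetic(self):
        t = np.arange(0, 3000.0, 60.0)
        series = make_series(t, 0.0046 * t + 1.0, 0.0012 * t + 0.8)
        rates = face_rates(fit_growth(series))
        assert rates.G_101 == pytest.approx([2.3], rel=1e-9)
        assert rates.G_110 == pytest.approx([0.6], rel=1e-9)

    def test_identity_factor_and_linearity(self):
        t = np.arange(0, 3000.0, 60.0)
        series = make_series(t, 0.002 * t, 0.001 * t + 0.2)
        fit = fit_growth(series)
        r1 = face_rates(fit, 1.0, 1.0)
        assert r1.G_101 == pytest.approx(fit.slopes_nm_per_s("M"), rel=1e-12)
        r3 = face_rates(fit, 1.5, 0.75)
        assert r3.G_110 == pytest.approx(1.5 * r1.G_110, rel=1e-12)
        assert r3.G_101 == pytest.approx(0.75 * r1.G_101, rel=1e-12)

    def test_negative_factor_rejected(self):
        t = np.arange(0, 3000.0, 60.0)
        fit = fit_growth(make_series(t, 0.002 * t, 0.001 * t + 0.2))
        with pytest.raises(ValueError):
            face_rates(fit, -0.5, 0.5)

    def test_condition_preset_recovery_shares_convention(self):
        """Rates seeded as face rates come back as the same face rates."""
        cfg = growth_condition_config("positive_high", seed=12)
        series, _ = simulate_length_series(cfg)
        rates = face_rates(fit_growth(series))
        assert rates.G_101[-1] == pytest.approx(2.3, rel=0.1)
        assert rates.G_110[-1] == pytest.approx(1.1, rel=0.1)


class TestAspectRatio:
    def test_two_to_one_pixel_start(self):
        series = make_series([0.0], [0.5], [0.25], limit=1)
        out = aspect_ratio_series(series)
        assert out.aspect_ratio[0] == pytest.approx(2.0)

    def test_equal_dimensions_unity(self):
        series = make_series([0.0, 1.0], [1.0, 2.0], [1.0, 2.0])
        assert aspect_ratio_series(series).aspect_ratio == pytest.approx(
            [1.0, 1.0])

    def test_censored_points_skipped(self):
        series = make_series([0.0, 1.0, 2.0], [1.0, 2.0, 3.0],
                             [0.25, 1.0, 1.5],
                             la_cens=[True, False, False])
        out = aspect_ratio_series(series)
        assert len(out.time) == 2 and out.time[0] == 1.0

    def test_equal_late_slopes_ratio_converges(self):
        """When late slopes match, M/L_A tends to 1 plus an O(1/t) offset."""
        cfg = SimGrowthConfig(stage_rates_M=[(2000.0, 0.5), (30000.0, 2.0)],
                              stage_rates_LA=[(2000.0, 1.0), (30000.0, 2.0)],
                              length_noise_sd=0.0, seed=0)
        series, _ = simulate_length_series(cfg)
        ratio = aspect_ratio_series(series).aspect_ratio
        # closed form: ratio -> 1 as the common-slope term dominates
        assert abs(ratio[-1] - 1.0) < 0.05
        assert abs(ratio[-1] - 1.0) < abs(ratio[len(ratio) // 2] - 1.0)

    def test_zero_width_rejected(self):
        series = make_series([0.0], [1.0], [0.0])
        with pytest.raises(ValueError):
            aspect_ratio_series(series)
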