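"""Seeded simulators: determinism, stage templates, censoring, rendering."""

from dataclasses import replace

import numpy as np
import pytest

from crystallokin.synthetic_data import (SimGrowthConfig, SimTraceConfig,
                                         render_frames,
                                         simulate_current_trace,
                                         simulate_length_series,
                                         trace_template)
from crystallokin.trace_signal import moving_std


class TestTraceSimulator:
    def test_seed_determinism(self):
        cfg = SimTraceConfig(seed=123,
                             oscillation=replace(SimTraceConfig().oscillation,
                                                 enabled=True))
        a, _ = simulate_current_trace(cfg)
        b, _ = simulate_current_trace(cfg)
        assert np.array_equal(a.current, b.current)
        assert np.array_equal(a.time, b.time)
        c, _ = simulate_current_trace(replace(cfg, seed=124))
        assert not np.array_equal(a.current, c.current)

    def test_zero_noise_equals_template(self):
        cfg = SimTraceConfig(preN_noise_sd=0.0, postN_noise_sd=0.0, seed=9)
        trace, _ = simulate_current_trace(cfg)
        assert np.array_equal(trace.current, trace_template(cfg, trace.time))

    def test_domain_drop_tens_of_na_within_a_minute(self):
        """The current decreases by >= 10 nA within 60 s of time zero."""
        cfg = SimTraceConfig(domain_drop=30.0, domain_drop_duration=60.0,
                             seed=1)
        trace, _ = simulate_current_trace(cfg)
        first_min = (trace.time >= 0) & (trace.time <= 60.0)
        cur = trace.current[first_min]
        assert cur[0] - cur[-1] >= 10.0

    def test_time_zero_is_potential_switch(self, default_trace):
        trace, _ = default_trace
        pre = trace.time < 0
        assert np.all(trace.potential[pre] < 0)
        assert np.all(trace.potential[~pre] > 0)
        assert trace.time[np.argmax(trace.potential > 0)] == 0.0

    def test_invalid_configs_raise(self):
        with pytest.raises(ValueError):
            SimTraceConfig(sampling_rate=0)
        with pytest.raises(ValueError):
            SimTraceConfig(t_S=3000.0, t_E=2500.0)

    def test_post_nucleation_noise_drops_over_seeds(self):
        """mean MSTD(post-N) < mean MSTD(pre-N) on every default-config seed."""
        lower = 0
        n_seeds = 20
        for seed in range(n_seeds):
            trace, truth = simulate_current_trace(SimTraceConfig(seed=seed))
            t_S, t_E = truth.params["t_S"], truth.params["t_E"]
            m = moving_std(trace.current, 50)
            tm = trace.time[49:]
            pre = (tm > truth.params["stage_bounds"]["preN"][0] + 10) \
                & (tm < t_S)
            post = tm > t_E
            if m[post].mean() < m[pre].mean():
                lower += 1
        assert lower == n_seeds


class TestLengthSimulator:
    def test_unquantized_noise_free_is_exact_line(self):
        cfg = SimGrowthConfig(stage_rates_M=[(1000.0, 1.0)],
                              stage_rates_LA=[(1000.0, 1.0)],
                              frame_interval=10.0, length_noise_sd=0.0,
                              quantize=False, seed=0)
        series, _ = simulate_length_series(cfg)
        assert np.allclose(series.M * 1000.0, series.time)

    def test_below_two_pixels_is_censored(self):
        """A true length of 400 nm at 250 nm/px, limit 2 px, is censored."""
        cfg = SimGrowthConfig(stage_rates_M=[(400.0, 1.0)],
                              stage_rates_LA=[(400.0, 1.0)],
                              frame_interval=400.0, length_noise_sd=0.0,
                              seed=0)
        series, _ = simulate_length_series(cfg)
        i = np.argmin(np.abs(series.time - 400.0))
        assert series.M[i] < 0.5
        assert series.M_censored[i]

    def test_two_stage_truth_slope_change(self):
        cfg = SimGrowthConfig(stage_rates_M=[(1000.0, 0.5), (1000.0, 1.1)],
                              stage_rates_LA=[(2000.0, 0.5)],
                              frame_interval=50.0, length_noise_sd=0.0,
                              quantize=False, seed=0)
        series, truth = simulate_length_series(cfg)
        assert truth.params["breakpoints_M"] == [1000.0]
        early = series.time <= 1000
        late = series.time >= 1000
        s1 = np.polyfit(series.time[early], series.M[early] * 1000, 1)[0]
        s2 = np.polyfit(series.time[late], series.M[late] * 1000, 1)[0]
        assert s1 == pytest.approx(0.5, rel=1e-9)
        assert s2 == pytest.approx(1.1, rel=1e-9)

    def test_monotone_censoring_zero_noise(self):
        cfg = SimGrowthConfig(length_noise_sd=0.0, seed=0)
        series, _ = simulate_length_series(cfg)
        for flags in (series.M_censored, series.LA_censored):
            # once measurable, never censored again
            assert np.all(np.diff(flags.astype(int)) <= 0)

    def test_seed_determinism(self):
        a, _ = simulate_length_series(SimGrowthConfig(seed=5))
        b, _ = simulate_length_series(SimGrowthConfig(seed=5))
        assert np.array_equal(a.M, b.M) and np.array_equal(a.L_A, b.L_A)

    def test_empty_stage_list_rejected(self):
        with pytest.raises(ValueError):
            SimGrowthConfig(stage_rates_M=[])


class TestRenderFrames:
    def _series(self, M_um, LA_um):
        from crystallokin.synthetic_data import LengthSeries
        n = len(M_um)
        return LengthSeries(np.arange(n, dtype=float), np.asarray(M_um),
                            np.asarray(LA_um), np.zeros(n, bool),
                            np.zeros(n, bool), 250.0, 2)

    def test_silhouette_bounding_box_arithmetic(self):
        """5 x 2 um at 250 nm/px renders as a 20 x 8 px rectangle."""
        frames = render_frames(self._series([5.0], [2.0]), 250.0, (32, 48),
                               noise_sd=0.0)
        mask = frames[0] > 0.5
        rows = np.any(mask, axis=1).sum()
        cols = np.any(mask, axis=0).sum()
        assert (cols, rows) == (20, 8)

    def test_zero_size_crystal_blank_frame(self):
        frames = render_frames(self._series([0.0], [0.0]), 250.0, (32, 48),
                               noise_sd=0.0)
        assert np.all(frames == 0.0)

    def test_oversized_crystal_raises(self):
        with pytest.raises(ValueError):
            render_frames(self._series([50.0], [2.0]), 250.0, (32, 48),
                          noise_sd=0.0)

    def test_seeded_noise_determinism(self):
        s = self._series([5.0, 6.0], [2.0, 2.5])
        a = render_frames(s, 250.0, (32, 48), noise_sd=0.05, seed=3)
        b = render_frames(s, 250.0, (32, 48), noise_sd=0.05, seed=3)
        assert np.array_equal(a, b)
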