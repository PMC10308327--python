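"""Seeded simulators for nanopipette crystallization experiments.

Every downstream stage of the package is testable without instrument data:
these generators produce current traces, facet length series and rendered
brightfield-like frames from known ground truth.

The current-trace template follows the phenomenology of a single-nanopipette
crystallization run: a pre-conditioning baseline at negative bias (typically
-0.1 V), a sharp tens-of-nA current drop over about a minute after the
positive potential switch (dense liquid-domain formation), a noisy drifting
pre-nucleation plateau with optional oscillation bursts, a ramped amplitude
step plus a noise-level reduction between t_S and t_E (nucleation), and a
drifting post-nucleation baseline.  Time zero is the instant the positive
voltage is applied.

Length series are continuous piecewise-linear in truth (two-stage facet
growth), quantized to the optical pixel size (250 nm by default) and censored
below the optical limit of two pixels.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .trace_signal import CurrentTrace

__all__ = [
    "OscillationConfig", "EdlSpikeConfig", "SimTraceConfig", "SimGrowthConfig",
    "TruthRecord", "LengthSeries", "simulate_current_trace",
    "simulate_length_series", "render_frames", "growth_condition_config",
    "GROWTH_CONDITIONS",
]


@dataclass
class OscillationConfig:
    """Pre-nucleation current oscillation bursts (windowed sinusoids)."""

    enabled: bool = False
    amplitude: float = 0.8      # nA
    burst_rate: float = 1 / 300  # bursts per second (Poisson)
    burst_length: float = 10.0   # s
    frequency: float = 0.5       # Hz


@dataclass
class EdlSpikeConfig:
    """Exponential-decay current spike at each potential switch (EDL charging)."""

    enabled: bool = False
    amplitude: float = 5.0       # nA
    time_constant: float = 2.0   # s


@dataclass
class SimTraceConfig:
    """Ground-truth parameters of a simulated crystallization current trace.

    Defaults reproduce the reference small-pipette (40 nm) run: 10 samples/s
    at +1.0 V, nucleation transition between t_S = 2809.8 s (46.83 min) and
    t_E = 3436.2 s (57.27 min), and a noise level that drops from the pre-N
    to the post-N baseline.
    """

    sampling_rate: float = 10.0          # samples/s
    precondition_duration: float = 120.0  # s at negative bias
    precondition_current: float = -5.0    # nA
    precondition_potential: float = -0.1  # V
    run_potential: float = 1.0            # V after time zero
    domain_drop: float = 30.0             # nA, magnitude of the sharp drop
    domain_drop_duration: float = 60.0    # s
    domain_decay_slope: float = -0.004    # nA/s, gradual pre-N drift
    preN_current: float = 50.0            # nA, plateau level at domain end
    preN_noise_sd: float = 0.4            # nA
    postN_noise_sd: float = 0.12          # nA
    t_S: float = 2809.8                   # s, nucleation start breakpoint
    t_E: float = 3436.2                   # s, nucleation end breakpoint
    nucleation_step: float = 10.0         # nA, amplitude decrease t_S -> t_E
    postN_drift_slope: float = -0.002     # nA/s
    postN_duration: float = 600.0         # s recorded after t_E
    oscillation: OscillationConfig = field(default_factory=OscillationConfig)
    edl_spike: EdlSpikeConfig = field(default_factory=EdlSpikeConfig)
    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.t_E > self.t_S:
            raise ValueError("t_E must exceed t_S")
        if self.t_S <= self.domain_drop_duration:
            raise ValueError("t_S must fall after the domain drop")
        for name in ("precondition_duration", "domain_drop_duration",
                     "postN_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def preN_duration(self) -> float:
        """Duration of the pre-nucleation plateau (domain end to t_S)."""
        return self.t_S - self.domain_drop_duration

    @property
    def total_duration(self) -> float:
        return self.t_E + self.postN_duration


@dataclass
class SimGrowthConfig:
    """Ground truth for a piecewise-linear facet length series.

    ``stage_rates_M`` / ``stage_rates_LA`` are (duration s, slope nm/s)
    stages of the dimension elongation (M: long axis; L_A: width).  Reported
    lengths are quantized to ``pixel_size`` and censored while below
    ``detection_limit`` pixels, matching the optical resolution limit.
    """

    stage_rates_M: list = field(
        default_factory=lambda: [(5400.0, 0.6), (9000.0, 4.4)])
    stage_rates_LA: list = field(
        default_factory=lambda: [(5400.0, 1.2), (9000.0, 3.0)])
    onset_delay: float = 0.0        # s after nucleation end before growth
    frame_interval: float = 60.0    # s
    pixel_size: float = 250.0       # nm per pixel
    detection_limit: int = 2        # pixels
    length_noise_sd: float = 60.0   # nm, pre-quantization measurement jitter
    quantize: bool = True           # snap observed lengths to the pixel grid
    seed: int = 0

    def __post_init__(self):
        for name, stages in (("stage_rates_M", self.stage_rates_M),
                             ("stage_rates_LA", self.stage_rates_LA)):
            if not stages:
                raise ValueError(f"{name} must contain at least one stage")
            for dur, slope in stages:
                if dur <= 0 or slope < 0:
                    raise ValueError(
                        f"{name}: durations must be > 0 and slopes >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.detection_limit < 1:
            raise ValueError("detection_limit must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")


@dataclass
class TruthRecord:
    """Everything seeded into a simulation, for recovery scoring."""

    kind: str
    params: dict

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({"kind": self.kind, "params": self.params}, fh,
                      indent=2, default=float)


@dataclass
class LengthSeries:
    """Per-frame facet lengths with censoring and pixel metadata.

    Lengths are in micrometres; censored entries hold the (unmeasurable)
    quantized value but must be excluded from kinetic fits.
    """

    time: np.ndarray         # s
    M: np.ndarray            # um, long axis
    L_A: np.ndarray          # um, width
    M_censored: np.ndarray   # bool
    LA_censored: np.ndarray  # bool
    pixel_size: float        # nm
    detection_limit: int     # pixels

    def __len__(self):
        return len(self.time)


def trace_template(config: SimTraceConfig, t: np.ndarray) -> np.ndarray:
    """Deterministic piecewise stage template of the current (nA) at times t."""
    c = config
    drop_end = c.domain_drop_duration
    level_S = c.preN_current + c.domain_decay_slope * (c.t_S - drop_end)
    level_E = level_S + c.domain_decay_slope * (c.t_E - c.t_S) \
        - c.nucleation_step
    knots_t = [0.0, drop_end, c.t_S, c.t_E]
    knots_y = [c.preN_current + c.domain_drop, c.preN_current, level_S,
               level_E]
    y = np.empty_like(t)
    pre = t < 0
    y[pre] = c.precondition_current
    post = ~pre
    tp = t[post]
    yy = np.interp(tp, knots_t, knots_y)
    after = tp > c.t_E
    yy[after] = level_E + c.postN_drift_slope * (tp[after] - c.t_E)
    y[post] = yy
    return y


def _noise_sd_profile(config: SimTraceConfig, t: np.ndarray) -> np.ndarray:
    c = config
    sd = np.interp(t, [c.t_S, c.t_E], [c.preN_noise_sd, c.postN_noise_sd])
    sd[t < 0] = c.postN_noise_sd
    return sd


def simulate_current_trace(config: SimTraceConfig
                           ) -> tuple[CurrentTrace, TruthRecord]:
    """Simulate a crystallization current trace with known ground truth.

    Identical config and seed give byte-identical traces.  With all noise
    standard deviations zero and oscillations disabled the trace equals
    ``trace_template`` exactly.
    """
    c = config
    fs = c.sampling_rate
    n_pre = int(round(c.precondition_duration * fs))
    n_post = int(round(c.total_duration * fs)) + 1
    t = np.arange(-n_pre, n_post) / fs
    y = trace_template(c, t)
    potential = np.where(t < 0, c.precondition_potential, c.run_potential)

    rng = np.random.default_rng(c.seed)
    sd = _noise_sd_profile(c, t)
    y = y + rng.standard_normal(len(t)) * sd

    if c.oscillation.enabled and c.oscillation.amplitude > 0:
        o = c.oscillation
        pre_n_window = (0.0, c.t_S)
        expected = max(o.burst_rate * (pre_n_window[1] - pre_n_window[0]), 0)
        n_bursts = rng.poisson(expected)
        for _ in range(n_bursts):
            t0 = rng.uniform(*pre_n_window)
            phase = rng.uniform(0, 2 * np.pi)
            m = (t >= t0) & (t < t0 + o.burst_length)
            tau = t[m] - t0
            window = np.sin(np.pi * tau / o.burst_length) ** 2  # Hann
            y[m] += o.amplitude * window * np.sin(
                2 * np.pi * o.frequency * tau + phase)

    if c.edl_spike.enabled and c.edl_spike.amplitude > 0:
        e = c.edl_spike
        m = t >= 0
        y[m] += e.amplitude * np.exp(-t[m] / e.time_constant)

    trace = CurrentTrace(t, y, potential, fs)
    truth = TruthRecord("current_trace", {
        "t_S": c.t_S, "t_E": c.t_E,
        "V_N": 1.0 / (c.t_E - c.t_S),
        "preN_noise_sd": c.preN_noise_sd,
        "postN_noise_sd": c.postN_noise_sd,
        "nucleation_step": c.nucleation_step,
        "domain_drop": c.domain_drop,
        "stage_bounds": {
            "precondition": (-c.precondition_duration, 0.0),
            "domain": (0.0, c.domain_drop_duration),
            "preN": (c.domain_drop_duration, c.t_S),
            "nucleation": (c.t_S, c.t_E),
            "postN": (c.t_E, c.total_duration),
        },
        "slopes": {
            "preN": c.domain_decay_slope,
            "nucleation": c.domain_decay_slope
            - c.nucleation_step / (c.t_E - c.t_S),
            "postN": c.postN_drift_slope,
        },
        "config": asdict(c),
    })
    return trace, truth


def _piecewise_length(t: np.ndarray, stages, onset: float) -> np.ndarray:
    """True length (nm) at times t for growth stages starting at ``onset``."""
    length = np.zeros_like(t, dtype=float)
    t0 = onset
    base = 0.0
    for dur, slope in stages:
        m = t >= t0
        length[m] = base + slope * np.minimum(t[m] - t0, dur)
        base += slope * dur
        t0 += dur
    return length


def simulate_length_series(config: SimGrowthConfig
                           ) -> tuple[LengthSeries, TruthRecord]:
    """Simulate a quantized, censored facet length series.

    Truth is continuous piecewise-linear per dimension; reported values add
    Gaussian measurement jitter, snap to the pixel grid and are flagged
    censored while below ``detection_limit`` pixels.
    """
    c = config
    total = c.onset_delay + max(sum(d for d, _ in c.stage_rates_M),
                                sum(d for d, _ in c.stage_rates_LA))
    n = int(np.floor(total / c.frame_interval)) + 1
    t = np.arange(n) * c.frame_interval
    true_M = _piecewise_length(t, c.stage_rates_M, c.onset_delay)
    true_LA = _piecewise_length(t, c.stage_rates_LA, c.onset_delay)
    rng = np.random.default_rng(c.seed)
    px = c.pixel_size

    def observe(true_nm, jitter):
        noisy = np.maximum(true_nm + jitter, 0.0)
        if c.quantize:
            # a crystal spans floor(L/px) whole pixels; it is measurable
            # only once it reaches detection_limit pixels
            obs = np.floor(noisy / px) * px
        else:
            obs = noisy
        censored = obs < c.detection_limit * px
        return obs, censored

    M_q, M_cens = observe(true_M, rng.standard_normal(n) * c.length_noise_sd)
    LA_q, LA_cens = observe(true_LA, rng.standard_normal(n) * c.length_noise_sd)

    series = LengthSeries(t, M_q / 1000.0, LA_q / 1000.0, M_cens, LA_cens,
                          px, c.detection_limit)
    bk_M = np.cumsum([d for d, _ in c.stage_rates_M[:-1]]) + c.onset_delay
    bk_LA = np.cumsum([d for d, _ in c.stage_rates_LA[:-1]]) + c.onset_delay
    truth = TruthRecord("length_series", {
        "slopes_M": [s for _, s in c.stage_rates_M],
        "slopes_LA": [s for _, s in c.stage_rates_LA],
        "breakpoints_M": list(map(float, bk_M)),
        "breakpoints_LA": list(map(float, bk_LA)),
        "onset_delay": c.onset_delay,
        "pixel_size": px,
        "detection_limit": c.detection_limit,
        "config": {**asdict(c)},
    })
    return series, truth


def render_frames(series: LengthSeries, pixel_size: float | None = None,
                  image_shape: tuple[int, int] = (64, 96),
                  noise_sd: float = 0.05,
                  seed: int = 0) -> np.ndarray:
    """Render each time point as one axis-aligned rectangular silhouette.

    The crystal appears as an intensity-1 rectangle of M x L_A (M along the
    image x axis) centred in a noisy zero-background frame; a zero-size
    crystal gives a blank frame.  Returns an (n_frames, H, W) float array.
    """
    px = pixel_size if pixel_size is not None else series.pixel_size
    h, w = image_shape
    rng = np.random.default_rng(seed)
    frames = np.zeros((len(series), h, w), dtype=float)
    for i in range(len(series)):
        m_px = int(round(series.M[i] * 1000.0 / px))
        la_px = int(round(series.L_A[i] * 1000.0 / px))
        if m_px > w or la_px > h:
            raise ValueError(f"frame {i}: crystal larger than frame")
        if m_px > 0 and la_px > 0:
            r0 = (h - la_px) // 2
            c0 = (w - m_px) // 2
            frames[i, r0:r0 + la_px, c0:c0 + m_px] = 1.0
    if noise_sd > 0:
        frames += rng.standard_normal(frames.shape) * noise_sd
    return frames


#: Printed two-stage face growth rates (nm/s) for the three bias conditions,
#: as (110)/(101) *face* rates; dimension slopes are rate / geometry_factor.
GROWTH_CONDITIONS = {
    # high positive bias (~+1.0 V, ca. +12 nA)
    "positive_high": {"G_101": [2.3], "G_110": [0.6, 1.1]},
    # low positive bias (~+0.2 V, ca. +2 nA)
    "positive_low": {"G_101": [1.5], "G_110": [0.5, 1.1]},
    # negative bias (~-0.5 V, ca. -60 nA): early (101) growth suppressed
    "negative": {"G_101": [0.3, 2.2], "G_110": [0.6, 1.5]},
}

_STAGE_DURATIONS = (5400.0, 9000.0)  # s: early stage, late stage


def growth_condition_config(condition: str, geometry_factor: float = 0.5,
                            seed: int = 0, **overrides) -> SimGrowthConfig:
    """Length-series config whose truth encodes a bias condition's face rates.

    The simulator and the estimator share the geometry convention: a face
    advancing at G nm/s elongates its dimension at G / geometry_factor nm/s
    (default factor 0.5, i.e. the face advances from the centre at half the
    dimension's elongation rate).
    """
    rates = GROWTH_CONDITIONS[condition]

    def stages(face_rates):
        k = len(face_rates)
        if k == 1:
            durs = [sum(_STAGE_DURATIONS)]
        else:
            durs = list(_STAGE_DURATIONS[:k])
        return [(d, g / geometry_factor) for d, g in zip(durs, face_rates)]

    cfg = SimGrowthConfig(stage_rates_M=stages(rates["G_101"]),
                          stage_rates_LA=stages(rates["G_110"]),
                          seed=seed)
    return replace(cfg, **overrides) if overrides else cfg
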