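"""Nucleation detection from nanopipette current traces.

A single protein nucleation event at the nanotip leaves two electroanalytical
signatures in the ionic current: (i) an abrupt, large amplitude decrease
between a start time t_S and an end time t_E, superimposed on the slowly
drifting pre-nucleation (pre-N) baseline, and (ii) a concurrent reduction of
the current noise level, tracked as a moving standard deviation (MSTD).  Both
channels are quantified with the same continuous piecewise-linear regression:
the first breakpoint leaving the pre-N baseline is t_S, the breakpoint joining
the post-N baseline is t_E, and the nucleation rate is the reciprocal interval
V_N = 1/(t_E - t_S) in events per second.

The noise channel corroborates the amplitude channel when their [t_S, t_E]
intervals overlap; with larger pipettes the noise reduction is often absent
and the amplitude channel alone carries the detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .piecewise import PiecewiseFit, fit_piecewise_linear, select_breakpoints

__all__ = [
    "CurrentTrace", "NoiseTrack", "NucleationEvent", "StageSegmentation",
    "moving_std", "smooth", "segment_stages", "detect_nucleation",
    "nucleation_rate", "fit_piecewise_linear", "select_breakpoints",
    "PiecewiseFit",
]

#: pre-N / post-N baselines should each span at least this long (seconds)
#: to be considered well established.
MIN_BASELINE_S = 480.0


@dataclass
class CurrentTrace:
    """Uniformly sampled ionic current with its applied-potential program."""

    time: np.ndarray        # s; strictly increasing uniform grid
    current: np.ndarray     # nA
    potential: np.ndarray   # V
    sampling_rate: float    # samples/s

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        self.potential = np.asarray(self.potential, dtype=float)
        if not (len(self.time) == len(self.current) == len(self.potential)):
            raise ValueError("time, current and potential must align")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        nominal = 1.0 / self.sampling_rate
        if np.any(dt > 2.0 * nominal):
            warnings.warn("sampling gaps exceed 2x the nominal interval",
                          stacklevel=2)

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class NoiseTrack:
    """Moving standard deviation of the current (the noise-level channel).

    Trailing window: the value at ``time[i]`` is the sample sd of the
    ``window_points`` samples ending there, so the track is causal and a
    noise-channel t_S can never precede the data that produced it.
    """

    time: np.ndarray
    mstd: np.ndarray
    window_points: int


@dataclass
class NucleationEvent:
    t_S: float              # s
    t_E: float              # s
    V_N: float              # events/s
    channel: str            # "amplitude" | "noise"
    corroborated: bool
    p_values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        if not self.t_E > self.t_S:
            raise ValueError("t_E must exceed t_S")


@dataclass
class StageSegmentation:
    """Ordered, non-overlapping labeled intervals covering the trace."""

    labels: list            # subset of precondition/domain/preN/nucleation/postN
    starts: np.ndarray      # s
    ends: np.ndarray        # s

    def interval(self, label: str):
        i = self.labels.index(label)
        return self.starts[i], self.ends[i]


def moving_std(values, window_points: int, ddof: int = 1) -> np.ndarray:
    """Trailing sliding-window sample standard deviation.

    Returns ``len(values) - window_points + 1`` values (windows that fit
    entirely).  Uses the n-1 denominator by default.
    """
    values = np.asarray(values, dtype=float)
    w = int(window_points)
    if w < 2:
        raise ValueError("window_points must be >= 2")
    if w > len(values):
        raise ValueError("window_points exceeds series length")
    windows = np.lib.stride_tricks.sliding_window_view(values, w)
    return windows.std(axis=-1, ddof=ddof)


def noise_track(trace: CurrentTrace, window_points: int = 50) -> NoiseTrack:
    """MSTD of a trace; timestamps anchored at the window end (causal)."""
    m = moving_std(trace.current, window_points)
    return NoiseTrack(trace.time[window_points - 1:], m, int(window_points))


def smooth(series, window_points: int = 1) -> np.ndarray:
    """Centred moving average; window must be odd, window 1 is the identity.

    Edges use the partial symmetric window, so interior points of affine
    data are reproduced exactly and length is preserved.
    """
    w = int(window_points)
    if w < 1 or w % 2 == 0:
        raise ValueError("window_points must be odd and >= 1")
    series = np.asarray(series, dtype=float)
    if w == 1:
        return series.copy()
    half = w // 2
    csum = np.cumsum(np.concatenate([[0.0], series]))
    n = len(series)
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)


def nucleation_rate(t_S: float, t_E: float) -> float:
    """Nucleation rate V_N = 1/(t_E - t_S), in events per second.

    t_S and t_E are the start/end breakpoints of the nucleation transition
    in seconds.
    """
    if not t_E > t_S:
        raise ValueError("t_E must exceed t_S")
    return 1.0 / (t_E - t_S)


def _domain_end_index(trace: CurrentTrace, i0: int,
                      slope_frac: float = 0.08) -> int:
    """Index (into trace) where the sharp domain-formation drop levels off.

    The dense liquid domain forming at the nanotip partially blocks ion
    transport, so the current falls by tens of nA within about a minute of
    the potential switch, then relaxes to a gradual pre-N drift.  The domain
    period is taken as the initial interval whose smoothed slope stays below
    ``slope_frac`` of the steepest (most negative) slope.
    """
    cur = trace.current[i0:]
    t = trace.time[i0:]
    fs = trace.sampling_rate
    span = max(int(round(5 * fs)), 3)
    span += (span + 1) % 2
    sm = smooth(cur, span)
    step = max(int(round(2 * fs)), 1)
    d = (sm[step:] - sm[:-step]) / (t[step:] - t[:-step])
    steepest = float(d.min()) if len(d) else 0.0
    if steepest >= -1e-12:
        return i0  # no resolvable drop
    thresh = slope_frac * steepest  # negative
    peak = int(np.argmin(d))
    after = np.nonzero(d[peak:] > thresh)[0]
    if len(after) == 0:
        return i0 + len(cur) - 1
    return i0 + peak + int(after[0])


def segment_stages(trace: CurrentTrace, window_points: int = 50,
                   alpha: float = 1e-4,
                   min_segment_points: int | None = None) -> StageSegmentation:
    """Label the trace as precondition / domain / preN / nucleation / postN.

    The precondition period is everything before time zero (the positive
    potential switch); the domain period is the initial steep current drop;
    the remainder is segmented by breakpoint regression of the amplitude.
    """
    pos = np.nonzero(trace.time >= 0)[0]
    if len(pos) == 0:
        if np.all(trace.potential <= 0):
            return StageSegmentation(["precondition"],
                                     np.array([trace.time[0]]),
                                     np.array([trace.time[-1]]))
        raise ValueError("trace has no samples at or after time zero")
    i0 = int(pos[0])
    labels, starts, ends = [], [], []
    if i0 > 0:
        labels.append("precondition")
        starts.append(trace.time[0])
        ends.append(trace.time[i0])
    i_dom = _domain_end_index(trace, i0)
    if i_dom > i0:
        labels.append("domain")
        starts.append(trace.time[i0])
        ends.append(trace.time[i_dom])
    msp = min_segment_points if min_segment_points is not None \
        else 2 * window_points
    t = trace.time[i_dom:]
    y = trace.current[i_dom:]
    fit = select_breakpoints(t, y, max_breakpoints=2,
                             min_segment_points=msp, alpha=alpha)
    cuts = [t[0], *fit.breakpoint_times, t[-1]]
    stage_names = {1: ["preN"], 2: ["preN", "nucleation"],
                   3: ["preN", "nucleation", "postN"]}[len(cuts) - 1]
    for name, lo, hi in zip(stage_names, cuts[:-1], cuts[1:]):
        labels.append(name)
        starts.append(lo)
        ends.append(hi)
    return StageSegmentation(labels, np.asarray(starts), np.asarray(ends))


def _channel_event(t, y, channel: str, msp: int,
                   alpha: float) -> tuple[NucleationEvent | None, PiecewiseFit]:
    fit = select_breakpoints(t, y, max_breakpoints=2,
                             min_segment_points=msp, alpha=alpha)
    if fit.n_breakpoints != 2:
        return None, fit
    t_S, t_E = float(fit.breakpoint_times[0]), float(fit.breakpoint_times[1])
    ev = NucleationEvent(t_S, t_E, nucleation_rate(t_S, t_E), channel,
                         corroborated=False,
                         p_values=fit.breakpoint_p_values.copy())
    return ev, fit


def detect_nucleation(trace: CurrentTrace, window_points: int = 50,
                      alpha: float = 1e-4,
                      min_segment_points: int | None = None
                      ) -> list[NucleationEvent]:
    """Dual-signature nucleation detection.

    Runs breakpoint selection independently on the current amplitude and on
    its MSTD noise track over the post-domain portion of the trace.  Each
    channel that resolves two significant breakpoints yields a
    ``NucleationEvent`` with V_N = 1/(t_E - t_S); events are marked
    corroborated when the two channels' intervals overlap.  An empty list
    signals "no nucleation".
    """
    msp = min_segment_points if min_segment_points is not None \
        else 2 * window_points
    pos = np.nonzero(trace.time >= 0)[0]
    if len(pos) == 0:
        raise ValueError("trace has no samples at positive potential")
    i_dom = _domain_end_index(trace, int(pos[0]))
    t = trace.time[i_dom:]
    y = trace.current[i_dom:]
    if len(t) < 3 * msp:
        raise ValueError("post-domain record too short for detection")

    amp_ev, _ = _channel_event(t, y, "amplitude", msp, alpha)
    # The MSTD of overlapping windows is autocorrelated over the window
    # length, which would make BIC and the F-test anticonservative; the
    # noise channel is therefore fitted on non-overlapping windows
    # (every window_points-th MSTD sample), which are nearly independent.
    m = moving_std(y, window_points)
    nt_t = t[window_points - 1::window_points]
    nt_y = m[::window_points]
    noise_ev = None
    msp_noise = max(2, msp // window_points)
    if len(nt_t) >= 3 * msp_noise:
        noise_ev, _ = _channel_event(nt_t, nt_y, "noise", msp_noise, alpha)

    events = []
    if amp_ev is not None:
        events.append(amp_ev)
    if noise_ev is not None:
        events.append(noise_ev)
    if amp_ev is not None and noise_ev is not None:
        overlap = (amp_ev.t_S < noise_ev.t_E) and (noise_ev.t_S < amp_ev.t_E)
        amp_ev.corroborated = noise_ev.corroborated = overlap
    for ev in events:
        pre = ev.t_S - t[0]
        post = t[-1] - ev.t_E
        if pre < MIN_BASELINE_S or post < MIN_BASELINE_S:
            warnings.warn(
                f"{ev.channel} channel baselines span {pre:.0f}/{post:.0f} s; "
                f"baselines of {MIN_BASELINE_S:.0f} s or longer are preferred",
                stacklevel=2)
    return events
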