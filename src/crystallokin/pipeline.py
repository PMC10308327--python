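"""Reproducible simulate → detect → growth → report orchestration.

File formats
------------
* trace CSV: columns ``time_s,current_nA,potential_V``
* length-series CSV: ``time_s,M_um,LA_um,M_censored,LA_censored``
* reports and truth records: JSON

Every report embeds provenance: the SHA-256 hash of the canonical config,
the seed, and the package version, so a rerun with the same config and seed
yields a byte-identical payload (timestamps are deliberately not recorded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .growth_kinetics import (GrowthFit, aspect_ratio_series, face_rates,
                              fit_growth)
from .synthetic_data import (LengthSeries, SimGrowthConfig, SimTraceConfig,
                             growth_condition_config, simulate_current_trace,
                             simulate_length_series)
from .trace_signal import CurrentTrace, detect_nucleation, segment_stages

__all__ = ["RunConfig", "RunReport", "SchemaError", "run_pipeline",
           "read_trace_csv", "write_trace_csv", "read_length_series_csv",
           "write_length_series_csv", "write_report"]

log = logging.getLogger("crystallokin")

TRACE_COLUMNS = ["time_s", "current_nA", "potential_V"]
SERIES_COLUMNS = ["time_s", "M_um", "LA_um", "M_censored", "LA_censored"]


class SchemaError(ValueError):
    """An input file does not match the documented column schema."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    trace_path: str | None = None
    series_path: str | None = None
    simulate_trace: bool = False
    trace_config: dict = field(default_factory=dict)
    simulate_series: bool = False
    series_condition: str | None = None      # preset name, optional
    series_config: dict = field(default_factory=dict)
    window_points: int = 50
    alpha: float = 1e-4
    min_segment_points: int | None = None
    pixel_size: float = 250.0
    max_stages: int = 2
    r_min: float = 0.99
    geometry_factor_110: float = 0.5
    geometry_factor_101: float = 0.5
    out_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def hash(self) -> str:
        # output location and verbosity do not affect results
        payload = {k: v for k, v in asdict(self).items()
                   if k not in ("out_dir", "log_level")}
        canon = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    version: str
    events: list = field(default_factory=list)
    stages: list = field(default_factory=list)
    growth: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def to_payload(self) -> dict:
        return asdict(self)


def read_trace_csv(path) -> CurrentTrace:
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trace CSV missing columns: {missing}")
    t = df["time_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise SchemaError("trace CSV time_s must be strictly increasing")
    fs = 1.0 / np.median(np.diff(t))
    return CurrentTrace(t, df["current_nA"].to_numpy(float),
                        df["potential_V"].to_numpy(float), fs)


def write_trace_csv(trace: CurrentTrace, path) -> None:
    pd.DataFrame({
        "time_s": trace.time,
        "current_nA": np.round(trace.current, 4),
        "potential_V": trace.potential,
    }).to_csv(path, index=False)


def read_length_series_csv(path, pixel_size: float = 250.0,
                           detection_limit: int = 2) -> LengthSeries:
    df = pd.read_csv(path)
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"length-series CSV missing columns: {missing}")
    t = df["time_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise SchemaError("length-series CSV time_s must be increasing")
    return LengthSeries(t, df["M_um"].to_numpy(float),
                        df["LA_um"].to_numpy(float),
                        df["M_censored"].to_numpy(bool),
                        df["LA_censored"].to_numpy(bool),
                        pixel_size, detection_limit)


def write_length_series_csv(series: LengthSeries, path) -> None:
    pd.DataFrame({
        "time_s": series.time,
        "M_um": series.M,
        "LA_um": series.L_A,
        "M_censored": series.M_censored,
        "LA_censored": series.LA_censored,
    }).to_csv(path, index=False)


def write_report(report: RunReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_payload(), fh, indent=2, default=float)


def _growth_payload(fit: GrowthFit, rates) -> dict:
    return {
        "M": {
            "breakpoints_s": fit.fit_M.breakpoint_times.tolist(),
            "slopes_nm_per_s": fit.slopes_nm_per_s("M").tolist(),
            "r_values": fit.fit_M.r_values.tolist(),
            "flagged": fit.M_flagged.tolist(),
        },
        "LA": {
            "breakpoints_s": fit.fit_LA.breakpoint_times.tolist(),
            "slopes_nm_per_s": fit.slopes_nm_per_s("LA").tolist(),
            "r_values": fit.fit_LA.r_values.tolist(),
            "flagged": fit.LA_flagged.tolist(),
        },
        "G_110_nm_per_s": rates.G_110.tolist(),
        "G_101_nm_per_s": rates.G_101.tolist(),
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages in order and write their artifacts.

    Partial inputs give partial reports: a trace (given or simulated) is
    segmented and scanned for nucleation; a length series (given or
    simulated) is fitted for two-stage growth, face rates and aspect ratio.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.hash(), seed=config.seed,
                       version=__version__)

    trace = None
    if config.simulate_trace:
        tc = SimTraceConfig(**{**config.trace_config, "seed": config.seed})
        trace, truth = simulate_current_trace(tc)
        write_trace_csv(trace, out / "trace.csv")
        truth.to_json(out / "trace_truth.json")
        report.truth["trace"] = {k: v for k, v in truth.params.items()
                                 if k != "config"}
        log.info("simulated trace: %d samples", len(trace))
    elif config.trace_path:
        trace = read_trace_csv(config.trace_path)

    if trace is not None:
        seg = segment_stages(trace, config.window_points, config.alpha,
                             config.min_segment_points)
        report.stages = [
            {"label": lab, "start_s": float(s), "end_s": float(e)}
            for lab, s, e in zip(seg.labels, seg.starts, seg.ends)]
        events = detect_nucleation(trace, config.window_points, config.alpha,
                                   config.min_segment_points)
        report.events = [{
            "t_S_s": ev.t_S, "t_E_s": ev.t_E, "V_N_per_s": ev.V_N,
            "channel": ev.channel, "corroborated": ev.corroborated,
            "p_values": ev.p_values.tolist(),
        } for ev in events]
        pd.DataFrame(report.stages).to_csv(out / "stages.csv", index=False)
        log.info("detected %d nucleation event(s)", len(events))

    series = None
    if config.simulate_series:
        if config.series_condition:
            sc = growth_condition_config(
                config.series_condition,
                geometry_factor=config.geometry_factor_101,
                seed=config.seed, **config.series_config)
        else:
            sc = SimGrowthConfig(**{**config.series_config,
                                    "seed": config.seed})
        series, struth = simulate_length_series(sc)
        write_length_series_csv(series, out / "length_series.csv")
        struth.to_json(out / "series_truth.json")
        report.truth["series"] = {k: v for k, v in struth.params.items()
                                  if k != "config"}
    elif config.series_path:
        series = read_length_series_csv(config.series_path,
                                        config.pixel_size)

    if series is not None:
        gfit = fit_growth(series, config.max_stages, config.r_min)
        rates = face_rates(gfit, config.geometry_factor_110,
                           config.geometry_factor_101)
        report.growth = _growth_payload(gfit, rates)
        ratio = aspect_ratio_series(series)
        pd.DataFrame({"time_s": ratio.time,
                      "aspect_ratio": ratio.aspect_ratio}
                     ).to_csv(out / "aspect_ratio.csv", index=False)

    write_report(report, out / "report.json")
    return report
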