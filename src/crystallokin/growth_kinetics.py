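"""Facet growth kinetics of single tetragonal lysozyme crystals.

Crystal habit is tracked through two in-plane dimensions of the brightfield
silhouette: the long axis M and the width L_A.  Their elongation is fitted as
continuous piecewise-linear growth (at most two stages by default — a slower
early stage followed by a faster, transport-independent late stage), and the
per-stage dimension slopes are converted to face growth rates: G_110 from the
L_A direction and G_101 from the M direction, via configurable geometry
factors (default 0.5: a face advances from the crystal centre at half the
dimension's elongation rate).

Lengths below the optical limit (``detection_limit`` pixels, default 2 px of
250 nm) are censored and excluded from fits, never imputed.  The evolving
habit is summarized by the aspect ratio M / L_A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .piecewise import PiecewiseFit, select_breakpoints
from .synthetic_data import LengthSeries

__all__ = ["LengthSeries", "GrowthFit", "FaceRates", "RatioSeries",
           "measure_lengths", "fit_growth", "face_rates",
           "aspect_ratio_series"]


@dataclass
class GrowthFit:
    """Per-dimension piecewise-linear growth fits (slopes in um/s)."""

    fit_M: PiecewiseFit
    fit_LA: PiecewiseFit
    r_min: float

    def _flags(self, fit):
        with np.errstate(invalid="ignore"):
            return np.abs(np.nan_to_num(fit.r_values)) < self.r_min

    @property
    def M_flagged(self) -> np.ndarray:
        """Segments of the M fit failing the |r| >= r_min quality bar."""
        return self._flags(self.fit_M)

    @property
    def LA_flagged(self) -> np.ndarray:
        return self._flags(self.fit_LA)

    def slopes_nm_per_s(self, dimension: str) -> np.ndarray:
        fit = self.fit_M if dimension == "M" else self.fit_LA
        return fit.segment_slopes * 1000.0


@dataclass
class FaceRates:
    """Per-stage face growth rates (nm/s) for the (110) and (101) faces."""

    G_110: np.ndarray
    G_101: np.ndarray
    geometry_factor_110: float
    geometry_factor_101: float


@dataclass
class RatioSeries:
    """Aspect ratio M / L_A wherever both dimensions are measurable."""

    time: np.ndarray
    aspect_ratio: np.ndarray


def _component_lengths(frame: np.ndarray, threshold: float,
                       square_tol: float = 0.05):
    """Longest/shortest extent (pixels) of the largest bright component.

    The component is measured along its principal axes (oriented bounding
    box); when the two principal variances are within ``square_tol`` of each
    other the orientation is ill-defined and the axis-aligned box is used.
    """
    mask = frame > threshold
    if not mask.any():
        return None
    labels = measure.label(mask)
    props = measure.regionprops(labels)
    region = max(props, key=lambda p: p.area)
    coords = region.coords.astype(float)
    if len(coords) == 1:
        return 1.0, 1.0
    centred = coords - coords.mean(axis=0)
    cov = centred.T @ centred / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] <= 0 or (evals[1] - evals[0]) / evals[1] < square_tol:
        spans = np.ptp(coords, axis=0) + 1.0
    else:
        proj = centred @ evecs
        spans = np.ptp(proj, axis=0) + 1.0
    spans = np.sort(spans)
    return float(spans[1]), float(spans[0])


def measure_lengths(frames: np.ndarray, pixel_size: float,
                    intensity_threshold: float = 0.5,
                    times: np.ndarray | None = None,
                    detection_limit: int = 2) -> LengthSeries:
    """Measure M and L_A from a stack of silhouette frames.

    Per frame: threshold, keep the largest connected component, measure its
    oriented bounding box; the longer side is M, the shorter L_A (in um via
    ``pixel_size`` in nm).  Sides below ``detection_limit`` pixels — and
    empty frames — are censored.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("frames must be a non-empty (n, H, W) stack")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    n = frames.shape[0]
    t = np.asarray(times, dtype=float) if times is not None \
        else np.arange(n, dtype=float)
    if len(t) != n:
        raise ValueError("times must match the number of frames")
    M = np.zeros(n)
    LA = np.zeros(n)
    M_c = np.ones(n, dtype=bool)
    LA_c = np.ones(n, dtype=bool)
    for i in range(n):
        got = _component_lengths(frames[i], intensity_threshold)
        if got is None:
            continue
        long_px, short_px = got
        M[i] = long_px * pixel_size / 1000.0
        LA[i] = short_px * pixel_size / 1000.0
        M_c[i] = long_px < detection_limit
        LA_c[i] = short_px < detection_limit
    return LengthSeries(t, M, LA, M_c, LA_c, pixel_size, detection_limit)


def _fit_dimension(t, length_um, censored, max_stages, min_segment_points,
                   alpha):
    keep = ~np.asarray(censored, dtype=bool)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 uncensored points")
    return select_breakpoints(np.asarray(t, float)[keep],
                              np.asarray(length_um, float)[keep],
                              max_breakpoints=max_stages - 1,
                              min_segment_points=min_segment_points,
                              alpha=alpha)


def fit_growth(series: LengthSeries, max_stages: int = 2,
               r_min: float = 0.99, min_segment_points: int = 8,
               alpha: float = 1e-4) -> GrowthFit:
    """Fit at-most-``max_stages`` piecewise-linear growth per dimension.

    Censored points are dropped.  Segments whose Pearson |r| falls below
    ``r_min`` are flagged (not rejected) on the returned fit.
    """
    if max_stages < 1:
        raise ValueError("max_stages must be >= 1")
    fit_M = _fit_dimension(series.time, series.M, series.M_censored,
                           max_stages, min_segment_points, alpha)
    fit_LA = _fit_dimension(series.time, series.L_A, series.LA_censored,
                            max_stages, min_segment_points, alpha)
    return GrowthFit(fit_M, fit_LA, r_min)


def face_rates(fit: GrowthFit, geometry_factor_110: float = 0.5,
               geometry_factor_101: float = 0.5) -> FaceRates:
    """Convert per-stage dimension slopes to face growth rates (nm/s).

    G_110(stage) = factor_110 * dL_A/dt;  G_101(stage) = factor_101 * dM/dt.
    """
    if geometry_factor_110 <= 0 or geometry_factor_101 <= 0:
        raise ValueError("geometry factors must be positive")
    return FaceRates(
        G_110=geometry_factor_110 * fit.slopes_nm_per_s("LA"),
        G_101=geometry_factor_101 * fit.slopes_nm_per_s("M"),
        geometry_factor_110=geometry_factor_110,
        geometry_factor_101=geometry_factor_101,
    )


def aspect_ratio_series(series: LengthSeries) -> RatioSeries:
    """Aspect ratio M / L_A at every co-measured (uncensored) time point."""
    if len(series) == 0:
        raise ValueError("empty length series")
    ok = ~series.M_censored & ~series.LA_censored
    la = series.L_A[ok]
    if np.any(la == 0):
        raise ValueError("L_A is zero at an uncensored point")
    return RatioSeries(series.time[ok], series.M[ok] / la)
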