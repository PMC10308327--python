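"""Continuous piecewise-linear regression with breakpoint search.

The central statistical primitive of the package: a least-squares fit of a
*continuous* broken-line model

    y(x) = b0 + b1*x + sum_j c_j * max(0, x - t_j)

where the breakpoints ``t_j`` are restricted to observed abscissae.  The
breakpoint locations are chosen by exhaustive search over all admissible
placements (globally optimal) when the candidate set is small, and by a
coarse-grid search followed by full-resolution coordinate refinement for long
records.  The per-placement residual sum of squares is evaluated in O(1) from
suffix cumulative sums of x, x^2, y, x*y, y^2, which makes exhaustive search
over ~10^5-10^6 placements cheap.

Model-order selection (`select_breakpoints`) uses BIC, after which every
retained breakpoint must survive an F-test against the nested model with that
breakpoint removed (default significance 1e-4).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["PiecewiseFit", "fit_piecewise_linear", "select_breakpoints"]


@dataclass
class PiecewiseFit:
    """A fitted continuous piecewise-linear model.

    ``breakpoint_times`` are strictly increasing interior abscissae;
    ``segment_slopes``/``segment_intercepts`` describe each linear piece in
    original units, left to right.  ``continuity`` is always True: adjacent
    pieces meet at every breakpoint by construction.
    """

    breakpoint_times: np.ndarray
    segment_slopes: np.ndarray
    segment_intercepts: np.ndarray
    rss: float
    n: int
    r_values: np.ndarray
    breakpoint_p_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    continuity: bool = True

    @property
    def n_breakpoints(self) -> int:
        return len(self.breakpoint_times)

    @property
    def n_parameters(self) -> int:
        # intercept + slope + (coefficient, location) per breakpoint
        return 2 + 2 * self.n_breakpoints

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        edges = np.concatenate([[-np.inf], self.breakpoint_times, [np.inf]])
        seg = np.clip(np.searchsorted(edges, x, side="right") - 1, 0,
                      len(self.segment_slopes) - 1)
        return self.segment_intercepts[seg] + self.segment_slopes[seg] * x

    def bic(self, rss_floor: float = 0.0) -> float:
        """BIC with a numerical rss floor.

        The floor keeps comparisons meaningful on (near-)exact data, where
        every model order reaches rounding-level rss and the raw
        log-likelihood would reward meaningless extra parameters.
        """
        n = self.n
        rss = max(self.rss, rss_floor, np.finfo(float).tiny * n)
        return n * np.log(rss / n) + self.n_parameters * np.log(n)


def _hinge_design(x: np.ndarray, breaks: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for b in breaks:
        cols.append(np.maximum(0.0, x - b))
    return np.column_stack(cols)


def _coefs_to_segments(beta: np.ndarray, breaks: np.ndarray):
    """Convert hinge-basis coefficients to per-segment slope/intercept."""
    slopes = np.cumsum(np.concatenate([[beta[1]], beta[2:]]))
    intercepts = [beta[0]]
    for j, b in enumerate(breaks):
        # continuity: value matches at b
        intercepts.append(intercepts[-1] + (slopes[j] - slopes[j + 1]) * b)
    return slopes, np.asarray(intercepts)


def _segment_r_values(x, y, breaks):
    edges = np.concatenate([[-np.inf], breaks, [np.inf]])
    rvals = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (x > lo) & (x <= hi)
        xs, ys = x[m], y[m]
        if len(xs) < 3 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
            rvals.append(np.nan)
        else:
            rvals.append(stats.pearsonr(xs, ys).statistic)
    return np.asarray(rvals)


def _lstsq_fit(x, y, breaks):
    X = _hinge_design(x, np.asarray(breaks, dtype=float))
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


class _SuffixSums:
    """O(1) suffix sums of 1, x, x^2, y, x*y over a sorted grid.

    Data are internally centred/scaled so the 4x4 normal equations stay well
    conditioned even for hour-long traces.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray):
        self.x0 = x.mean()
        self.xs = np.ptp(x) / 2 or 1.0
        self.y0 = y.mean()
        xn = (x - self.x0) / self.xs
        yn = y - self.y0
        self.xn = xn
        self.yn = yn
        n = len(x)
        self.n = n

        def suff(v):
            c = np.zeros(n + 1)
            np.cumsum(v[::-1], out=c[1:])
            return c[::-1].copy()

        self.S0 = suff(np.ones(n))
        self.S1 = suff(xn)
        self.S2 = suff(xn * xn)
        self.Sy = suff(yn)
        self.Sxy = suff(xn * yn)
        self.Syy = float(yn @ yn)

    def to_scaled(self, i: np.ndarray) -> np.ndarray:
        return self.xn[i]

    def rss_for_index_sets(self, idx: np.ndarray) -> np.ndarray:
        """RSS (scaled-y units) for each row of breakpoint indices.

        ``idx`` has shape (m, k) with k in {0, 1, 2}; each row holds sorted
        positions of the breakpoints in the data grid.
        """
        idx = np.atleast_2d(idx)
        m, k = idx.shape
        p = 2 + k
        G = np.empty((m, p, p))
        r = np.empty((m, p))
        n = self.n
        G[:, 0, 0] = n
        G[:, 0, 1] = G[:, 1, 0] = self.S1[0]
        G[:, 1, 1] = self.S2[0]
        r[:, 0] = self.Sy[0]
        r[:, 1] = self.Sxy[0]
        bvals = self.xn[idx]  # (m, k)
        for a in range(k):
            s = idx[:, a] + 1  # hinge is zero at and before its own abscissa
            b = bvals[:, a]
            S0s, S1s, S2s = self.S0[s], self.S1[s], self.S2[s]
            G[:, 0, 2 + a] = G[:, 2 + a, 0] = S1s - b * S0s
            G[:, 1, 2 + a] = G[:, 2 + a, 1] = S2s - b * S1s
            r[:, 2 + a] = self.Sxy[s] - b * self.Sy[s]
            for c in range(a, k):
                s2 = idx[:, c] + 1
                b2 = bvals[:, c]
                val = (self.S2[s2] - (b + b2) * self.S1[s2]
                       + b * b2 * self.S0[s2])
                G[:, 2 + a, 2 + c] = G[:, 2 + c, 2 + a] = val
        try:
            beta = np.linalg.solve(G, r[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # a singular placement somewhere in the batch: tiny ridge
            G = G + 1e-10 * np.trace(G, axis1=1, axis2=2)[:, None, None] \
                * np.eye(p)
            beta = np.linalg.solve(G, r[..., None])[..., 0]
        rss = self.Syy - np.einsum("mp,mp->m", beta, r)
        return np.maximum(rss, 0.0)


def _admissible_range(n: int, msp: int):
    lo = msp - 1          # left segment keeps >= msp points
    hi = n - 1 - msp      # right segment keeps >= msp points
    return lo, hi


def _pair_grid(cands: np.ndarray, msp: int):
    i, j = np.meshgrid(cands, cands, indexing="ij")
    keep = (j - i) >= msp
    return np.column_stack([i[keep], j[keep]])


_MAX_EXHAUSTIVE_PAIRS = 2_000_000
_COARSE_CANDIDATES = 400
_CHUNK = 400_000


def _best_indices(ss: _SuffixSums, k: int, msp: int) -> np.ndarray:
    """Globally search breakpoint index placements minimizing rss."""
    n = ss.n
    lo, hi = _admissible_range(n, msp)
    if hi < lo or (k == 2 and hi - lo < msp):
        raise ValueError("infeasible segment constraints")
    cands = np.arange(lo, hi + 1)
    if k == 1:
        return _argmin_pairs(ss, cands[:, None])
    # k == 2
    n_pairs_full = len(cands) * (len(cands) - 1) // 2
    if n_pairs_full <= _MAX_EXHAUSTIVE_PAIRS:
        pairs = _pair_grid(cands, msp)
        return _argmin_pairs(ss, pairs)
    # coarse-to-fine
    stride = max(1, len(cands) // _COARSE_CANDIDATES)
    coarse = cands[::stride]
    pairs = _pair_grid(coarse, msp)
    cur = _argmin_pairs(ss, pairs)
    for _ in range(4):
        prev = cur.copy()
        for a in range(2):
            lo_a = max(lo, cur[a] - stride)
            hi_a = min(hi, cur[a] + stride)
            sweep = np.arange(lo_a, hi_a + 1)
            other = cur[1 - a]
            if a == 0:
                sweep = sweep[(other - sweep) >= msp]
                rows = np.column_stack([sweep, np.full_like(sweep, other)])
            else:
                sweep = sweep[(sweep - other) >= msp]
                rows = np.column_stack([np.full_like(sweep, other), sweep])
            if len(rows) == 0:
                continue
            rss = ss.rss_for_index_sets(rows)
            cur[a] = rows[int(np.argmin(rss))][a]
        if np.array_equal(cur, prev):
            break
    return cur


def _argmin_pairs(ss: _SuffixSums, pairs: np.ndarray) -> np.ndarray:
    best_rss = np.inf
    best = None
    for start in range(0, len(pairs), _CHUNK):
        chunk = pairs[start:start + _CHUNK]
        rss = ss.rss_for_index_sets(chunk)
        a = int(np.argmin(rss))
        if rss[a] < best_rss:
            best_rss = rss[a]
            best = chunk[a]
    return np.asarray(best, dtype=int).copy()


def fit_piecewise_linear(x, y, n_breakpoints: int = 0,
                         min_segment_points: int = 2) -> PiecewiseFit:
    """Least-squares continuous piecewise-linear fit with fixed model order.

    Breakpoint candidates are the observed abscissae; every segment must
    contain at least ``min_segment_points`` points.  With zero breakpoints
    this is ordinary simple linear regression.  Ties in rss are broken toward
    the earliest breakpoint placement.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if np.any(np.diff(x) <= 0):
        order = np.argsort(x, kind="stable")
        x, y = x[order], y[order]
    n = len(x)
    if n_breakpoints < 0:
        raise ValueError("n_breakpoints must be >= 0")
    if n_breakpoints > 2:
        raise NotImplementedError("at most 2 breakpoints are supported")
    msp = max(int(min_segment_points), 1)
    if n < (n_breakpoints + 1) * msp:
        raise ValueError(
            f"need at least {(n_breakpoints + 1) * msp} points for "
            f"{n_breakpoints} breakpoints with min_segment_points={msp}")
    if n_breakpoints == 0:
        beta, rss = _lstsq_fit(x, y, np.empty(0))
        slopes, intercepts = _coefs_to_segments(beta, np.empty(0))
        return PiecewiseFit(np.empty(0), slopes, intercepts, rss, n,
                            _segment_r_values(x, y, np.empty(0)))
    ss = _SuffixSums(x, y)
    idx = _best_indices(ss, n_breakpoints, msp)
    breaks = x[idx]
    beta, rss = _lstsq_fit(x, y, breaks)
    slopes, intercepts = _coefs_to_segments(beta, breaks)
    return PiecewiseFit(breaks, slopes, intercepts, rss, n,
                        _segment_r_values(x, y, breaks))


def _breakpoint_p_values(x, y, fit: PiecewiseFit) -> np.ndarray:
    """F-test of each breakpoint against the nested model without it.

    Removing a breakpoint frees 2 parameters (its hinge coefficient and its
    location); the reduced model keeps the remaining breakpoints fixed.
    """
    n = fit.n
    k = fit.n_breakpoints
    dfe = n - fit.n_parameters
    if dfe <= 0:
        return np.full(k, np.nan)
    pvals = np.empty(k)
    for j in range(k):
        reduced = np.delete(fit.breakpoint_times, j)
        _, rss_red = _lstsq_fit(np.asarray(x, float), np.asarray(y, float),
                                reduced)
        if fit.rss <= 0:
            pvals[j] = 0.0
            continue
        F = (rss_red - fit.rss) / 2.0 / (fit.rss / dfe)
        pvals[j] = stats.f.sf(max(F, 0.0), 2, dfe)
    return pvals


def select_breakpoints(x, y, max_breakpoints: int = 2,
                       min_segment_points: int = 2,
                       alpha: float = 1e-4) -> PiecewiseFit:
    """Fit with data-driven model order.

    Fits 0..``max_breakpoints`` breakpoints, picks the order by BIC, then
    requires every retained breakpoint to pass an F-test (p < ``alpha``)
    against the nested model without it; non-significant breakpoints are
    dropped (least significant first) and the smaller model is refitted.
    Returns the 0-breakpoint fit when nothing is significant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    msp = max(int(min_segment_points), 1)
    fits = {}
    for k in range(int(max_breakpoints) + 1):
        if len(x) < (k + 1) * msp:
            break
        try:
            fits[k] = fit_piecewise_linear(x, y, k, msp)
        except ValueError:
            break
    if not fits:
        raise ValueError("series too short for even a single linear fit")
    floor = len(x) * (1e-10 * max(np.ptp(y), np.finfo(float).tiny)) ** 2
    k = min(fits, key=lambda kk: fits[kk].bic(floor))
    fit = fits[k]
    while fit.n_breakpoints > 0:
        pvals = _breakpoint_p_values(x, y, fit)
        fit.breakpoint_p_values = pvals
        if np.all(pvals < alpha):
            break
        k = fit.n_breakpoints - 1
        fit = fits.get(k) or fit_piecewise_linear(x, y, k, msp)
    if fit.n_breakpoints == 0:
        fit.breakpoint_p_values = np.empty(0)
    return fit
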