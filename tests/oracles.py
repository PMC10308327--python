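"""Independent brute-force oracles used to validate the fitting engine.

Deliberately naive: explicit hinge design matrices solved with
``np.linalg.lstsq`` and full enumeration of admissible breakpoint
placements.  Must stay independent of ``crystallokin.piecewise``'s
cumulative-sum normal-equation machinery.
"""

import numpy as np


def hinge_design(x, breaks):
    cols = [np.ones_like(x), x]
    for b in breaks:
        cols.append(np.maximum(0.0, x - b))
    return np.column_stack(cols)


def lstsq_rss(x, y, breaks):
    X = hinge_design(x, np.asarray(breaks, dtype=float))
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def brute_force_best(x, y, n_breakpoints, min_segment_points):
    """(min rss, breakpoint times) by exhaustive enumeration."""
    n = len(x)
    msp = min_segment_points
    lo, hi = msp - 1, n - 1 - msp
    if n_breakpoints == 0:
        combos = [()]
    elif n_breakpoints == 1:
        combos = [(i,) for i in range(lo, hi + 1)]
    elif n_breakpoints == 2:
        combos = [(i, j) for i in range(lo, hi + 1)
                  for j in range(i + msp, hi + 1)]
    else:
        raise ValueError("oracle supports at most 2 breakpoints")
    best_rss, best_combo = np.inf, None
    for combo in combos:
        rss = lstsq_rss(x, y, x[list(combo)])
        if rss < best_rss:
            best_rss, best_combo = rss, combo
    return best_rss, x[list(best_combo)]


def ols_closed_form(x, y):
    """Textbook simple-regression slope/intercept from moment formulas."""
    xm, ym = x.mean(), y.mean()
    slope = ((x - xm) @ (y - ym)) / ((x - xm) @ (x - xm))
    return slope, ym - slope * xm
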