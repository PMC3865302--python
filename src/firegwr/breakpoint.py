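"""Broken-stick quantile regression: population-density thresholds in fire.

The conditional tau-quantile of log10 burned area given log10 population
density is modelled as a continuous piecewise-linear function.  For a
candidate breakpoint set {c1 < c2 < ...} the design is the hinge basis
{1, x, (x - c1)+, (x - c2)+, ...}, fit by minimising the check loss

    sum_i rho_tau(y_i - f(x_i)),   rho_tau(r) = r * (tau - 1[r < 0]).

Breakpoints are found by exhaustive search over a grid of candidates inside
the central 90% of the x range: the loss is piecewise linear in c, so grid
search is exact to the grid resolution and auditable against brute force.
Candidates leaving any segment with fewer than 10 points are skipped; ties
break toward the smallest breakpoint.  A breakpoint c on the log10 axis is
a threshold of 10^c persons/km^2.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

MIN_SEGMENT_POINTS = 10


@dataclass
class BrokenStickFit:
    tau: float
    n_breaks: int
    breakpoints: list[float]
    slopes: list[float]          # per segment, left to right
    intercept: float             # of the first segment
    loss: float
    candidate_grid: np.ndarray = field(repr=False, default=None)

    def predict(self, x) -> np.ndarray:
        from .synthetic import polyline_value

        return polyline_value(x, self.intercept, self.breakpoints, self.slopes)


def check_loss(residuals, tau: float) -> float:
    """Asymmetric absolute loss whose minimiser is the tau-th quantile."""
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must lie in (0, 1)")
    r = np.asarray(residuals, dtype=float)
    return float(np.sum(r * (tau - (r < 0))))


def _quantreg(X: np.ndarray, y: np.ndarray, tau: float) -> np.ndarray:
    """Check-loss minimising coefficients for design X (statsmodels IRLS)."""
    from statsmodels.regression.quantile_regression import QuantReg

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = QuantReg(y, X).fit(q=tau, p_tol=1e-9, max_iter=2000)
    return np.asarray(res.params, dtype=float)


def fit_quantile_line(x, y, tau: float) -> tuple[float, float, float]:
    """Single-line quantile fit; returns (intercept, slope, check loss)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate constant predictor")
    X = np.column_stack([np.ones_like(x), x])
    beta = _quantreg(X, y, tau)
    loss = check_loss(y - X @ beta, tau)
    return float(beta[0]), float(beta[1]), loss


def _hinge_design(x: np.ndarray, breaks: tuple[float, ...]) -> np.ndarray:
    cols = [np.ones_like(x), x]
    cols += [np.maximum(x - c, 0.0) for c in breaks]
    return np.column_stack(cols)


def _segment_counts(x: np.ndarray, breaks: tuple[float, ...]) -> list[int]:
    edges = [-np.inf, *breaks, np.inf]
    return [int(((x > lo) & (x <= hi)).sum()) for lo, hi in zip(edges, edges[1:])]


def fit_broken_stick(x, y, tau: float, n_breaks: int = 1,
                     grid: np.ndarray | int | None = None) -> BrokenStickFit:
    """Continuous piecewise-linear quantile fit with 1 or 2 breakpoints.

    ``grid`` is the candidate-breakpoint axis: an explicit array, a count
    (points spread over the central 90% of the x range), or None for the
    default (101 candidates for one break, 31 per axis for two).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_breaks not in (1, 2):
        raise ValueError("n_breaks must be 1 or 2")
    lo, hi = np.quantile(x, [0.05, 0.95])
    if grid is None:
        grid = 101 if n_breaks == 1 else 31
    if np.isscalar(grid):
        grid = np.linspace(lo, hi, int(grid))
    grid = np.asarray(grid, dtype=float)

    candidates = (itertools.combinations(grid, 2) if n_breaks == 2
                  else ((c,) for c in grid))
    best = None
    for breaks in candidates:
        breaks = tuple(breaks)
        if min(_segment_counts(x, breaks)) < MIN_SEGMENT_POINTS:
            continue
        X = _hinge_design(x, breaks)
        try:
            beta = _quantreg(X, y, tau)
        except Exception:
            continue
        loss = check_loss(y - X @ beta, tau)
        # strict < keeps the earliest (smallest-breakpoint) minimiser
        if best is None or loss < best[0] - 1e-12:
            best = (loss, breaks, beta)
    if best is None:
        raise ValueError("no valid breakpoint candidate (segments too small)")
    loss, breaks, beta = best
    slopes = [float(beta[1])]
    for j in range(n_breaks):
        slopes.append(slopes[-1] + float(beta[2 + j]))
    return BrokenStickFit(tau=tau, n_breaks=n_breaks, breakpoints=list(breaks),
                          slopes=slopes, intercept=float(beta[0]), loss=loss,
                          candidate_grid=grid)


def threshold_in_density_units(fit: BrokenStickFit) -> list[float]:
    """Breakpoints converted from the log10 axis to persons/km^2."""
    return [float(10.0 ** c) for c in fit.breakpoints]
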