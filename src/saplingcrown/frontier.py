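"""Polynomial frontier (boundary) estimation for branch-tip clouds.

Given branch tips ``(rdinc_i, ocr_i)`` the frontier of degree ``p`` is the
polynomial ``phi(x) = theta_0 + theta_1 x + ... + theta_p x**p`` that lies
on or above every point while enclosing the least area over the support
``[a, b]`` (default [0, 1], the biological range of relative crown depth):

    minimise    sum_k theta_k (b**(k+1) - a**(k+1)) / (k + 1)
    subject to  phi(x_i) >= y_i   for every data point
                phi(g_j) >= 0     on an even grid over the support

— a linear program in theta, solved with the HiGHS solver.  The
nonnegativity rows encode that a crown radius is a physical length; they
also bound the program (without them a tilted envelope pivoting outside a
one-sided point cloud can decrease the enclosed area without limit).  The degree is
chosen by information criteria on the envelope slack sum
``S(p) = sum_i (phi_p(x_i) - y_i)``:

    AIC(p) = log(S(p)) + (p + 1)/n
    BIC(p) = log(S(p)) + log(n) (p + 1)/(2 n)

(the forms used in the polynomial-frontier literature).  AIC decides; when
AIC and BIC disagree, the smaller of the two degrees is taken (parsimony).

Enveloping the data points does not envelope the continuum between them: a
post-hoc audit evaluates the polynomial on an equally spaced grid and
reports dips below the binned data maxima and below zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

__all__ = ["FrontierFit", "FrontierError", "fit_polynomial_frontier",
           "select_degree", "eval_frontier", "audit_frontier"]


class FrontierError(RuntimeError):
    pass


@dataclass
class FrontierFit:
    """A fitted polynomial envelope of a point cloud."""

    degree: int
    theta: np.ndarray          # theta_0 .. theta_p
    support: tuple[float, float]
    aic: float
    bic: float
    n_points: int

    def __call__(self, grid):
        return eval_frontier(self, grid)

    def to_dict(self) -> dict:
        return {"degree": self.degree, "theta": list(map(float, self.theta)),
                "support": list(self.support), "aic": self.aic, "bic": self.bic,
                "n_points": self.n_points}


def _area_coefficients(degree: int, a: float, b: float) -> np.ndarray:
    k = np.arange(degree + 1)
    return (b ** (k + 1) - a ** (k + 1)) / (k + 1)


def _information_criteria(slack_sum: float, degree: int, n: int) -> tuple[float, float]:
    # envelopes exact to solver tolerance are treated as zero-slack so the
    # complexity penalty (not log of numerical noise) breaks ties toward
    # smaller degrees; the floor keeps the log finite
    s = np.log(slack_sum if slack_sum > 1e-9 else 1e-300)
    return (float(s + (degree + 1) / n),
            float(s + np.log(n) * (degree + 1) / (2 * n)))


def fit_polynomial_frontier(x, y, degree: int,
                            support: tuple[float, float] = (0.0, 1.0),
                            n_nonneg: int = 201) -> FrontierFit:
    """Minimal-area polynomial envelope of the points, as a linear program.

    Requires at least ``degree + 1`` points with all ``x`` inside the
    support.  ``n_nonneg`` grid points carry the radius-nonnegativity rows.
    Raises :class:`FrontierError` when the program fails.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    a, b = map(float, support)
    if np.any((x < a - 1e-12) | (x > b + 1e-12)):
        raise ValueError("all x must lie within the support interval")
    n = x.size
    if n < degree + 1:
        raise ValueError(f"{n} points cannot constrain a degree-{degree} frontier")
    c = _area_coefficients(degree, a, b)
    vander = np.vander(x, degree + 1, increasing=True)   # phi(x_i) = V @ theta
    grid = np.linspace(a, b, n_nonneg)
    vg = np.vander(grid, degree + 1, increasing=True)    # phi(g_j) >= 0
    res = linprog(c, A_ub=-np.vstack([vander, vg]),
                  b_ub=-np.concatenate([y, np.zeros(n_nonneg)]),
                  bounds=[(None, None)] * (degree + 1), method="highs",
                  options={"primal_feasibility_tolerance": 1e-10})
    if not res.success:
        raise FrontierError(
            f"frontier LP failed (degree={degree}, n={n}): {res.message}")
    theta = np.asarray(res.x, float)
    # lift the intercept by any residual solver infeasibility so the fitted
    # polynomial envelopes every point exactly (area cost is of the same
    # ~1e-10 order as the solver tolerance)
    violation = float(np.min(vander @ theta - y))
    if violation < 0:
        theta[0] -= violation
    slack = float(np.sum(vander @ theta - y))
    aic, bic = _information_criteria(slack, degree, n)
    return FrontierFit(degree=degree, theta=theta, support=(a, b),
                       aic=aic, bic=bic, n_points=n)


def select_degree(x, y, max_degree: int = 20,
                  support: tuple[float, float] = (0.0, 1.0)) -> FrontierFit:
    """Fit degrees 0..max_degree and return the information-criterion choice.

    Degrees beyond ``n - 1`` points are skipped (underdetermined); degrees
    whose LP fails are skipped with a note on the returned fit's record.
    """
    x = np.asarray(x, float)
    n = x.size
    if n == 0:
        raise ValueError("no points")
    fits: dict[int, FrontierFit] = {}
    for p in range(0, min(max_degree, n - 1) + 1):
        try:
            fits[p] = fit_polynomial_frontier(x, y, p, support=support)
        except FrontierError:
            continue
    if not fits:
        raise FrontierError("no degree produced a bounded frontier")
    p_aic = min(fits, key=lambda p: (fits[p].aic, p))
    p_bic = min(fits, key=lambda p: (fits[p].bic, p))
    return fits[min(p_aic, p_bic)]


def eval_frontier(fit: FrontierFit, grid) -> np.ndarray:
    """Evaluate the fitted polynomial on a grid (Horner scheme)."""
    g = np.asarray(grid, float)
    out = np.zeros_like(g)
    for coef in fit.theta[::-1]:
        out = out * g + coef
    return out


def audit_frontier(fit: FrontierFit, x, y, n_grid: int = 201) -> dict:
    """Post-hoc envelope audit.

    Returns the minimal slack at the data points (negative = violation of
    the envelope constraint beyond solver tolerance), plus between-point
    diagnostics on an ``n_grid`` equally spaced grid: dips of the polynomial
    below the running data maxima of the corresponding bin, and any
    negative (non-physical) radii.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    a, b = fit.support
    at_data = eval_frontier(fit, x) - y
    grid = np.linspace(a, b, n_grid)
    vals = eval_frontier(fit, grid)
    # binned data maxima: for each grid cell, the largest observed y
    idx = np.clip(np.searchsorted(grid, x, side="right") - 1, 0, n_grid - 2)
    bin_max = np.full(n_grid - 1, -np.inf)
    np.maximum.at(bin_max, idx, y)
    mid_vals = eval_frontier(fit, 0.5 * (grid[:-1] + grid[1:]))
    occupied = np.isfinite(bin_max)
    dips = int(np.sum(mid_vals[occupied] < bin_max[occupied] - 1e-9))
    return {
        "min_slack_at_data": float(at_data.min()) if x.size else np.nan,
        "n_data_violations": int(np.sum(at_data < -1e-9)),
        "n_grid_dips_below_bin_max": dips,
        "n_grid_negative": int(np.sum(vals < -1e-9)),
        "min_value_on_grid": float(vals.min()),
    }
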