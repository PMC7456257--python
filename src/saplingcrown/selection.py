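"""Selecting the outermost quantile against per-sapling boundary curves.

For every sapling, each quantile-regression curve (fitted at strip level,
evaluated at the sapling's own DBH and crown ratio) is compared with the
nonparametric boundary fitted to that sapling's branch tips.  Both curves
are evaluated on a fine relative-depth grid (10,000 even intervals, i.e.
10,001 points on [0, 1]) and compared by mean absolute distance; the
quantile with the smallest distance describes that sapling's outermost
crown profile.  Strip-level summaries report both the mean of per-sapling
best quantiles (rounded back to the 0.01 grid) and the quantile minimising
the aggregate (column-mean) distance; the two can differ and both are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .frontier import FrontierFit, eval_frontier, select_degree
from .io import Dataset, StripType
from .models import eval_profile
from .quantile import QuantileGridResult

__all__ = ["rdinc_grid", "curve_distance", "select_quantile_per_sapling",
           "strip_level_quantile", "QuantileSelection", "run_selection"]

N_INTERVALS = 10_000


def rdinc_grid() -> np.ndarray:
    """The 10,001-point evaluation grid: 0.0000, 0.0001, ..., 1.0000."""
    return np.linspace(0.0, 1.0, N_INTERVALS + 1)


def curve_distance(curve_a, curve_b) -> float:
    """Mean absolute distance between two curves on a common grid."""
    a = np.asarray(curve_a, float)
    b = np.asarray(curve_b, float)
    if a.shape != b.shape:
        raise ValueError(f"curve length mismatch: {a.shape} vs {b.shape}")
    return float(np.mean(np.abs(a - b)))


@dataclass
class QuantileSelection:
    """Selection outcome for one strip."""

    per_sapling: dict[str, tuple[float, float]]   # sapling_id -> (best tau, distance)
    distance_matrix: pd.DataFrame                  # saplings x taus, mean |curve diff|
    strip_tau_mean: float                          # mean of best taus, on the 0.01 grid
    strip_tau_argmin: float                        # tau minimising the aggregate distance
    frontier_degrees: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_sapling": {k: {"best_tau": v[0], "distance": v[1]}
                            for k, v in self.per_sapling.items()},
            "strip_tau_mean": self.strip_tau_mean,
            "strip_tau_argmin": self.strip_tau_argmin,
            "frontier_degrees": self.frontier_degrees,
        }


def _tau_curves(grid_fits: QuantileGridResult, dbh: float, cr: float,
                grid: np.ndarray) -> dict[float, np.ndarray]:
    """Quantile curves at one sapling's covariates, clamped at zero radius."""
    out = {}
    for tau in grid_fits.taus:
        if tau not in grid_fits.fits:
            continue
        c = np.asarray(eval_profile(grid_fits.fits[tau].params, dbh=dbh, cr=cr,
                                    rdinc=grid))
        out[tau] = np.clip(c, 0.0, None)
    return out


def select_quantile_per_sapling(dbh: float, cr: float,
                                grid_fits: QuantileGridResult,
                                frontier, grid: np.ndarray | None = None
                                ) -> tuple[float, float]:
    """Best (tau, distance) for one sapling against its boundary curve.

    ``frontier`` is a :class:`FrontierFit` or a precomputed curve on the
    grid.  Ties break toward the larger tau (the outermost curve).
    """
    grid = rdinc_grid() if grid is None else np.asarray(grid, float)
    target = (eval_frontier(frontier, grid) if isinstance(frontier, FrontierFit)
              else np.asarray(frontier, float))
    target = np.clip(target, 0.0, None)
    curves = _tau_curves(grid_fits, dbh, cr, grid)
    if not curves:
        raise ValueError("no fitted quantile curves available")
    best_tau, best_d = None, np.inf
    for tau, curve in curves.items():
        d = curve_distance(curve, target)
        if d < best_d or (d == best_d and best_tau is not None and tau > best_tau):
            best_tau, best_d = tau, d
    return best_tau, best_d


def strip_level_quantile(selections: dict[str, tuple[float, float]],
                         distance_matrix: pd.DataFrame | None = None
                         ) -> tuple[float, float | None]:
    """Strip summaries: mean of per-sapling taus (rounded to the 0.01 grid),
    and the aggregate-distance argmin tau when a distance matrix is given."""
    if not selections:
        raise ValueError("no per-sapling selections")
    taus = np.array([v[0] for v in selections.values()])
    tau_mean = float(np.round(np.mean(taus), 2))
    tau_argmin = None
    if distance_matrix is not None and len(distance_matrix.columns):
        col_means = distance_matrix.mean(axis=0)
        best = col_means.min()
        # ties toward the larger tau
        tau_argmin = float(max(c for c in distance_matrix.columns
                               if col_means[c] <= best + 1e-15))
    return tau_mean, tau_argmin


def run_selection(dataset: Dataset, grid_fits: QuantileGridResult,
                  strip: str | StripType, max_degree: int = 6,
                  min_branches: int = 4) -> QuantileSelection:
    """Full selection for one strip.

    Per sapling: fit an information-criterion-selected polynomial boundary
    to its own branch tips (rdinc, ocr), evaluate every quantile curve at
    the sapling's DBH/CR on the fine grid, and take the closest quantile.
    Saplings with fewer than ``min_branches`` measured branches are skipped
    (a boundary through 2-3 points is not informative).
    """
    ds = dataset.subset(strip)
    grid = rdinc_grid()
    per_sapling: dict[str, tuple[float, float]] = {}
    degrees: dict[str, int] = {}
    rows = {}
    for _, sap in ds.saplings.iterrows():
        sid = sap["sapling_id"]
        brs = ds.branches[ds.branches["sapling_id"] == sid]
        if len(brs) < min_branches:
            continue
        x = brs["rdinc"].to_numpy(float)
        y = brs["ocr_m"].to_numpy(float)
        front = select_degree(x, y, max_degree=max_degree)
        degrees[sid] = front.degree
        target = np.clip(eval_frontier(front, grid), 0.0, None)
        cr = float(sap["cl_m"] / sap["ht_m"])
        curves = _tau_curves(grid_fits, float(sap["dbh_cm"]), cr, grid)
        dists = {tau: curve_distance(c, target) for tau, c in curves.items()}
        rows[sid] = dists
        best = min(dists.values())
        best_tau = max(t for t, d in dists.items() if d <= best + 1e-15)
        per_sapling[sid] = (best_tau, dists[best_tau])
    if not per_sapling:
        raise ValueError(f"no sapling in strip {strip!r} had enough branches")
    dm = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
    tau_mean, tau_argmin = strip_level_quantile(per_sapling, dm)
    return QuantileSelection(per_sapling=per_sapling, distance_matrix=dm,
                             strip_tau_mean=tau_mean, strip_tau_argmin=tau_argmin,
                             frontier_degrees=degrees)
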