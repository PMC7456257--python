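"""Nonlinear least-squares fitting of crown-profile forms and fit statistics.

Goodness of fit follows the forestry-biometrics conventions used with these
models: ``R2 = 1 - SSE/SST`` (SST about the mean of the observations),
``R2_adj = 1 - (1 - R2)(n - 1)/(n - p)``, and ``RMSE = sqrt(SSE/(n - 1))``
with ``n`` the total branch count.  Note the RMSE denominator is ``n - 1``,
not ``n - p`` — an intentional divergence from the common definition, kept
for comparability with published crown-profile fit tables.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .models import FORMS, ProfileDomainError, ProfileParams

__all__ = ["FitResult", "fit_ols", "r_squared", "r2_adjusted", "rmse",
           "compare_models", "UnderdeterminedError", "NonConvergenceError"]


class UnderdeterminedError(ValueError):
    pass


class NonConvergenceError(RuntimeError):
    def __init__(self, msg, best=None):
        super().__init__(msg)
        self.best = best


@dataclass
class FitResult:
    """One fitted crown-profile model with its diagnostics."""

    params: ProfileParams
    r2: float
    r2_adj: float
    rmse: float
    n_obs: int
    n_params: int
    converged: bool
    loss_value: float
    residuals: np.ndarray = field(repr=False)
    data_key: str = ""   # fingerprint of the fitted observations
    tau: float | None = None  # set for quantile fits

    def to_dict(self) -> dict:
        return {
            "form": self.params.form,
            "coefficients": list(self.params.coefficients),
            "tau": self.tau,
            "r2": self.r2, "r2_adj": self.r2_adj, "rmse": self.rmse,
            "n_obs": self.n_obs, "n_params": self.n_params,
            "converged": self.converged, "loss_value": self.loss_value,
        }


def data_fingerprint(y: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(np.asarray(y, float)).tobytes()).hexdigest()[:16]


def r_squared(obs, pred) -> float:
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        raise ValueError("zero total sum of squares: R^2 undefined")
    sse = float(np.sum((obs - pred) ** 2))
    return 1.0 - sse / sst


def r2_adjusted(obs, pred, n_params: int) -> float:
    """Adjusted R^2 with the (n-1)/(n-p) penalty."""
    obs = np.asarray(obs, float)
    n = obs.size
    if n < n_params + 1:
        raise ValueError("need at least n_params + 1 observations")
    r2 = r_squared(obs, pred)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params)


def rmse(obs, pred) -> float:
    """Root mean square error with denominator n - 1."""
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    if obs.size < 2:
        raise ValueError("rmse needs at least 2 observations")
    return float(np.sqrt(np.sum((obs - pred) ** 2) / (obs.size - 1)))


# ---------------------------------------------------------------------------

def default_init(form: str, y: np.ndarray) -> np.ndarray:
    """Starting coefficients; signs follow the fitted-table pattern for the
    power-exponential forms (a1>0, a4<0, a5<0)."""
    ybar = float(np.mean(y)) if len(y) else 0.3
    return {
        "power_exp_basic": np.array([max(ybar, 1e-3), 0.5, -1.0]),
        "power_exp_full": np.array([max(ybar, 1e-3), 0.5, 1.0, -0.5, -1.0]),
        "kozak_basic": np.array([max(ybar, 1e-3), 1.0, 0.7]),
        "kozak_mod": np.array([max(ybar, 1e-3), 0.5, 0.5, 0.5, 1.0]),
    }[form]


def _bounds(form: str):
    inf = np.inf
    if form == "power_exp_basic":
        return ([1e-8, -inf, -inf], [inf, inf, inf])
    if form == "power_exp_full":
        return ([1e-8, -inf, -inf, -inf, -inf], [inf, inf, inf, inf, inf])
    if form == "kozak_basic":
        return ([1e-8, -inf, 1e-6], [inf, inf, 1 - 1e-6])
    if form == "kozak_mod":
        # keep c3*CR**c4 inside (0,1) for CR in (0,1]: c3 in (0,1), c4 >= 0
        return ([1e-8, -inf, 1e-6, 0.0, -inf], [inf, inf, 1 - 1e-6, inf, inf])
    raise ValueError(form)


def _predict(form: str, theta: np.ndarray, frame: pd.DataFrame) -> np.ndarray:
    """Vectorised model prediction over a regression frame.

    Evaluates the form directly on the per-branch covariate arrays; kept
    consistent with :func:`saplingcrown.models.eval_profile` (property-tested).
    """
    from .models import _safe_pow
    t = frame["rdinc"].to_numpy(float)
    if form == "power_exp_basic":
        a1, a2, a3 = theta
        return a1 * _safe_pow(t, a2) * np.exp(a3 * t)
    if form == "kozak_basic":
        c1, c2, p = theta
        if not 0.0 < p < 1.0:
            raise ProfileDomainError(f"kozak_basic inflection p={p} outside (0, 1)")
        x = (1.0 - np.sqrt(1.0 - t)) / (1.0 - np.sqrt(p))
        return c1 * _safe_pow(x, c2)
    dbh = frame["dbh_cm"].to_numpy(float)
    cr = frame["cr"].to_numpy(float)
    if form == "power_exp_full":
        a1, a2, a3, a4, a5 = theta
        return a1 * np.power(dbh, a2) * _safe_pow(t, a3 + a4 * cr) * np.exp(a5 * t)
    if form == "kozak_mod":
        c1, c2, c3, c4, c5 = theta
        s = c3 * np.power(cr, c4)
        if np.any((s <= 0.0) | (s >= 1.0)):
            raise ProfileDomainError("kozak_mod base term c3*CR**c4 outside (0, 1)")
        base = (1.0 - np.sqrt(1.0 - t)) / (1.0 - np.sqrt(s))
        return c1 * np.power(dbh, c2) * _safe_pow(base, c5 * (1.0 - t))
    raise ValueError(form)


def predict_profile(form: str, theta, frame: pd.DataFrame) -> np.ndarray:
    """Model prediction for each row of a regression frame
    (columns dbh_cm, cr, rdinc)."""
    return _predict(form, np.asarray(theta, float), frame)


def fit_ols(form: str, frame: pd.DataFrame, init=None, n_starts: int = 20,
            seed: int = 0, xtol: float = 1e-12, gtol: float = 1e-10) -> FitResult:
    """Fit a profile form by nonlinear least squares with multi-start.

    ``frame`` is a regression frame from :func:`saplingcrown.io.model_frame`
    (the candidate-model protocol passes the largest branch per whorl).
    Starts are the default (or given) init plus ``n_starts`` multiplicative
    U(0.5, 2) perturbations of it, seed-controlled; the best converged start
    wins.
    """
    if form not in FORMS:
        raise ValueError(f"unknown form {form!r}")
    y = frame["ocr_m"].to_numpy(float)
    p = FORMS[form]
    if len(y) < p + 1:
        raise UnderdeterminedError(f"{len(y)} observations cannot identify {p} parameters")
    x0 = np.asarray(init, float) if init is not None else default_init(form, y)
    lo, hi = _bounds(form)
    x0 = np.clip(x0, np.asarray(lo) + 1e-9, np.asarray(hi) - 1e-9 if np.all(np.isfinite(hi)) else np.asarray(hi))
    rng = np.random.default_rng(seed)
    starts = [x0] + [x0 * rng.uniform(0.5, 2.0, size=p) for _ in range(n_starts)]

    def resid(theta):
        try:
            pred = _predict(form, theta, frame)
        except (ProfileDomainError, FloatingPointError):
            return np.full(len(y), 1e6)
        return np.nan_to_num(pred - y, nan=1e6, posinf=1e6, neginf=-1e6)

    best = None
    for s in starts:
        s = np.clip(s, lo, hi)
        try:
            sol = least_squares(resid, s, bounds=(lo, hi), xtol=xtol, gtol=gtol, ftol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise NonConvergenceError(f"all {len(starts)} starts failed for {form}")
    theta = best.x
    pred = _predict(form, theta, frame)
    res = y - pred
    return FitResult(
        params=ProfileParams(form=form, coefficients=tuple(theta)),
        r2=r_squared(y, pred), r2_adj=r2_adjusted(y, pred, p), rmse=rmse(y, pred),
        n_obs=len(y), n_params=p, converged=bool(best.status > 0),
        loss_value=float(np.sum(res ** 2)), residuals=res,
        data_key=data_fingerprint(y))


def compare_models(fits: list[FitResult]) -> list[FitResult]:
    """Rank fits of the same data: largest adjusted R^2 first, ties broken
    by smaller RMSE."""
    if not fits:
        return []
    keys = {f.data_key for f in fits}
    if len(keys) > 1:
        raise ValueError("fits were computed on different datasets; ranking is meaningless")
    return sorted(fits, key=lambda f: (-f.r2_adj, f.rmse))
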