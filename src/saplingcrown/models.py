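"""Crown-profile model forms and derived crown metrics.

The crown of a conifer sapling is described by the outer crown radius (OCR,
metres) as a function of the relative depth into the crown (RDINC, 0 at the
tree tip, 1 at the crown base).  Four parametric forms are supported:

``power_exp_basic``
    ``OCR = a1 * RDINC**a2 * exp(a3 * RDINC)`` — three parameters.
``kozak_basic``
    ``OCR = c1 * X**c2`` with ``X = (1 - sqrt(1 - RDINC)) / (1 - sqrt(p))``,
    a variable-exponent taper-type base with inflection parameter ``p`` —
    three parameters ``(c1, c2, p)``.
``power_exp_full``
    ``OCR = a1 * DBH**a2 * RDINC**(a3 + a4*CR) * exp(a5 * RDINC)`` — the
    power-exponential form reparameterised with diameter at breast height
    (DBH, cm) and crown ratio (CR = crown length / total height) — five
    parameters.
``kozak_mod``
    ``OCR = c1 * DBH**c2 * B**(c5*(1 - RDINC))`` with
    ``B = (1 - sqrt(1 - RDINC)) / (1 - sqrt(c3 * CR**c4))`` — five
    parameters.  At ``RDINC = 1`` the exponent is 0 and the value is the
    limit ``c1 * DBH**c2``.

The ``power_exp_full`` profile has a closed-form depth of maximum radius
(the "inflection point" in crown-morphology usage): setting the derivative
``A * t**(b-1) * exp(c*t) * (b + c*t)`` to zero gives ``t* = -b/c`` with
``b = a3 + a4*CR`` and ``c = a5``; for ``a5 < 0`` and ``b > 0`` this is the
unique interior argmax, capped at the crown base ``t* = 1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Callable

import numpy as np
from scipy.integrate import simpson

__all__ = [
    "FORMS",
    "ProfileParams",
    "CrownMetrics",
    "eval_profile",
    "inflection_point",
    "is_monotone",
    "largest_crown_radius",
    "crown_volume",
    "crown_metrics",
    "load_reference_params",
    "ProfileDomainError",
]


class ProfileDomainError(ValueError):
    """Model evaluated outside its mathematical domain."""


#: form name -> number of coefficients
FORMS: dict[str, int] = {
    "power_exp_basic": 3,
    "kozak_basic": 3,
    "power_exp_full": 5,
    "kozak_mod": 5,
}


@dataclass(frozen=True)
class ProfileParams:
    """A crown-profile model form plus its coefficient vector.

    Coefficient order follows the form definitions in the module docstring:
    ``power_exp_basic``: (a1, a2, a3); ``kozak_basic``: (c1, c2, p);
    ``power_exp_full``: (a1, a2, a3, a4, a5); ``kozak_mod``: (c1..c5).
    """

    form: str
    coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown model form {self.form!r}")
        if len(self.coefficients) != FORMS[self.form]:
            raise ValueError(
                f"{self.form} takes {FORMS[self.form]} coefficients, "
                f"got {len(self.coefficients)}"
            )
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))

    def to_json(self) -> str:
        return json.dumps({"form": self.form, "coefficients": list(self.coefficients)})

    @classmethod
    def from_json(cls, text: str) -> "ProfileParams":
        obj = json.loads(text)
        return cls(form=obj["form"], coefficients=tuple(obj["coefficients"]))


@dataclass(frozen=True)
class CrownMetrics:
    """Derived crown morphology summary for one (DBH, CR, CL) setting."""

    inflection_rdinc: float  # relative depth of the largest radius
    largest_radius: float    # m
    upper_volume: float      # m^3, rotational integral over the upper crown


def eval_profile(params: ProfileParams, dbh=None, cr=None, rdinc=None):
    """Evaluate the crown radius (m) at one or many relative depths.

    ``dbh`` (cm) and ``cr`` are ignored by the basic forms.  ``rdinc`` may
    be a scalar or array in [0, 1]; the return matches its shape.
    """
    t = np.asarray(rdinc, dtype=float)
    if np.any((t < 0) | (t > 1)):
        raise ProfileDomainError("rdinc must lie in [0, 1]")
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    c = params.coefficients

    if params.form == "power_exp_basic":
        a1, a2, a3 = c
        out = a1 * _safe_pow(t, a2) * np.exp(a3 * t)
    elif params.form == "power_exp_full":
        a1, a2, a3, a4, a5 = c
        _need(dbh is not None and cr is not None, "power_exp_full needs dbh and cr")
        b = a3 + a4 * float(cr)
        out = a1 * float(dbh) ** a2 * _safe_pow(t, b) * np.exp(a5 * t)
    elif params.form == "kozak_basic":
        c1, c2, p = c
        if not 0.0 < p < 1.0:
            raise ProfileDomainError(f"kozak_basic inflection p={p} outside (0, 1)")
        x = (1.0 - np.sqrt(1.0 - t)) / (1.0 - np.sqrt(p))
        out = c1 * _safe_pow(x, c2)
    elif params.form == "kozak_mod":
        c1, c2, c3, c4, c5 = c
        _need(dbh is not None and cr is not None, "kozak_mod needs dbh and cr")
        s = c3 * float(cr) ** c4
        if not 0.0 < s < 1.0:
            raise ProfileDomainError(f"kozak_mod base term c3*CR**c4={s} outside (0, 1)")
        base = (1.0 - np.sqrt(1.0 - t)) / (1.0 - np.sqrt(s))
        out = c1 * float(dbh) ** c2 * _safe_pow(base, c5 * (1.0 - t))
    else:  # pragma: no cover - guarded by ProfileParams
        raise ValueError(params.form)

    return float(out[0]) if scalar else out


def _need(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def _safe_pow(base: np.ndarray, expo) -> np.ndarray:
    """``base**expo`` with the 0**0 -> 1 and 0**positive -> 0 conventions.

    ``expo`` may be a scalar or an array broadcastable with ``base``.
    0 raised to a negative power raises a domain error (profile diverges).
    """
    b = np.asarray(base, dtype=float)
    e = np.broadcast_to(np.asarray(expo, dtype=float), b.shape)
    zero = b == 0.0
    if np.any(zero & (e < 0)):
        raise ProfileDomainError("profile diverges: 0 raised to a negative exponent")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.power(b, e)
    out = np.where(zero & (e > 0), 0.0, out)
    out = np.where(zero & (e == 0), 1.0, out)
    return out


def inflection_point(params: ProfileParams, cr: float | None = None) -> float:
    """Relative depth of the maximum crown radius (closed form).

    For ``power_exp_full``: ``t* = min(1, (a3 + a4*cr) / (-a5))``; for
    ``power_exp_basic``: ``t* = min(1, a2 / (-a3))``; for ``kozak_basic``
    the inflection is the parameter ``p`` itself.  A profile with a
    nonnegative exponential rate has no interior maximum and returns 1.0
    (monotone up to the crown base); see :func:`is_monotone`.
    """
    c = params.coefficients
    if params.form == "power_exp_full":
        _need(cr is not None, "power_exp_full inflection needs cr")
        b, rate = c[2] + c[3] * float(cr), c[4]
    elif params.form == "power_exp_basic":
        b, rate = c[1], c[2]
    elif params.form == "kozak_basic":
        return float(c[2])
    else:
        raise ValueError(f"no closed-form inflection for form {params.form!r}")
    if b <= 0:
        raise ProfileDomainError(f"rdinc exponent {b} <= 0: profile has no interior maximum")
    if rate >= 0:
        return 1.0  # monotone: maximum at the crown base
    return float(min(1.0, b / (-rate)))


def is_monotone(params: ProfileParams, cr: float | None = None) -> bool:
    """True when the profile increases all the way to the crown base."""
    if params.form == "power_exp_full":
        b, rate = params.coefficients[2] + params.coefficients[3] * float(cr), params.coefficients[4]
    elif params.form == "power_exp_basic":
        b, rate = params.coefficients[1], params.coefficients[2]
    else:
        raise ValueError(f"monotonicity check not defined for form {params.form!r}")
    return rate >= 0 or b / (-rate) >= 1.0


def largest_crown_radius(params: ProfileParams, dbh: float | None = None,
                         cr: float | None = None) -> float:
    """Largest crown radius (m): the profile evaluated at its argmax depth."""
    t_star = inflection_point(params, cr)
    return float(eval_profile(params, dbh=dbh, cr=cr, rdinc=t_star))


def crown_volume(radius_fn: Callable[[np.ndarray], np.ndarray], cl: float,
                 region: tuple[float, float] = (0.0, 1.0), n: int = 2001) -> float:
    """Crown volume (m^3) as a solid of revolution of the profile curve.

    ``V = pi * cl * integral of r(t)**2 dt`` over ``region`` (a sub-interval
    of [0, 1] in relative depth), by composite Simpson quadrature on ``n``
    points (``n >= 2001`` recommended; odd n gives the classical rule).
    An empty or degenerate region yields 0.
    """
    a, b = float(region[0]), float(region[1])
    if b <= a:
        return 0.0
    t = np.linspace(a, b, int(n))
    r = np.asarray(radius_fn(t), dtype=float)
    if np.any(r < -1e-12):
        raise ValueError("radius function must be nonnegative on the region")
    return float(np.pi * cl * simpson(np.clip(r, 0.0, None) ** 2, x=t))


def crown_metrics(params: ProfileParams, dbh: float, cr: float, cl: float,
                  region: tuple[float, float] | None = None, n: int = 2001) -> CrownMetrics:
    """Inflection depth, largest radius and upper-crown volume in one call.

    The "upper crown" defaults to the region from the tip to the inflection
    depth; pass ``region`` to override.
    """
    t_star = inflection_point(params, cr)
    radius = float(eval_profile(params, dbh=dbh, cr=cr, rdinc=t_star))
    reg = (0.0, t_star) if region is None else region
    vol = crown_volume(lambda t: eval_profile(params, dbh=dbh, cr=cr, rdinc=t), cl, reg, n=n)
    return CrownMetrics(inflection_rdinc=t_star, largest_radius=radius, upper_volume=vol)


def load_reference_params() -> dict:
    """Published power-exponential coefficient estimates for naturally
    regenerated Chinese pine (Pinus tabuliformis) saplings.

    Returns a dict with per-strip OLS and quantile-regression coefficient
    rows (``ProfileParams`` values), the selected outermost quantile per
    strip (0.88 shelterwood-cut, 0.92 uncut), and the reference evaluation
    settings (CR = 0.80, DBH = 2.0 cm).
    """
    text = resources.files("saplingcrown.data").joinpath("reference_params.json").read_text()
    raw = json.loads(text)
    out = {"crown_ratio_reference": raw["crown_ratio_reference"],
           "dbh_reference_cm": raw["dbh_reference_cm"], "strips": {}}
    for strip, rows in raw["strips"].items():
        out["strips"][strip] = {
            "selected": rows["selected"],
            "fits": {label: ProfileParams(form=raw["form"], coefficients=tuple(v))
                     for label, v in rows["fits"].items()},
        }
    return out


def grid_argmax_radius(params: ProfileParams, dbh: float | None, cr: float | None,
                       n: int = 10_001) -> tuple[float, float]:
    """Brute-force (rdinc*, radius*) over an ``n``-point grid on [0, 1].

    Slower cross-check for :func:`inflection_point` /
    :func:`largest_crown_radius`; useful for audits.
    """
    t = np.linspace(0.0, 1.0, int(n))
    r = np.asarray(eval_profile(params, dbh=dbh, cr=cr, rdinc=t))
    k = int(np.argmax(r))
    return float(t[k]), float(r[k])
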