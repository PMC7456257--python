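"""Synthetic sapling stands with a known outermost crown envelope.

The generator emulates the measurement structure of a destructive branch
analysis of naturally regenerated conifer saplings in two treatment strips
(shelterwood-cut vs uncut).  Per sapling, DBH and height come from
truncated normals matching the field sample moments (DBH in (0.5, 5) cm,
HT > 1.3 m — the sampling criteria); crown length is CR x HT with CR from a
truncated normal on (0, 1].  Whorls sit at a fixed vertical spacing from
the crown base to the tip, each carrying a few branches.

Branch radii follow a one-sided envelope-noise model: each strip has a
*true* outermost profile (a power-exponential crown-profile model), and an
observed branch radius is the envelope radius at the branch's relative
depth multiplied by a Beta(alpha, beta) depletion factor ``u`` on (0, 1] —
every observation lies on or below the envelope, with ``alpha`` and
``beta`` controlling how densely the cloud hugs the boundary.  Chord length
and the tip-to-base distance are then back-solved so that the geometric
derivation (``ocr = bc sin(va)``, ``dinc = l - bc cos(va)``) reproduces the
drawn (rdinc, ocr) exactly.

Annual branch-length growth series emulate a strip-cut experiment: equal
growth-rate means across strips before the treatment year, strip-specific
means after it (the shade-grown strip pulling ahead first, the released
strip overtaking later).

Within-crown depletion is an assumption, not a field estimate: the Beta
family is the simplest one-sided multiplicative noise on (0, 1] and its
shape parameters are configuration, not constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .io import Dataset, StripType, _derive_frame
from .models import ProfileParams, eval_profile

__all__ = ["StripStandConfig", "StandConfig", "GrowthConfig",
           "generate_stand", "generate_growth_series",
           "stand_config_from_yaml", "stand_config_to_yaml"]

CUT = StripType.SHELTERWOOD_CUT.value
UNCUT = StripType.UNCUT.value

#: published selected-quantile coefficient rows, used as the generative truth
_DEFAULT_ENVELOPES = {
    CUT: ProfileParams("power_exp_full", (0.4030, 0.4751, 1.1811, -0.5538, -0.9125)),
    UNCUT: ProfileParams("power_exp_full", (1.2834, 0.3950, 1.2543, -0.1097, -1.8092)),
}


@dataclass(frozen=True)
class StripStandConfig:
    """Moments and envelope truth for one strip's saplings (field units)."""

    n_saplings: int
    dbh_mean: float   # cm
    dbh_sd: float
    ht_mean: float    # m
    ht_sd: float
    cr_mean: float    # dimensionless, (0, 1]
    cr_sd: float
    va_mean: float    # degrees
    va_sd: float
    envelope: ProfileParams

    def __post_init__(self) -> None:
        if min(self.dbh_sd, self.ht_sd, self.cr_sd, self.va_sd) < 0:
            raise ValueError("standard deviations must be nonnegative")
        if not 0 < self.cr_mean <= 1:
            raise ValueError("cr_mean must lie in (0, 1]")


@dataclass(frozen=True)
class StandConfig:
    """Full stand configuration; defaults mirror the field sample
    (49 shelterwood-cut and 30 uncut saplings and their Table-of-moments
    DBH/HT/CL/VA statistics)."""

    strips: dict[str, StripStandConfig] = field(default_factory=lambda: {
        CUT: StripStandConfig(49, 2.46, 0.99, 2.40, 0.59, 0.77, 0.08,
                              62.0, 17.0, _DEFAULT_ENVELOPES[CUT]),
        UNCUT: StripStandConfig(30, 1.36, 0.54, 2.18, 0.49, 0.74, 0.08,
                                73.0, 14.0, _DEFAULT_ENVELOPES[UNCUT]),
    })
    whorl_spacing: float = 0.20          # m between successive whorls
    branches_per_whorl: tuple[int, int] = (2, 4)
    noise_alpha: float = 4.0             # Beta depletion shape (towards 1)
    noise_beta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_alpha <= 0 or self.noise_beta <= 0:
            raise ValueError("Beta shapes must be positive")
        if self.whorl_spacing <= 0:
            raise ValueError("whorl_spacing must be positive")
        lo, hi = self.branches_per_whorl
        if not 1 <= lo <= hi:
            raise ValueError("branches_per_whorl must be a nondecreasing positive range")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Draw by rejection; exact truncation, deterministic under rng."""
    if sd == 0:
        vals = np.full(size, float(mean))
        if np.any((vals <= lo) | (vals >= hi)):
            raise ValueError("degenerate mean outside truncation bounds")
        return vals
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        draw = draw[(draw > lo) & (draw < hi)]
        take = min(len(draw), size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def _check_envelope(envelope: ProfileParams) -> None:
    t = np.linspace(0.0, 1.0, 201)
    r = np.asarray(eval_profile(envelope, dbh=2.0, cr=0.8, rdinc=t))
    if np.any(r < 0) or not np.all(np.isfinite(r)):
        raise ValueError("envelope parameters yield negative or non-finite radii on [0, 1]")


def generate_stand(config: StandConfig) -> Dataset:
    """Generate a two-strip stand dataset with known envelope truth.

    Identical config (including seed) gives an identical dataset.  Every
    observed radius satisfies ``ocr <= envelope radius``; the derived
    geometry round-trips the drawn (rdinc, ocr) exactly.
    """
    rng = np.random.default_rng(config.seed)
    sap_rows, br_rows = [], []
    lo_b, hi_b = config.branches_per_whorl
    for strip in sorted(config.strips):
        sc = config.strips[strip]
        _check_envelope(sc.envelope)
        if sc.n_saplings == 0:
            continue
        dbh = _truncated_normal(rng, sc.dbh_mean, sc.dbh_sd, 0.5, 5.0, sc.n_saplings)
        ht = _truncated_normal(rng, sc.ht_mean, sc.ht_sd, 1.3, np.inf, sc.n_saplings)
        cr = _truncated_normal(rng, sc.cr_mean, sc.cr_sd, 1e-3, 1.0, sc.n_saplings)
        cl = cr * ht
        for i in range(sc.n_saplings):
            sid = f"{strip}_{i + 1:03d}"
            sap_rows.append({"sapling_id": sid, "strip_type": strip,
                             "dbh_cm": dbh[i], "ht_m": ht[i], "cl_m": cl[i],
                             "excluded_flag": 0})
            # whorls from just below the tip down to the crown base
            n_whorls = max(1, int(np.floor(cl[i] / config.whorl_spacing)))
            dincs = np.arange(1, n_whorls + 1) * config.whorl_spacing
            dincs = np.minimum(dincs, cl[i])
            for w, dinc in enumerate(dincs, start=1):
                rdinc = dinc / cl[i]
                nb = int(rng.integers(lo_b, hi_b + 1))
                r_env = float(eval_profile(sc.envelope, dbh=dbh[i], cr=cr[i],
                                           rdinc=rdinc))
                u = rng.beta(config.noise_alpha, config.noise_beta, size=nb)
                ocr = np.maximum(r_env * u, 1e-4)  # metres; keep chords positive
                va = _truncated_normal(rng, sc.va_mean, sc.va_sd, 5.0, 160.0, nb)
                va_rad = np.radians(va)
                bc_m = ocr / np.sin(va_rad)
                l = rdinc * cl[i] + bc_m * np.cos(va_rad)
                # drooping branches near the tip could imply l < 0; mirroring
                # the insertion angle keeps ocr (sin) and flips the projection
                flip = l < 0
                va = np.where(flip, 180.0 - va, va)
                va_rad = np.radians(va)
                l = rdinc * cl[i] + bc_m * np.cos(va_rad)
                bl_cm = bc_m * 100.0 * rng.uniform(1.0, 1.1, size=nb)
                bd = np.clip(1.3 + 18.0 * ocr + rng.normal(0, 1.2, size=nb), 0.5, None)
                az = rng.uniform(0.0, 360.0, size=nb)
                for j in range(nb):
                    br_rows.append({
                        "sapling_id": sid, "whorl_index": w, "l_m": l[j],
                        "bl_cm": bl_cm[j], "bc_cm": bc_m[j] * 100.0,
                        "va_deg": va[j], "bd_mm": bd[j], "azimuth_deg": az[j],
                    })
    saplings = pd.DataFrame(sap_rows, columns=["sapling_id", "strip_type", "dbh_cm",
                                               "ht_m", "cl_m", "excluded_flag"])
    branches = pd.DataFrame(br_rows, columns=["sapling_id", "whorl_index", "l_m",
                                              "bl_cm", "bc_cm", "va_deg", "bd_mm",
                                              "azimuth_deg"])
    if len(branches):
        branches = _derive_frame(branches, saplings)
    else:
        for c in ("dinc_m", "rdinc", "ocr_m"):
            branches[c] = pd.Series(dtype=float)
    return Dataset(saplings=saplings, branches=branches,
                   provenance=f"generate_stand(seed={config.seed})")


@dataclass(frozen=True)
class GrowthConfig:
    """Annual branch-length growth emulation (cm per year).

    Before ``treatment_year`` both strips share ``pre_treatment_rate_mean``;
    from the treatment year on, per-year (cut, uncut) means apply.  The
    default trajectory follows the reported pattern: near-equal growth in
    the year before the strip cut (means 11.2/11.5 averaged to a common
    11.35), the shade-grown (uncut) saplings growing faster in the first
    post-treatment years (12.9 vs 14.0 in the treatment year), and the
    released (cut) saplings overtaking from two years after the cut.
    """

    years: tuple[int, ...] = (2013, 2014, 2015, 2016, 2017)
    pre_treatment_rate_mean: float = 11.35
    post_treatment_rates: dict[int, tuple[float, float]] = field(default_factory=lambda: {
        2014: (12.9, 14.0), 2015: (14.5, 15.8), 2016: (17.5, 15.0),
        2017: (19.5, 15.2)})
    rate_sd: float = 2.5
    treatment_year: int = 2014
    seed: int = 0

    def __post_init__(self) -> None:
        if any(b - a != 1 for a, b in zip(self.years, self.years[1:])):
            raise ValueError("years must be consecutive")
        if self.pre_treatment_rate_mean <= 0:
            raise ValueError("rate means must be positive")
        for y, (mc, mu) in self.post_treatment_rates.items():
            if mc <= 0 or mu <= 0:
                raise ValueError(f"rate means must be positive (year {y})")
        missing = [y for y in self.years if y >= self.treatment_year
                   and y not in self.post_treatment_rates]
        if missing:
            raise ValueError(f"post-treatment years without rates: {missing}")


def generate_growth_series(dataset: Dataset, config: GrowthConfig) -> Dataset:
    """Attach annual branch-length increments to one branch per sapling.

    The sampled branch is the one whose whorl index is closest to 5 (the
    five-year-old sample-branch protocol).  With ``rate_sd = 0`` every
    increment equals its strip-year mean exactly.
    """
    for strip in (CUT, UNCUT):
        if dataset.n_saplings(strip) < 1:
            raise ValueError(f"dataset needs at least one sapling per strip ({strip})")
    rng = np.random.default_rng(config.seed)
    branches = dataset.branches.copy()
    strip_of = dataset.saplings.set_index("sapling_id")["strip_type"]
    for y in config.years:
        branches[f"year_{y}"] = np.nan
    for sid in dataset.saplings["sapling_id"]:
        rows = branches.index[branches["sapling_id"] == sid]
        if not len(rows):
            continue
        whorls = branches.loc[rows, "whorl_index"]
        target = rows[(whorls - 5).abs().to_numpy().argmin()]
        col_strip = 0 if strip_of[sid] == CUT else 1
        for y in config.years:
            if y < config.treatment_year:
                mean = config.pre_treatment_rate_mean
            else:
                mean = config.post_treatment_rates[y][col_strip]
            inc = mean + (config.rate_sd * rng.standard_normal()
                          if config.rate_sd > 0 else 0.0)
            branches.loc[target, f"year_{y}"] = max(inc, 0.0)
    return Dataset(saplings=dataset.saplings, branches=branches,
                   provenance=f"{dataset.provenance} [growth seed={config.seed}]")


# ---------------------------------------------------------------------------
# YAML round-trip for stand configurations

def stand_config_to_yaml(config: StandConfig, path) -> None:
    obj = {
        "whorl_spacing": config.whorl_spacing,
        "branches_per_whorl": list(config.branches_per_whorl),
        "noise_alpha": config.noise_alpha, "noise_beta": config.noise_beta,
        "seed": config.seed,
        "strips": {
            strip: {
                "n_saplings": sc.n_saplings,
                "dbh_mean": sc.dbh_mean, "dbh_sd": sc.dbh_sd,
                "ht_mean": sc.ht_mean, "ht_sd": sc.ht_sd,
                "cr_mean": sc.cr_mean, "cr_sd": sc.cr_sd,
                "va_mean": sc.va_mean, "va_sd": sc.va_sd,
                "envelope": {"form": sc.envelope.form,
                             "coefficients": list(sc.envelope.coefficients)},
            } for strip, sc in config.strips.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def stand_config_from_yaml(path, seed: int | None = None) -> StandConfig:
    with open(path) as fh:
        obj = yaml.safe_load(fh)
    strips = {
        strip: StripStandConfig(
            n_saplings=d["n_saplings"], dbh_mean=d["dbh_mean"], dbh_sd=d["dbh_sd"],
            ht_mean=d["ht_mean"], ht_sd=d["ht_sd"], cr_mean=d["cr_mean"],
            cr_sd=d["cr_sd"], va_mean=d["va_mean"], va_sd=d["va_sd"],
            envelope=ProfileParams(d["envelope"]["form"],
                                   tuple(d["envelope"]["coefficients"])))
        for strip, d in obj["strips"].items()
    }
    cfg = StandConfig(strips=strips, whorl_spacing=obj["whorl_spacing"],
                      branches_per_whorl=tuple(obj["branches_per_whorl"]),
                      noise_alpha=obj["noise_alpha"], noise_beta=obj["noise_beta"],
                      seed=obj.get("seed", 0))
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    return cfg
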