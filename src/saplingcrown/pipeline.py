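"""End-to-end pipeline stages with file handoffs.

Each stage reads its inputs from disk and writes its outputs to disk, so
partial reruns are cheap and each stage is testable in isolation:

``run_simulate``  config.yaml -> saplings.csv + branches.csv
``run_fit``       dataset dir -> params.json (OLS + quantile grid per strip)
``run_select``    dataset dir + params.json -> selection.json (+ distance CSVs)
``run_compare``   selection + params + dataset -> report directory

The analysis drivers and the command-line interface are thin wrappers over
these functions.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__
from .compare import annual_growth_compare, crown_metrics_table, render_report
from .io import StripType, model_frame, read_branch_table, validate_dataset, write_dataset
from .models import ProfileParams
from .ols import fit_ols
from .quantile import crossing_fraction, default_tau_grid, fit_quantile_grid
from .selection import run_selection
from .synthetic import (GrowthConfig, StandConfig, generate_growth_series,
                        generate_stand, stand_config_from_yaml)

STRIPS = [s.value for s in StripType]


def _log(outdir: Path, stage: str, **info) -> None:
    entry = {"stage": stage, "version": __version__, **info}
    with open(outdir / "run.log", "a") as fh:
        fh.write(json.dumps(entry, default=str) + "\n")


def _digest(path: Path) -> str:
    return hashlib.sha1(path.read_bytes()).hexdigest()[:16]


def run_simulate(config_path: str | None, out: str, seed: int,
                 with_growth: bool = True) -> Path:
    """Generate a synthetic stand (and growth series) into ``out``."""
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    if config_path is None:
        from dataclasses import replace
        cfg = replace(StandConfig(), seed=seed)
        cfg_digest = "builtin-default"
    else:
        cfg = stand_config_from_yaml(config_path, seed=seed)
        cfg_digest = _digest(Path(config_path))
    ds = generate_stand(cfg)
    if with_growth:
        ds = generate_growth_series(ds, GrowthConfig(seed=seed + 1))
    write_dataset(ds, outdir)
    _log(outdir, "simulate", seed=seed, config=cfg_digest,
         n_saplings=ds.n_saplings(), n_branches=ds.n_branches())
    return outdir


def run_fit(data_dir: str, out: str, form: str = "power_exp_full",
            taus=None, seed: int = 0, strips=None,
            compare_forms: bool = False) -> Path:
    """Fit OLS and the quantile grid per strip; write ``params.json``."""
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset = read_branch_table(data_dir)
    dataset, _ = validate_dataset(dataset, policy="clip")
    taus = default_tau_grid() if taus is None else tuple(taus)
    result = {"form": form, "taus": list(taus), "strips": {}}
    for strip in (strips or STRIPS):
        frame_all = model_frame(dataset, strip=strip)
        frame_lbw = model_frame(dataset, strip=strip, largest_per_whorl=True)
        ols = fit_ols(form, frame_lbw, seed=seed)
        grid = fit_quantile_grid(form, frame_all, taus=taus, seed=seed)
        entry = {"ols": ols.to_dict(), "quantiles": grid.to_dict(),
                 "crossing_fraction": crossing_fraction(
                     grid, dbh=float(frame_all["dbh_cm"].mean()),
                     cr=float(frame_all["cr"].mean()))}
        if compare_forms:
            from .ols import compare_models
            fits = []
            for f in ("power_exp_full", "kozak_mod"):
                try:
                    fits.append(fit_ols(f, frame_lbw, seed=seed))
                except Exception:
                    continue
            entry["candidate_ranking"] = [f.to_dict() for f in compare_models(fits)]
        result["strips"][strip] = entry
    path = outdir / "params.json"
    path.write_text(json.dumps(result, indent=2))
    _log(outdir, "fit", seed=seed, data=_digest(Path(data_dir) / "branches.csv"),
         form=form, n_taus=len(taus))
    return path


def _load_grid(params_path: Path, strip: str):
    from .ols import FitResult, data_fingerprint
    from .quantile import QuantileGridResult
    obj = json.loads(Path(params_path).read_text())
    entry = obj["strips"][strip]["quantiles"]
    fits = {}
    for key, fd in entry["fits"].items():
        tau = float(key)
        fits[tau] = FitResult(
            params=ProfileParams(fd["form"], tuple(fd["coefficients"])),
            r2=fd["r2"], r2_adj=fd["r2_adj"], rmse=fd["rmse"],
            n_obs=fd["n_obs"], n_params=fd["n_params"],
            converged=fd["converged"], loss_value=fd["loss_value"],
            residuals=np.empty(0), tau=tau)
    return QuantileGridResult(taus=tuple(entry["taus"]), fits=fits), obj


def run_select(data_dir: str, params_path: str, out: str,
               max_degree: int = 6, strips=None) -> Path:
    """Boundary-based quantile selection per strip; write ``selection.json``."""
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    params_path = Path(params_path)
    if not params_path.exists():
        raise FileNotFoundError(
            f"{params_path} not found: run the 'fit' stage first")
    dataset = read_branch_table(data_dir)
    dataset, _ = validate_dataset(dataset, policy="clip")
    result = {}
    for strip in (strips or STRIPS):
        grid, _ = _load_grid(params_path, strip)
        sel = run_selection(dataset, grid, strip, max_degree=max_degree)
        result[strip] = sel.to_dict()
        sel.distance_matrix.to_csv(outdir / f"distances_{strip}.csv",
                                   float_format="%.8g")
    path = outdir / "selection.json"
    path.write_text(json.dumps(result, indent=2))
    _log(outdir, "select", params=_digest(params_path), max_degree=max_degree)
    return path


def run_compare(data_dir: str, params_path: str, selection_path: str, out: str,
                cr: float = 0.80, cl: float = 1.7, dbh_grid=None) -> Path:
    """Morphology metrics, growth tests and the final report directory."""
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    for p, stage in ((Path(params_path), "fit"), (Path(selection_path), "select")):
        if not p.exists():
            raise FileNotFoundError(f"{p} not found: run the '{stage}' stage first")
    params_obj = json.loads(Path(params_path).read_text())
    selection_obj = json.loads(Path(selection_path).read_text())
    params_by_strip = {}
    for strip in STRIPS:
        tau = selection_obj[strip]["strip_tau_argmin"] or \
            selection_obj[strip]["strip_tau_mean"]
        key = f"{float(tau):.2f}"
        fd = params_obj["strips"][strip]["quantiles"]["fits"][key]
        params_by_strip[strip] = ProfileParams(fd["form"], tuple(fd["coefficients"]))
    metrics = crown_metrics_table(params_by_strip, dbh_grid=dbh_grid, cr=cr, cl=cl)
    dataset = read_branch_table(data_dir)
    try:
        growth = annual_growth_compare(dataset)
    except ValueError:
        growth = None
    render_report(outdir, metrics=metrics, growth=growth,
                  selection=selection_obj,
                  params={s: {"form": p.form, "coefficients": list(p.coefficients)}
                          for s, p in params_by_strip.items()},
                  metadata={"cr": cr, "cl": cl})
    _log(outdir, "compare", cr=cr, cl=cl)
    return outdir
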