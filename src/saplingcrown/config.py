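"""Run configuration for the end-to-end pipeline.

A :class:`RunConfig` collects everything a full analysis run needs — input
locations (or a synthetic stand config), the quantile grid, the frontier
search depth, the evaluation settings and the seed — and can be loaded
from YAML with keyword overrides (overrides win, mirroring CLI flags).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .quantile import default_tau_grid

__all__ = ["RunConfig", "load_run_config"]


@dataclass(frozen=True)
class RunConfig:
    outdir: str = "results"
    data_dir: str | None = None          # existing dataset; None -> simulate
    stand_config: str | None = None      # YAML for the synthetic generator
    strips: tuple[str, ...] | None = None  # None -> both
    form: str = "power_exp_full"
    taus: tuple[float, ...] = field(default_factory=default_tau_grid)
    max_frontier_degree: int = 6
    cr_eval: float = 0.80                # crown ratio for morphology tables
    cl_eval: float = 1.7                 # crown length (m) for volumes
    dbh_grid: tuple[float, float, float] = (0.5, 5.0, 0.1)  # start, stop, step
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0 < t < 1 for t in self.taus):
            raise ValueError("all taus must lie in (0, 1)")
        if self.seed is None:
            raise ValueError("a seed is mandatory for any stochastic stage")
        for attr in ("data_dir", "stand_config"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr} path does not exist: {p}")


def load_run_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus overrides."""
    obj = {}
    if path is not None:
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
    obj.update({k: v for k, v in overrides.items() if v is not None})
    for key in ("taus", "strips", "dbh_grid"):
        if key in obj and obj[key] is not None:
            obj[key] = tuple(obj[key])
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(obj) - known
    if unknown:
        raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
    return RunConfig(**obj)
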