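"""Reading, writing and deriving crown geometry from branch measurement tables.

A dataset is a pair of CSV tables:

``saplings.csv``
    ``sapling_id, strip_type, dbh_cm, ht_m, cl_m, excluded_flag``
``branches.csv``
    ``sapling_id, whorl_index, l_m, bl_cm, bc_cm, va_deg, bd_mm,
    azimuth_deg`` plus optional ``year_YYYY`` columns holding annual
    branch-length increments (cm).

Field measurements per branch are: L, the distance along the trunk from the
sapling tip to the branch base (m); BL, branch length (cm); BC, branch chord
length (cm); VA, branch insertion angle (degrees); BD, branch diameter (mm);
azimuth (degrees clockwise from north).  From these the crown geometry is
derived per branch:

* ``DINC = L - BC*cos(VA)`` — depth of the branch *tip* into the crown:
  tip-to-base distance minus the chord's projection onto the trunk (m);
* ``OCR  = BC*sin(VA)`` — outer crown radius, the horizontal reach of the
  branch tip (m);
* ``RDINC = DINC / CL`` — relative depth, 0 at the tip, 1 at the crown base.

Internally all lengths are metres and angles radians; the file dialect keeps
the field units above.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StripType",
    "SaplingRecord",
    "BranchRecord",
    "DerivedBranch",
    "Dataset",
    "SchemaError",
    "ParseError",
    "ReferentialIntegrityError",
    "ValidationError",
    "derive_branch_geometry",
    "crown_ratio",
    "read_dataset",
    "read_branch_table",
    "write_dataset",
    "largest_branch_per_whorl",
    "validate_dataset",
    "model_frame",
]


class SchemaError(ValueError):
    pass


class ParseError(ValueError):
    pass


class ReferentialIntegrityError(ValueError):
    pass


class ValidationError(ValueError):
    pass


class StripType(str, enum.Enum):
    SHELTERWOOD_CUT = "shelterwood_cut"
    UNCUT = "uncut"


SAPLING_COLUMNS = ["sapling_id", "strip_type", "dbh_cm", "ht_m", "cl_m", "excluded_flag"]
BRANCH_COLUMNS = ["sapling_id", "whorl_index", "l_m", "bl_cm", "bc_cm",
                  "va_deg", "bd_mm", "azimuth_deg"]
#: derived per-branch columns added by this module
DERIVED_COLUMNS = ["dinc_m", "rdinc", "ocr_m"]


@dataclass(frozen=True)
class SaplingRecord:
    """Whole-tree measurements for one sapling.

    Sampling criteria: total height > 1.3 m, DBH < 5 cm, 0 < CL <= HT.
    """

    sapling_id: str
    strip_type: StripType
    dbh: float  # cm
    ht: float   # m
    cl: float   # m
    excluded: bool = False

    def __post_init__(self) -> None:
        if not self.ht > 1.3:
            raise ValueError(f"sapling {self.sapling_id}: ht={self.ht} must exceed 1.3 m")
        if not 0 < self.dbh < 5.0:
            raise ValueError(f"sapling {self.sapling_id}: dbh={self.dbh} outside (0, 5) cm")
        if not 0 < self.cl <= self.ht:
            raise ValueError(f"sapling {self.sapling_id}: cl={self.cl} outside (0, ht]")


@dataclass(frozen=True)
class BranchRecord:
    """Raw whorl measurements for one branch (field units)."""

    sapling_id: str
    whorl_index: int
    l: float        # m, tip to branch base
    bl: float       # cm, branch length
    bc: float       # cm, branch chord length
    va: float       # degrees
    bd: float       # mm
    azimuth: float  # degrees in [0, 360)
    annual_lengths: tuple[tuple[int, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.l < 0:
            raise ValueError("l must be nonnegative")
        if not 0 < self.bc <= self.bl:
            raise ValueError(f"bc={self.bc} must be in (0, bl={self.bl}]")
        if not 0 < self.va < 180:
            raise ValueError(f"va={self.va} outside (0, 180) degrees")
        if not 0 <= self.azimuth < 360:
            raise ValueError(f"azimuth={self.azimuth} outside [0, 360)")


@dataclass(frozen=True)
class DerivedBranch:
    branch: BranchRecord
    dinc: float   # m
    rdinc: float  # dimensionless
    ocr: float    # m
    cr_of_parent: float


@dataclass
class Dataset:
    """Sapling and branch tables plus provenance.

    ``saplings`` and ``branches`` are DataFrames in the column dialect at
    the module top; ``branches`` additionally carries the derived columns
    ``dinc_m, rdinc, ocr_m`` once geometry has been computed.
    """

    saplings: pd.DataFrame
    branches: pd.DataFrame
    provenance: str = ""

    def n_saplings(self, strip: str | StripType | None = None) -> int:
        return len(self._strip_mask(self.saplings, strip))

    def n_branches(self, strip: str | StripType | None = None) -> int:
        if strip is None:
            return len(self.branches)
        ids = set(self._strip_mask(self.saplings, strip)["sapling_id"])
        return int(self.branches["sapling_id"].isin(ids).sum())

    def subset(self, strip: str | StripType) -> "Dataset":
        saps = self._strip_mask(self.saplings, strip).reset_index(drop=True)
        ids = set(saps["sapling_id"])
        brs = self.branches[self.branches["sapling_id"].isin(ids)].reset_index(drop=True)
        return Dataset(saplings=saps, branches=brs,
                       provenance=f"{self.provenance} [strip={_strip_value(strip)}]")

    @staticmethod
    def _strip_mask(df: pd.DataFrame, strip) -> pd.DataFrame:
        if strip is None:
            return df
        return df[df["strip_type"] == _strip_value(strip)]

    def year_columns(self) -> list[str]:
        return [c for c in self.branches.columns if c.startswith("year_")]


def _strip_value(strip) -> str:
    return strip.value if isinstance(strip, StripType) else str(strip)


# ---------------------------------------------------------------------------
# geometry

def derive_branch_geometry(branch: BranchRecord, sapling: SaplingRecord) -> DerivedBranch:
    """Compute DINC, RDINC and OCR for one branch (scalar form).

    Chord length is converted cm -> m; the insertion angle to radians.
    Insertion angles above 90 degrees (observed on drooping lower branches)
    give a negative chord projection, hence ``dinc > l``; downstream the
    rdinc in [0, 1] policy of :func:`validate_dataset` applies.
    """
    if sapling.cl <= 0:
        raise ValueError("crown length must be positive")
    bc_m = branch.bc / 100.0
    va = math.radians(branch.va)
    dinc = branch.l - bc_m * math.cos(va)
    ocr = bc_m * math.sin(va)
    return DerivedBranch(branch=branch, dinc=dinc, rdinc=dinc / sapling.cl,
                         ocr=ocr, cr_of_parent=crown_ratio(sapling))


def crown_ratio(sapling: SaplingRecord) -> float:
    """Crown ratio CR = CL / HT, in (0, 1]."""
    if sapling.ht <= 0:
        raise ValueError("ht must be positive")
    if sapling.cl > sapling.ht:
        raise ValueError("cl exceeds ht")
    return sapling.cl / sapling.ht


def _derive_frame(branches: pd.DataFrame, saplings: pd.DataFrame) -> pd.DataFrame:
    """Vectorised geometry derivation; returns branches with derived columns."""
    sap = saplings.set_index("sapling_id")
    cl = branches["sapling_id"].map(sap["cl_m"])
    if cl.isna().any():
        bad = branches.loc[cl.isna(), "sapling_id"].unique().tolist()
        raise ReferentialIntegrityError(f"branches reference unknown sapling ids: {bad}")
    bc_m = branches["bc_cm"].to_numpy(float) / 100.0
    va = np.radians(branches["va_deg"].to_numpy(float))
    out = branches.copy()
    out["dinc_m"] = branches["l_m"].to_numpy(float) - bc_m * np.cos(va)
    out["ocr_m"] = bc_m * np.sin(va)
    out["rdinc"] = out["dinc_m"] / cl.to_numpy(float)
    return out


# ---------------------------------------------------------------------------
# I/O

def _map_columns(df: pd.DataFrame, schema: dict[str, str] | None, required: list[str],
                 what: str) -> pd.DataFrame:
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table missing mandatory columns: {missing}")
    return df


def _coerce_numeric(df: pd.DataFrame, cols: list[str], what: str) -> pd.DataFrame:
    df = df.copy()
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            row = int(df.index[bad][0])
            raise ParseError(f"non-numeric value in {what}.{c} at row {row}: {df[c][bad].iloc[0]!r}")
        df[c] = coerced
    return df


def read_dataset(saplings_path, branches_path, schema: dict[str, str] | None = None,
                 derive: bool = True) -> Dataset:
    """Read the two-table CSV dialect and compute derived geometry.

    ``schema`` maps canonical column names to the file's column names for
    either table (e.g. ``{"dbh_cm": "DBH"}``).
    """
    saps = pd.read_csv(saplings_path)
    brs = pd.read_csv(branches_path)
    saps = _map_columns(saps, schema, [c for c in SAPLING_COLUMNS if c != "excluded_flag"],
                        "saplings")
    if "excluded_flag" not in saps.columns:
        saps["excluded_flag"] = 0
    brs = _map_columns(brs, schema, BRANCH_COLUMNS, "branches")
    saps = _coerce_numeric(saps, ["dbh_cm", "ht_m", "cl_m"], "saplings")
    brs = _coerce_numeric(brs, [c for c in BRANCH_COLUMNS if c not in ("sapling_id",)],
                          "branches")
    saps["sapling_id"] = saps["sapling_id"].astype(str)
    brs["sapling_id"] = brs["sapling_id"].astype(str)
    bad = ~saps["strip_type"].isin([s.value for s in StripType])
    if bad.any():
        raise ParseError(f"unknown strip_type values: {saps.loc[bad, 'strip_type'].unique().tolist()}")
    unknown = ~brs["sapling_id"].isin(set(saps["sapling_id"]))
    if unknown.any():
        raise ReferentialIntegrityError(
            f"branches reference unknown sapling ids: "
            f"{brs.loc[unknown, 'sapling_id'].unique().tolist()}")
    # drop manually flagged saplings (field exclusions) and their branches
    keep = saps["excluded_flag"].fillna(0).astype(int) == 0
    saps = saps[keep].reset_index(drop=True)
    brs = brs[brs["sapling_id"].isin(set(saps["sapling_id"]))].reset_index(drop=True)
    if derive and len(brs):
        brs = _derive_frame(brs, saps)
    elif derive:
        for c in DERIVED_COLUMNS:
            brs[c] = pd.Series(dtype=float)
    return Dataset(saplings=saps, branches=brs,
                   provenance=f"read_dataset({saplings_path}, {branches_path})")


def read_branch_table(path, schema: dict[str, str] | None = None) -> Dataset:
    """Read a dataset from a directory holding ``saplings.csv`` and ``branches.csv``."""
    p = Path(path)
    return read_dataset(p / "saplings.csv", p / "branches.csv", schema=schema)


def write_dataset(dataset: Dataset, outdir) -> tuple[Path, Path]:
    """Write ``saplings.csv`` and ``branches.csv``; numeric fields keep full
    double precision (round-trip stable)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sp, bp = out / "saplings.csv", out / "branches.csv"
    dataset.saplings.to_csv(sp, index=False, float_format="%.12g")
    cols = [c for c in dataset.branches.columns if c not in DERIVED_COLUMNS]
    dataset.branches[cols].to_csv(bp, index=False, float_format="%.12g")
    return sp, bp


# ---------------------------------------------------------------------------
# selection rules

def largest_branch_per_whorl(dataset: Dataset, by: str = "ocr") -> Dataset:
    """Keep one branch per (sapling, whorl): the one with the largest radius.

    ``by="ocr"`` ranks on the derived outer crown radius (default);
    ``by="bd"`` ranks on branch diameter instead.  Ties break toward larger
    branch diameter, then the earlier row (stable).
    """
    if by not in ("ocr", "bd"):
        raise ValueError("by must be 'ocr' or 'bd'")
    key = "ocr_m" if by == "ocr" else "bd_mm"
    brs = dataset.branches
    if key not in brs.columns:
        raise ValueError(f"derived column {key} absent; read with derive=True")
    df = brs.reset_index(drop=True)
    order = df.sort_values([key, "bd_mm"], ascending=[False, False], kind="mergesort")
    picked = order.drop_duplicates(["sapling_id", "whorl_index"], keep="first")
    picked = picked.sort_index().reset_index(drop=True)
    return Dataset(saplings=dataset.saplings, branches=picked,
                   provenance=f"{dataset.provenance} [largest per whorl by {by}]")


def validate_dataset(dataset: Dataset, policy: str = "clip") -> tuple[Dataset, pd.DataFrame]:
    """Apply the rdinc in [0, 1] retention policy.

    ``drop`` removes offending branches, ``clip`` snaps rdinc to [0, 1]
    (keeping sample size), ``fail`` raises.  Returns the handled dataset and
    a report DataFrame (one row per affected branch: row index, sapling_id,
    whorl_index, rdinc, rule).
    """
    if policy not in ("drop", "clip", "fail"):
        raise ValueError("policy must be drop, clip or fail")
    brs = dataset.branches.reset_index(drop=True)
    rd = brs["rdinc"]
    low, high = rd < 0, rd > 1
    mask = low | high
    report = pd.DataFrame({
        "row": brs.index[mask],
        "sapling_id": brs.loc[mask, "sapling_id"].to_numpy(),
        "whorl_index": brs.loc[mask, "whorl_index"].to_numpy(),
        "rdinc": rd[mask].to_numpy(),
        "rule": np.where(rd[mask] < 0, "rdinc<0", "rdinc>1"),
    }).reset_index(drop=True)
    if not mask.any():
        return dataset, report
    if policy == "fail":
        raise ValidationError(f"{int(mask.sum())} branches violate rdinc in [0,1]")
    if policy == "drop":
        out = brs[~mask].reset_index(drop=True)
    else:
        out = brs.copy()
        out.loc[mask, "rdinc"] = rd[mask].clip(0.0, 1.0)
        # keep dinc consistent with the clipped relative depth
        sap = dataset.saplings.set_index("sapling_id")["cl_m"]
        out.loc[mask, "dinc_m"] = out.loc[mask, "rdinc"] * out.loc[mask, "sapling_id"].map(sap)
    return (Dataset(saplings=dataset.saplings, branches=out,
                    provenance=f"{dataset.provenance} [validated:{policy}]"), report)


def model_frame(dataset: Dataset, strip: str | StripType | None = None,
                largest_per_whorl: bool = False) -> pd.DataFrame:
    """Per-branch regression frame: dbh_cm, cr, rdinc, ocr_m (+ sapling_id).

    Joins sapling covariates onto branches; optionally keeps only the
    largest branch per whorl (candidate-model comparison protocol).
    """
    ds = dataset if strip is None else dataset.subset(strip)
    if largest_per_whorl:
        ds = largest_branch_per_whorl(ds)
    sap = ds.saplings.set_index("sapling_id")
    brs = ds.branches
    return pd.DataFrame({
        "sapling_id": brs["sapling_id"].to_numpy(),
        "dbh_cm": brs["sapling_id"].map(sap["dbh_cm"]).to_numpy(float),
        "cr": brs["sapling_id"].map(sap["cl_m"] / sap["ht_m"]).to_numpy(float),
        "rdinc": brs["rdinc"].to_numpy(float),
        "ocr_m": brs["ocr_m"].to_numpy(float),
    })
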