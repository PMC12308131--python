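"""Cohort table schema: validation, reading, writing, and the scanner QC check.

A cohort is three long-format comma-separated tables:

``clinical.csv``
    One row per clinical encounter: EDSS, the seven functional-system
    scores (FSS), an ambulation flag, a relapse flag, and the patient's
    age (decimal years) at the visit.

``brain_mri.csv``
    One row per brain-MRI time point: T2 lesion volume (ml) in the seven
    brain subcompartments, head-size-normalized cerebral and
    infratentorial parenchymal volumes, and optionally a cord
    cross-sectional area (mucca, mm^2) derived from the brain T1.

``cord_mri.csv``
    One row per cord-MRI time point: cervical lesion volumes (ml) in the
    high/low cervical subcompartments and mucca (mm^2).

Validation is total: every cell either parses to its semantic type or
raises a :class:`SchemaError` naming the file, row and field.  Missing
optional cells become NaN, never zero.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# Schema constants
# --------------------------------------------------------------------------

#: Valid EDSS values: 0.0, then 1.0 to 10.0 in half-point steps.
EDSS_GRID: tuple[float, ...] = (0.0,) + tuple(np.arange(1.0, 10.01, 0.5))

#: Maximum score per functional system.
FSS_RANGES: dict[str, int] = {
    "fss_pyramidal": 6,
    "fss_cerebellar": 5,
    "fss_brainstem": 5,
    "fss_sensory": 6,
    "fss_bowel_bladder": 6,
    "fss_visual": 6,
    "fss_mental": 5,
}
FSS_COLUMNS: tuple[str, ...] = tuple(FSS_RANGES)

CLINICAL_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "date",
    "age",
    "edss",
    *FSS_COLUMNS,
    "ambulation_affected",
    "relapse",
)

#: Brain lesion subcompartments (ml), grouped cerebral then infratentorial.
CEREBRAL_SUBCOMPARTMENTS: tuple[str, ...] = (
    "juxtacortical_ml",
    "deep_white_matter_ml",
    "periventricular_ml",
)
INFRATENTORIAL_SUBCOMPARTMENTS: tuple[str, ...] = (
    "medulla_ml",
    "pons_ml",
    "midbrain_ml",
    "cerebellum_ml",
)
CORD_SUBCOMPARTMENTS: tuple[str, ...] = ("high_cervical_ml", "low_cervical_ml")

BRAIN_MRI_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "date",
    "scanner_id",
    *CEREBRAL_SUBCOMPARTMENTS,
    *INFRATENTORIAL_SUBCOMPARTMENTS,
    "p_cereb",
    "p_infra",
    "mucca_brain_t1_mm2",
)

CORD_MRI_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "date",
    "scanner_id",
    *CORD_SUBCOMPARTMENTS,
    "mucca_mm2",
)

#: Columns that may legitimately be empty in the input files.
OPTIONAL_COLUMNS: frozenset[str] = frozenset(
    {"mucca_brain_t1_mm2", "mucca_mm2", "edss", "age", *FSS_COLUMNS}
)

#: Provenance labels attached to every matched value downstream.
PROVENANCE_LEVELS: tuple[str, ...] = (
    "measured",
    "nearest_15d",
    "forward_filled",
    "backward_filled",
    "clinical_filled_9m",
    "missing",
)

FILE_NAMES = {
    "clinical": "clinical.csv",
    "brain": "brain_mri.csv",
    "cord": "cord_mri.csv",
}


class SchemaError(ValueError):
    """A cohort table cell failed validation; message names row and field."""


@dataclass(frozen=True)
class CompartmentTriple:
    """A value per topographical compartment: cervical cord, infratentorial
    (brainstem + cerebellum), cerebral hemispheres."""

    cord: float
    infra: float
    cereb: float

    def as_dict(self) -> dict[str, float]:
        return {"cord": self.cord, "infra": self.infra, "cereb": self.cereb}

    @classmethod
    def from_any(cls, value: "CompartmentTriple | Mapping | Sequence") -> "CompartmentTriple":
        if isinstance(value, cls):
            return value
        if isinstance(value, Mapping):
            return cls(cord=float(value["cord"]), infra=float(value["infra"]),
                       cereb=float(value["cereb"]))
        cord, infra, cereb = value
        return cls(cord=float(cord), infra=float(infra), cereb=float(cereb))


COMPARTMENTS: tuple[str, ...] = ("cord", "infra", "cereb")


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

def _err(table: str, row: int | str, field: str, msg: str) -> SchemaError:
    return SchemaError(f"{table}, row {row}, field '{field}': {msg}")


def _parse_table(df: pd.DataFrame, table: str, columns: Sequence[str]) -> pd.DataFrame:
    unknown = [c for c in df.columns if c not in columns]
    if unknown:
        raise SchemaError(f"{table}: unknown column(s) {unknown}")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing column(s) {missing}")
    out = df.loc[:, list(columns)].copy()

    for i, raw in out["date"].items():
        try:
            out.loc[i, "date"] = pd.Timestamp(str(raw)).normalize()
        except (ValueError, TypeError):
            raise _err(table, i, "date", f"unparseable date {raw!r}") from None
    out["date"] = pd.to_datetime(out["date"])
    out["patient_id"] = out["patient_id"].astype(str)

    dup = out.duplicated(subset=["patient_id", "date"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise _err(table, out.index[i], "date",
                   "duplicate (patient_id, date) entry")
    return out


def _coerce_numeric(df: pd.DataFrame, table: str, col: str,
                    *, optional: bool, lo: float | None = None,
                    hi: float | None = None, grid: Iterable[float] | None = None,
                    integral: bool = False) -> pd.Series:
    # parse with Python's float(): correctly rounded, so a write -> read ->
    # write cycle is byte-identical (pandas' fast parser is not)
    parsed = []
    for i, raw in df[col].items():
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            parsed.append(np.nan)
            continue
        if isinstance(raw, (int, float, np.integer, np.floating, np.bool_, bool)):
            parsed.append(float(raw))
            continue
        s = str(raw).strip()
        if s == "":
            parsed.append(np.nan)
            continue
        try:
            parsed.append(float(s))
        except ValueError:
            raise _err(table, i, col, f"not a number: {raw!r}") from None
    values = pd.Series(parsed, index=df.index, dtype=float)
    if not optional and values.isna().any():
        i = values.isna().idxmax()
        raise _err(table, i, col, "required value is missing")
    present = values.dropna()
    if lo is not None and (present < lo).any():
        i = present[present < lo].index[0]
        raise _err(table, i, col, f"value {values[i]} below minimum {lo}")
    if hi is not None and (present > hi).any():
        i = present[present > hi].index[0]
        raise _err(table, i, col, f"value {values[i]} above maximum {hi}")
    if integral:
        off = present[~np.isclose(present % 1.0, 0.0)]
        if len(off):
            i = off.index[0]
            raise _err(table, i, col, f"value {values[i]} is not an integer score")
    if grid is not None:
        grid_arr = np.asarray(sorted(grid), dtype=float)
        on_grid = np.isclose(present.to_numpy(dtype=float)[:, None], grid_arr).any(axis=1)
        if not on_grid.all():
            i = present.index[int(np.flatnonzero(~on_grid)[0])]
            raise _err(table, i, col, f"value {values[i]} is off the EDSS grid")
    return values.astype(float)


def _coerce_bool(df: pd.DataFrame, table: str, col: str) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False,
               "yes": True, "no": False}
    out = []
    for i, raw in df[col].items():
        if isinstance(raw, (bool, np.bool_)):
            out.append(bool(raw))
            continue
        key = str(raw).strip().lower()
        if key not in mapping:
            raise _err(table, i, col, f"not a boolean: {raw!r}")
        out.append(mapping[key])
    return pd.Series(out, index=df.index, dtype=bool)


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and type a clinical-visit table; returns a typed copy."""
    table = "clinical"
    out = _parse_table(df, table, CLINICAL_COLUMNS)
    out["age"] = _coerce_numeric(out, table, "age", optional=True, lo=0.0, hi=120.0)
    out["edss"] = _coerce_numeric(out, table, "edss", optional=True, grid=EDSS_GRID)
    for col, top in FSS_RANGES.items():
        out[col] = _coerce_numeric(out, table, col, optional=True,
                                   lo=0, hi=top, integral=True)
    out["ambulation_affected"] = _coerce_bool(out, table, "ambulation_affected")
    out["relapse"] = _coerce_bool(out, table, "relapse")
    return out.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)


def validate_brain_mri(df: pd.DataFrame) -> pd.DataFrame:
    table = "brain_mri"
    out = _parse_table(df, table, BRAIN_MRI_COLUMNS)
    out["scanner_id"] = out["scanner_id"].astype(str)
    for col in CEREBRAL_SUBCOMPARTMENTS + INFRATENTORIAL_SUBCOMPARTMENTS:
        out[col] = _coerce_numeric(out, table, col, optional=False, lo=0.0)
    for col in ("p_cereb", "p_infra"):
        out[col] = _coerce_numeric(out, table, col, optional=False, lo=0.0)
    out["mucca_brain_t1_mm2"] = _coerce_numeric(
        out, table, "mucca_brain_t1_mm2", optional=True, lo=1e-12)
    return out.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)


def validate_cord_mri(df: pd.DataFrame) -> pd.DataFrame:
    table = "cord_mri"
    out = _parse_table(df, table, CORD_MRI_COLUMNS)
    out["scanner_id"] = out["scanner_id"].astype(str)
    for col in CORD_SUBCOMPARTMENTS:
        out[col] = _coerce_numeric(out, table, col, optional=False, lo=0.0)
    out["mucca_mm2"] = _coerce_numeric(out, table, "mucca_mm2", optional=True, lo=1e-12)
    return out.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)


# --------------------------------------------------------------------------
# Reading / writing
# --------------------------------------------------------------------------

def read_cohort(in_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read and validate ``clinical.csv``, ``brain_mri.csv``, ``cord_mri.csv``.

    Returns typed ``(clinical, brain, cord)`` frames sorted by
    (patient_id, date).  Raises :class:`SchemaError` with a located
    message on the first invalid cell.
    """
    in_dir = Path(in_dir)
    frames = {}
    for key, fname in FILE_NAMES.items():
        path = in_dir / fname
        if not path.exists():
            raise FileNotFoundError(path)
        frames[key] = pd.read_csv(path, dtype=str, keep_default_na=False)
        frames[key] = frames[key].replace({"": None})
    return (
        validate_clinical(frames["clinical"]),
        validate_brain_mri(frames["brain"]),
        validate_cord_mri(frames["cord"]),
    )


def _format_frame(df: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    out = df.loc[:, list(columns)].copy()
    out = out.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    for col in columns:
        if out[col].dtype == bool:
            out[col] = out[col].map({True: "True", False: "False"})
    return out


def write_cohort(clinical: pd.DataFrame, brain: pd.DataFrame, cord: pd.DataFrame,
                 out_dir: str | Path) -> dict[str, Path]:
    """Write the three cohort tables with deterministic row/column order.

    Missing optional cells are written as empty fields, not zeros; two
    writes of the same records are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for key, df, cols in (
        ("clinical", clinical, CLINICAL_COLUMNS),
        ("brain", brain, BRAIN_MRI_COLUMNS),
        ("cord", cord, CORD_MRI_COLUMNS),
    ):
        path = out_dir / FILE_NAMES[key]
        formatted = _format_frame(df, cols)
        formatted.to_csv(path, index=False, lineterminator="\n", na_rep="")
        paths[key] = path
    return paths


# --------------------------------------------------------------------------
# Scanner harmonization check
# --------------------------------------------------------------------------

def ks_scanner_check(frame: pd.DataFrame, measures: Sequence[str] | None = None,
                     alpha: float = 0.05, min_group: int = 5) -> pd.DataFrame:
    """Two-sample Kolmogorov-Smirnov comparison of measurement distributions
    across scanners.

    For every numeric measure and every pair of scanners, computes the
    two-sided two-sample KS statistic and p-value; p-values are Holm-adjusted
    within each measure and a pair is flagged when the adjusted p falls
    below ``alpha``.  Scanner groups with fewer than ``min_group``
    non-missing values are skipped with a warning.

    Returns a frame with columns
    ``measure, scanner_a, scanner_b, n_a, n_b, statistic, p_value, p_holm,
    flagged``.
    """
    if "scanner_id" not in frame.columns:
        raise ValueError("frame must carry a scanner_id column")
    if measures is None:
        skip = {"patient_id", "date", "scanner_id"}
        measures = [c for c in frame.columns
                    if c not in skip and pd.api.types.is_numeric_dtype(frame[c])]
    rows = []
    for measure in measures:
        groups = {}
        for scanner, sub in frame.groupby("scanner_id"):
            values = pd.to_numeric(sub[measure], errors="coerce").dropna().to_numpy()
            if len(values) < min_group:
                logger.warning(
                    "ks_scanner_check: scanner %s has %d < %d values for %s; skipped",
                    scanner, len(values), min_group, measure)
                continue
            groups[str(scanner)] = values
        if len(groups) < 2:
            continue
        pairs = list(itertools.combinations(sorted(groups), 2))
        stats_p = [stats.ks_2samp(groups[a], groups[b], alternative="two-sided")
                   for a, b in pairs]
        pvals = [float(r.pvalue) for r in stats_p]
        holm = multipletests(pvals, method="holm")[1] if pairs else []
        for (a, b), res, ph in zip(pairs, stats_p, holm):
            rows.append({
                "measure": measure,
                "scanner_a": a,
                "scanner_b": b,
                "n_a": len(groups[a]),
                "n_b": len(groups[b]),
                "statistic": float(res.statistic),
                "p_value": float(res.pvalue),
                "p_holm": float(ph),
                "flagged": bool(ph < alpha),
            })
    report = pd.DataFrame(rows, columns=["measure", "scanner_a", "scanner_b",
                                         "n_a", "n_b", "statistic", "p_value",
                                         "p_holm", "flagged"])
    return report


def harmonization_needed(report: pd.DataFrame) -> bool:
    """True when any scanner pair was flagged; False means the cohort can be
    pooled across scanners without further harmonization."""
    return bool(len(report)) and bool(report["flagged"].any())
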