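"""Lesion parenchymal fraction: compartment aggregation, mucca calibration,
percentile transforms, and the modelling feature table.

The lesion parenchymal fraction (LPF) of a compartment is its T2 lesion
volume divided by its parenchymal measure:

* cervical cord: cord lesion volume (ml) over the mean upper cervical
  cord cross-sectional area (mucca, mm^2),
* infratentorial: brainstem + cerebellum lesion volume over the
  infratentorial parenchymal volume,
* cerebral: hemispheric lesion volume over the cerebral parenchymal
  volume (whole brain minus infratentorial tissue, stored pre-split).

Each compartment's LPF is an internally consistent index; lesion,
parenchymal and LPF values are transformed to percentiles with respect
to the pooled study sample (all patients, all time points) so their
scales become comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import matching
from .io import (
    CEREBRAL_SUBCOMPARTMENTS,
    COMPARTMENTS,
    CORD_SUBCOMPARTMENTS,
    INFRATENTORIAL_SUBCOMPARTMENTS,
    CompartmentTriple,
)

logger = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """Raised when the mucca calibration cannot be fitted as requested."""


@dataclass(frozen=True)
class MuccaCalibration:
    """Quadratic map from brain-T1-derived mucca to cord-MRI-derived mucca.

    ``predicted = c0 + c1 * b + c2 * b**2`` where ``b`` is the brain-T1
    value.  ``kind`` records whether a quadratic, linear or identity map
    was fitted (the latter two are degeneracy fallbacks).
    """

    c0: float
    c1: float
    c2: float
    n_pairs: int
    residual_rmse: float
    kind: str = "quadratic"

    def coefficients(self) -> tuple[float, float, float]:
        return (self.c0, self.c1, self.c2)


IDENTITY_CALIBRATION = MuccaCalibration(0.0, 1.0, 0.0, 0, 0.0, kind="identity")


@dataclass
class ExclusionReport:
    """Bookkeeping for rows/patients dropped by the completeness rule."""

    n_rows_total: int = 0
    n_rows_excluded: int = 0
    n_patients_total: int = 0
    n_patients_excluded: int = 0
    missing_by_column: dict[str, int] = field(default_factory=dict)

    @property
    def n_rows_kept(self) -> int:
        return self.n_rows_total - self.n_rows_excluded

    @property
    def n_patients_kept(self) -> int:
        return self.n_patients_total - self.n_patients_excluded


# --------------------------------------------------------------------------
# Compartment aggregation
# --------------------------------------------------------------------------

def aggregate_subcompartments(frame: pd.DataFrame) -> pd.DataFrame:
    """Sum subcompartment lesion volumes into the three compartments.

    Works on any frame carrying the subcompartment columns (a matched
    frame or a merged MRI frame).  A compartment total is missing if any
    of its constituents is missing; cord lesions missing does not block
    the brain compartments.  Adds ``l_cord, l_infra, l_cereb`` and passes
    ``p_cereb, p_infra, mucca_mm2`` through as ``p_cereb, p_infra, p_cord``.
    """
    out = frame.copy()
    out["l_cereb"] = frame[list(CEREBRAL_SUBCOMPARTMENTS)].sum(axis=1, skipna=False)
    out["l_infra"] = frame[list(INFRATENTORIAL_SUBCOMPARTMENTS)].sum(axis=1, skipna=False)
    out["l_cord"] = frame[list(CORD_SUBCOMPARTMENTS)].sum(axis=1, skipna=False)
    if "mucca_mm2" in frame.columns:
        out["p_cord"] = frame["mucca_mm2"]
    return out


def aggregate_record(record: pd.Series) -> tuple[CompartmentTriple, CompartmentTriple]:
    """Aggregate a single MRI record row into (L, P) compartment triples."""
    agg = aggregate_subcompartments(record.to_frame().T).iloc[0]
    L = CompartmentTriple(cord=float(agg["l_cord"]), infra=float(agg["l_infra"]),
                          cereb=float(agg["l_cereb"]))
    P = CompartmentTriple(cord=float(agg.get("p_cord", np.nan)),
                          infra=float(agg.get("p_infra", np.nan)),
                          cereb=float(agg.get("p_cereb", np.nan)))
    return L, P


# --------------------------------------------------------------------------
# mucca calibration
# --------------------------------------------------------------------------

def fit_mucca_calibration(pairs: "np.ndarray | list[tuple[float, float]]",
                          degree: int = 2) -> MuccaCalibration:
    """Least-squares polynomial fit of cord-MRI mucca on brain-T1 mucca.

    Requires at least ``degree + 1`` pairs with distinct brain values;
    raises :class:`CalibrationError` otherwise (callers may fall back to
    :func:`fit_mucca_calibration_with_fallback`).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise CalibrationError("pairs must be (brain_t1, cord_mri) tuples")
    arr = arr[~np.isnan(arr).any(axis=1)]
    brain, cord = arr[:, 0], arr[:, 1]
    n_distinct = len(np.unique(brain))
    if len(arr) < degree + 1 or n_distinct < degree + 1:
        raise CalibrationError(
            f"need >= {degree + 1} pairs with distinct brain values to fit a "
            f"degree-{degree} calibration (got {len(arr)} pairs, "
            f"{n_distinct} distinct); fall back to a lower degree or identity")
    design = np.vander(brain, degree + 1, increasing=True)
    coef, _, rank, _ = np.linalg.lstsq(design, cord, rcond=None)
    if rank < degree + 1:
        raise CalibrationError(
            f"rank-deficient design for degree-{degree} calibration; "
            "fall back to a lower degree or identity")
    resid = cord - design @ coef
    coef = np.pad(coef, (0, 3 - len(coef)))
    kind = {2: "quadratic", 1: "linear"}.get(degree, f"degree-{degree}")
    return MuccaCalibration(float(coef[0]), float(coef[1]), float(coef[2]),
                            n_pairs=len(arr),
                            residual_rmse=float(np.sqrt(np.mean(resid ** 2))),
                            kind=kind)


def fit_mucca_calibration_with_fallback(pairs) -> MuccaCalibration:
    """Quadratic fit, falling back to linear (>= 2 pairs) then identity."""
    for degree in (2, 1):
        try:
            return fit_mucca_calibration(pairs, degree=degree)
        except CalibrationError as exc:
            logger.warning("mucca calibration degree %d failed (%s)", degree, exc)
    logger.warning("mucca calibration falling back to identity")
    return IDENTITY_CALIBRATION


def apply_mucca_calibration(calibration: MuccaCalibration,
                            brain_t1_mucca) -> np.ndarray | float:
    """Map brain-T1 mucca values through the calibration.

    Non-positive results are invalid measurements and are returned as NaN
    (discarded downstream, mirroring quality-control discards).
    """
    b = np.asarray(brain_t1_mucca, dtype=float)
    out = calibration.c0 + calibration.c1 * b + calibration.c2 * b ** 2
    invalid = out <= 0
    if np.any(invalid):
        logger.warning("mucca calibration produced %d non-positive values; "
                       "flagged invalid", int(np.sum(invalid)))
    out = np.where(invalid, np.nan, out)
    return float(out) if np.isscalar(brain_t1_mucca) else out


# --------------------------------------------------------------------------
# LPF and percentiles
# --------------------------------------------------------------------------

def compute_lpf(L, P):
    """Raw lesion parenchymal fraction L / P.

    ``P`` must be strictly positive where present; a missing ``L`` or
    missing ``P`` yields a missing LPF.
    """
    L_arr = np.asarray(L, dtype=float)
    P_arr = np.asarray(P, dtype=float)
    if np.any((~np.isnan(P_arr)) & (P_arr <= 0)):
        raise ValueError("parenchymal measure must be > 0 where present")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = L_arr / P_arr
    out = np.where(np.isnan(L_arr) | np.isnan(P_arr), np.nan, out)
    return float(out) if np.isscalar(L) and np.isscalar(P) else out


def to_percentiles(values) -> np.ndarray:
    """Hazen percentile rank, ``100 * (r - 0.5) / n`` with midranks for ties.

    Computed over the non-missing entries of ``values`` (the pooled study
    sample of a measure); missing in, missing out.  Requires at least two
    non-missing values.
    """
    arr = np.asarray(values, dtype=float)
    mask = ~np.isnan(arr)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("cannot compute percentiles of an all-missing sample")
    if n < 2:
        raise ValueError("need at least 2 non-missing values for percentiles")
    ranks = rankdata(arr[mask], method="average")
    out = np.full(arr.shape, np.nan)
    out[mask] = 100.0 * (ranks - 0.5) / n
    return out


def percentile_of(values, reference) -> np.ndarray:
    """Hazen percentile of ``values`` with respect to a fixed reference sample.

    For a value v, the midrank within the reference is
    ``(# ref < v) + (# ref == v + 1) / 2``; consistent with
    :func:`to_percentiles` when v is drawn from the reference itself.
    """
    ref = np.asarray(reference, dtype=float)
    ref = ref[~np.isnan(ref)]
    if len(ref) < 2:
        raise ValueError("reference sample needs at least 2 values")
    v = np.atleast_1d(np.asarray(values, dtype=float))
    ref_sorted = np.sort(ref)
    below = np.searchsorted(ref_sorted, v, side="left")
    upto = np.searchsorted(ref_sorted, v, side="right")
    rank = below + (upto - below + 1) / 2.0
    out = 100.0 * (rank - 0.5) / len(ref)
    out[np.isnan(v)] = np.nan
    return out if np.ndim(values) else float(out[0])


# --------------------------------------------------------------------------
# mucca resolution (cord scan first, calibrated brain T1 otherwise)
# --------------------------------------------------------------------------

def resolve_mucca(brain: pd.DataFrame, cord: pd.DataFrame,
                  pair_window_days: int = matching.WINDOW_DAYS_DEFAULT
                  ) -> tuple[dict[str, tuple[pd.Series, pd.Series]], MuccaCalibration]:
    """Build each patient's measured mucca series, calibrating brain-T1
    values where no cord scan exists.

    The calibration (quadratic, with linear/identity fallbacks) is fitted
    on time points with both a brain-T1 mucca and a cord scan within
    ``pair_window_days``, pooled over the cohort.  Returns a mapping
    ``patient_id -> (mucca series, source labels)`` with labels in
    ``{cord_mri, calibrated_brain_t1}``, plus the fitted calibration.
    """
    pairs = []
    per_patient_brain: dict[str, pd.Series] = {}
    per_patient_cord: dict[str, pd.Series] = {}
    for pid in sorted(set(brain["patient_id"]) | set(cord["patient_id"])):
        bsub = brain[brain["patient_id"] == pid]
        csub = cord[cord["patient_id"] == pid]
        b = pd.Series(bsub["mucca_brain_t1_mm2"].to_numpy(dtype=float),
                      index=pd.to_datetime(bsub["date"])).dropna().sort_index()
        c = pd.Series(csub["mucca_mm2"].to_numpy(dtype=float),
                      index=pd.to_datetime(csub["date"])).dropna().sort_index()
        per_patient_brain[pid] = b
        per_patient_cord[pid] = c
        window = np.timedelta64(pair_window_days, "D")
        for date, bval in b.items():
            if not len(c):
                continue
            dist = np.abs(c.index.to_numpy() - np.datetime64(date))
            k = int(np.argmin(dist))
            if dist[k] <= window:
                pairs.append((bval, float(c.iloc[k])))

    calibration = fit_mucca_calibration_with_fallback(pairs) if pairs \
        else IDENTITY_CALIBRATION

    resolved: dict[str, tuple[pd.Series, pd.Series]] = {}
    window = np.timedelta64(pair_window_days, "D")
    for pid in per_patient_brain:
        c = per_patient_cord[pid]
        b = per_patient_brain[pid]
        values = dict(c)
        sources = {d: "cord_mri" for d in c.index}
        for date, bval in b.items():
            has_cord_nearby = len(c) and (
                np.abs(c.index.to_numpy() - np.datetime64(date)) <= window).any()
            if has_cord_nearby or date in values:
                continue
            est = apply_mucca_calibration(calibration, float(bval))
            if not np.isnan(est):
                values[date] = est
                sources[date] = "calibrated_brain_t1"
        idx = pd.DatetimeIndex(sorted(values))
        resolved[pid] = (pd.Series([values[d] for d in idx], index=idx),
                         pd.Series([sources[d] for d in idx], index=idx))
    return resolved, calibration


# --------------------------------------------------------------------------
# Feature table
# --------------------------------------------------------------------------

FEATURE_PCT_COLUMNS: tuple[str, ...] = tuple(
    f"{kind}_{comp}_pct" for kind in ("l", "p", "lpf") for comp in COMPARTMENTS
)
REQUIRED_FEATURE_COLUMNS: tuple[str, ...] = FEATURE_PCT_COLUMNS + ("edss", "age0")


def build_feature_table(matched: pd.DataFrame
                        ) -> tuple[pd.DataFrame, ExclusionReport]:
    """Turn a matched cohort frame into the modelling feature table.

    Per row: lesion, parenchymal and LPF percentiles per compartment
    (pooled Hazen percentiles over the whole matched sample), measured
    EDSS, and ``age0`` (the patient's age at their earliest matched time
    point).  Rows missing any required feature are excluded and counted;
    patients with zero complete rows are reported as excluded.
    """
    frame = aggregate_subcompartments(matched)
    for comp in COMPARTMENTS:
        frame[f"lpf_{comp}_raw"] = compute_lpf(frame[f"l_{comp}"],
                                               frame[f"p_{comp}"])
    age0 = frame.groupby("patient_id")["age"].transform("min")
    frame["age0"] = age0

    for comp in COMPARTMENTS:
        for kind, src in (("l", f"l_{comp}"), ("p", f"p_{comp}"),
                          ("lpf", f"lpf_{comp}_raw")):
            col = f"{kind}_{comp}_pct"
            vals = frame[src].to_numpy(dtype=float)
            if np.sum(~np.isnan(vals)) >= 2:
                frame[col] = to_percentiles(vals)
            else:
                frame[col] = np.nan

    report = ExclusionReport(
        n_rows_total=len(frame),
        n_patients_total=frame["patient_id"].nunique(),
    )
    required = list(REQUIRED_FEATURE_COLUMNS)
    complete = frame[required].notna().all(axis=1)
    report.n_rows_excluded = int((~complete).sum())
    report.missing_by_column = {
        c: int(frame.loc[~complete, c].isna().sum()) for c in required}
    kept = frame[complete].copy()
    report.n_patients_excluded = (report.n_patients_total
                                  - kept["patient_id"].nunique())
    if report.n_rows_excluded:
        logger.info("feature table: excluded %d/%d rows (%d patients with no "
                    "complete rows)", report.n_rows_excluded,
                    report.n_rows_total, report.n_patients_excluded)

    keep_cols = (["patient_id", "date", "age0", "edss"]
                 + list(FEATURE_PCT_COLUMNS)
                 + [f"l_{c}" for c in COMPARTMENTS]
                 + [f"p_{c}" for c in COMPARTMENTS]
                 + [f"lpf_{c}_raw" for c in COMPARTMENTS])
    keep_cols += [c for c in ("mucca_source",) if c in kept.columns]
    features = kept[keep_cols].reset_index(drop=True)
    return features, report
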