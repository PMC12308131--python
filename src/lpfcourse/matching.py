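"""Merge clinical and MRI visit streams onto unified per-patient time points.

Clinical visits and MRI scans are rarely acquired on identical dates, so
each patient's analysis time line is the union of all their visit dates,
with missing values completed by copy-fills in a fixed stage order:

1. MRI-derived measures missing on a unified date take the nearest dated
   measurement within +/- 15 days (ties broken toward the earlier date).
2. Lesion volumes are forward-filled: lesions, once formed, are treated
   as permanent.  Parenchymal measures (tissue volumes, cord
   cross-sectional area) are backward-filled: adult parenchyma does not
   regrow, so an earlier gap can safely take the next measured value.
3. Clinical scores (EDSS, FSS, ambulation flag) are filled from the
   nearest clinical visit up to 9 months (274 days) away in either
   direction.

Only copy-fills are used, never interpolation, and each stage sees the
previous stage's output exactly once (fills do not chain within a
stage's own window).  Every value carries a provenance flag from
:data:`lpfcourse.io.PROVENANCE_LEVELS`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import (
    CEREBRAL_SUBCOMPARTMENTS,
    CORD_SUBCOMPARTMENTS,
    FSS_COLUMNS,
    INFRATENTORIAL_SUBCOMPARTMENTS,
)

WINDOW_DAYS_DEFAULT = 15
#: 9 months as days: 365.25 * 0.75, rounded.
CLINICAL_WINDOW_DAYS_DEFAULT = 274

LESION_MEASURES: tuple[str, ...] = (
    CEREBRAL_SUBCOMPARTMENTS + INFRATENTORIAL_SUBCOMPARTMENTS + CORD_SUBCOMPARTMENTS
)
PARENCHYMAL_MEASURES: tuple[str, ...] = ("p_cereb", "p_infra", "mucca_mm2")
CLINICAL_MEASURES: tuple[str, ...] = ("edss",) + FSS_COLUMNS + ("ambulation_affected",)


def unify_dates(visits: pd.DataFrame, mris: pd.DataFrame | None = None,
                *more: pd.DataFrame) -> pd.DatetimeIndex:
    """Union of clinical and MRI dates for one patient, deduplicated, ascending."""
    frames = [visits] + ([mris] if mris is not None else []) + list(more)
    dates: list[pd.Timestamp] = []
    for frame in frames:
        if frame is not None and len(frame):
            dates.extend(pd.to_datetime(frame["date"]))
    return pd.DatetimeIndex(sorted(set(dates)))


def _nearest_within(measured: pd.Series, targets: pd.DatetimeIndex,
                    window_days: int, fill_label: str
                    ) -> tuple[pd.Series, pd.Series]:
    """Place measured values on target dates; fill gaps from the nearest
    measurement within the window.  Exact-date matches keep provenance
    ``measured``; equidistant candidates resolve to the earlier date."""
    values = pd.Series(np.nan, index=targets, dtype=float)
    src = pd.Series("missing", index=targets, dtype=object)
    measured = measured.dropna().sort_index()
    if measured.empty:
        return values, src
    m_dates = measured.index.to_numpy()
    m_vals = measured.to_numpy(dtype=float)
    window = np.timedelta64(window_days, "D")
    for t in targets:
        t64 = np.datetime64(t)
        delta = m_dates - t64
        exact = np.flatnonzero(delta == np.timedelta64(0))
        if len(exact):
            values[t] = m_vals[exact[0]]
            src[t] = "measured"
            continue
        dist = np.abs(delta)
        inside = np.flatnonzero(dist <= window)
        if not len(inside):
            continue
        best = dist[inside].min()
        candidates = inside[dist[inside] == best]
        pick = candidates[np.argmin(m_dates[candidates])]  # earlier wins ties
        values[t] = m_vals[pick]
        src[t] = fill_label
    return values, src


def nearest_fill(series: pd.Series, target_dates: pd.DatetimeIndex,
                 window_days: int = WINDOW_DAYS_DEFAULT
                 ) -> tuple[pd.Series, pd.Series]:
    """MRI-measure stage-1 fill: nearest measurement within +/- ``window_days``.

    ``series`` is indexed by measurement date.  Returns (values, provenance)
    aligned to ``target_dates``; a measurement exactly ``window_days`` away
    still fills, one day beyond does not.
    """
    return _nearest_within(series, target_dates, window_days, "nearest_15d")


def fill_clinical(series: pd.Series, target_dates: pd.DatetimeIndex,
                  max_days: int = CLINICAL_WINDOW_DAYS_DEFAULT
                  ) -> tuple[pd.Series, pd.Series]:
    """Clinical-score fill: nearest visit within 9 months either direction."""
    return _nearest_within(series, target_dates, max_days, "clinical_filled_9m")


def forward_fill_lesions(values: pd.Series, src: pd.Series
                         ) -> tuple[pd.Series, pd.Series]:
    """Carry the last observed lesion volume forward over later gaps.

    No fill occurs before the first observation; filling is idempotent.
    """
    values = values.copy()
    src = src.copy()
    filled = values.ffill()
    newly = values.isna() & filled.notna()
    values[newly] = filled[newly]
    src[newly] = "forward_filled"
    return values, src


def backward_fill_parenchyma(values: pd.Series, src: pd.Series
                             ) -> tuple[pd.Series, pd.Series]:
    """Carry the next observed parenchymal value backwards over earlier gaps.

    No fill occurs after the last observation; filling is idempotent.
    """
    values = values.copy()
    src = src.copy()
    filled = values.bfill()
    newly = values.isna() & filled.notna()
    values[newly] = filled[newly]
    src[newly] = "backward_filled"
    return values, src


def _series_for(frame: pd.DataFrame, col: str) -> pd.Series:
    if frame is None or not len(frame) or col not in frame.columns:
        return pd.Series(dtype=float)
    s = pd.Series(frame[col].to_numpy(dtype=float),
                  index=pd.to_datetime(frame["date"]))
    return s.dropna()


def match_patient(clinical: pd.DataFrame, brain: pd.DataFrame,
                  cord: pd.DataFrame,
                  mucca_series: pd.Series | None = None,
                  mucca_source: pd.Series | None = None,
                  window_days: int = WINDOW_DAYS_DEFAULT,
                  clinical_window_days: int = CLINICAL_WINDOW_DAYS_DEFAULT
                  ) -> pd.DataFrame:
    """Match one patient's streams; returns a wide frame indexed by date with
    a value column and a ``<col>_src`` provenance column per measure."""
    dates = unify_dates(clinical, brain, cord)
    out = pd.DataFrame(index=dates)
    out.index.name = "date"

    measure_frames = {}
    for col in CEREBRAL_SUBCOMPARTMENTS + INFRATENTORIAL_SUBCOMPARTMENTS:
        measure_frames[col] = _series_for(brain, col)
    for col in CORD_SUBCOMPARTMENTS:
        measure_frames[col] = _series_for(cord, col)
    measure_frames["p_cereb"] = _series_for(brain, "p_cereb")
    measure_frames["p_infra"] = _series_for(brain, "p_infra")
    if mucca_series is not None:
        measure_frames["mucca_mm2"] = mucca_series.dropna().sort_index()
    else:
        measure_frames["mucca_mm2"] = _series_for(cord, "mucca_mm2")

    for col in LESION_MEASURES:
        values, src = nearest_fill(measure_frames[col], dates, window_days)
        values, src = forward_fill_lesions(values, src)
        out[col] = values
        out[col + "_src"] = src
    for col in PARENCHYMAL_MEASURES:
        values, src = nearest_fill(measure_frames[col], dates, window_days)
        values, src = backward_fill_parenchyma(values, src)
        out[col] = values
        out[col + "_src"] = src

    # mucca provenance of origin (cord scan vs calibrated brain T1) travels
    # with the value through the fills
    if mucca_source is not None and len(out):
        out["mucca_source"] = _carry_labels(
            measure_frames["mucca_mm2"], mucca_source, out, window_days)
    elif len(out):
        out["mucca_source"] = np.where(out["mucca_mm2"].notna(), "cord_mri", "")

    for col in CLINICAL_MEASURES:
        numeric = clinical.copy()
        if col == "ambulation_affected":
            numeric[col] = clinical[col].astype(float)
        values, src = fill_clinical(_series_for(numeric, col), dates,
                                    clinical_window_days)
        out[col] = values
        out[col + "_src"] = src

    # relapse flags are events: true only on the clinical date they were
    # attributed to, never filled
    relapse = pd.Series(False, index=dates)
    if len(clinical):
        flagged = pd.to_datetime(
            clinical.loc[clinical["relapse"].astype(bool), "date"])
        relapse[relapse.index.isin(flagged)] = True
    out["relapse"] = relapse

    # age is recomputed exactly at every unified date from the implied birth
    # date of the first clinical row carrying an age
    out["age"] = np.nan
    aged = clinical.dropna(subset=["age"]) if "age" in clinical.columns else clinical.iloc[0:0]
    if len(aged):
        ref_date = pd.Timestamp(aged["date"].iloc[0])
        ref_age = float(aged["age"].iloc[0])
        out["age"] = ref_age + (dates - ref_date).days / 365.25
    return out


def _carry_labels(measured_values: pd.Series, labels: pd.Series,
                  matched: pd.DataFrame, window_days: int) -> pd.Series:
    """Assign each matched mucca value the origin label of the measurement it
    was copied from (fills copy values, so the label follows the value's
    source date)."""
    out = pd.Series("", index=matched.index, dtype=object)
    measured_values = measured_values.dropna().sort_index()
    labels = labels.reindex(measured_values.index)
    vals = matched["mucca_mm2"]
    src = matched["mucca_mm2_src"]
    m_dates = measured_values.index.to_numpy()
    for t in matched.index:
        if pd.isna(vals[t]):
            continue
        stage = src[t]
        t64 = np.datetime64(t)
        if stage == "measured":
            out[t] = labels.loc[t]
        elif stage == "nearest_15d":
            dist = np.abs(m_dates - t64)
            inside = np.flatnonzero(dist <= np.timedelta64(window_days, "D"))
            best = dist[inside].min()
            cand = inside[dist[inside] == best]
            pick = cand[np.argmin(m_dates[cand])]
            out[t] = labels.iloc[pick]
        elif stage == "backward_filled":
            later = np.flatnonzero(m_dates > t64)
            if len(later):
                out[t] = labels.iloc[later[0]]
        elif stage == "forward_filled":
            earlier = np.flatnonzero(m_dates < t64)
            if len(earlier):
                out[t] = labels.iloc[earlier[-1]]
    return out


def match_cohort(clinical: pd.DataFrame, brain: pd.DataFrame, cord: pd.DataFrame,
                 mucca_by_patient: dict[str, tuple[pd.Series, pd.Series]] | None = None,
                 window_days: int = WINDOW_DAYS_DEFAULT,
                 clinical_window_days: int = CLINICAL_WINDOW_DAYS_DEFAULT
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Match every patient; returns (matched frame, provenance counts).

    The matched frame has one row per (patient_id, date) with value and
    ``_src`` columns per measure.  The counts frame tabulates provenance
    per measure over all rows.  Input row order is irrelevant: streams are
    sorted per patient before matching.
    """
    patients = sorted(set(clinical["patient_id"]) | set(brain["patient_id"])
                      | set(cord["patient_id"]))
    pieces = []
    for pid in patients:
        cl = clinical[clinical["patient_id"] == pid].sort_values("date")
        br = brain[brain["patient_id"] == pid].sort_values("date")
        co = cord[cord["patient_id"] == pid].sort_values("date")
        mucca_series = mucca_source = None
        if mucca_by_patient is not None and pid in mucca_by_patient:
            mucca_series, mucca_source = mucca_by_patient[pid]
        piece = match_patient(cl, br, co, mucca_series, mucca_source,
                              window_days, clinical_window_days)
        piece.insert(0, "patient_id", pid)
        pieces.append(piece.reset_index())
    if not pieces:
        raise ValueError("no patients to match")
    matched = pd.concat(pieces, ignore_index=True)

    src_cols = [c for c in matched.columns if c.endswith("_src")]
    counts = (matched[src_cols]
              .apply(lambda s: s.value_counts())
              .fillna(0).astype(int).T)
    counts.index = [c[:-4] for c in counts.index]
    counts.index.name = "measure"
    return matched, counts
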