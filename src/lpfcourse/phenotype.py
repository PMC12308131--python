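"""Classify progressing (RRMS -> SPMS) versus non-progressing patients from
longitudinal clinical series, and date the onset of progression.

The transition to secondary progressive MS is called retrospectively
from relapse-free disability progression via either of two pathways:

``edss_gt4``
    A sustained, relapse-free EDSS increase (>= 1.0 point over the
    roving reference when the reference is below 6.0, >= 0.5 otherwise,
    the usual MSBase step sizes), confirmed at the next visit at least
    three months later, with the EDSS subsequently exceeding 4.0.

``fss_two_step``
    Any single functional system score increasing by at least two steps
    over its roving reference, relapse-free and confirmed at the next
    visit at least three months later.  This pathway admits progression
    that is not purely ambulatory.

The reference is a roving baseline: it starts at the first score and is
reset only by *confirmed* changes (a lower score confirmed at the next
visit at least three months later resets it downwards; a confirmed
progression event resets it upwards), so an isolated noisy dip or spike
cannot move it.

An increase is relapse-free when no relapse is attributed to a window
around its date (default 90 days before to 30 days after).  The onset
of progression is the date of the first relapse-free increase in EDSS
or any FSS at or before the first qualifying confirmed event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FSS_COLUMNS

CONFIRMATION_DAYS_DEFAULT = 91        # "sustained": confirmed >= 3 months later
RELAPSE_WINDOW_BEFORE_DAYS = 90
RELAPSE_WINDOW_AFTER_DAYS = 30


@dataclass(frozen=True)
class PhenotypeCall:
    patient_id: str
    progressing: bool
    onset_date: pd.Timestamp | None
    pathway: str  # edss_gt4 | fss_two_step | none

    def __post_init__(self):
        if self.progressing and (self.onset_date is None or self.pathway == "none"):
            raise ValueError("progressing call requires onset date and pathway")


def relapse_free(date: pd.Timestamp, relapse_dates,
                 before_days: int = RELAPSE_WINDOW_BEFORE_DAYS,
                 after_days: int = RELAPSE_WINDOW_AFTER_DAYS) -> bool:
    """True iff no relapse falls in [date - before_days, date + after_days].

    The window is the attribution window of a disability increase: an
    increase that closely follows (or is immediately followed by) a
    relapse is attributed to relapse activity, not progression.
    """
    return _relapse_free(date, relapse_dates, before_days, after_days)


def _relapse_free(date, relapse_dates, before_days, after_days) -> bool:
    date = pd.Timestamp(date)
    for r in relapse_dates:
        delta = (date - pd.Timestamp(r)).days
        # relapse up to `before_days` before or `after_days` after the increase
        if -after_days <= delta <= before_days:
            return False
    return True


def _edss_step(reference: float) -> float:
    return 1.0 if reference < 6.0 else 0.5


def _confirming_value(dates, values, i: int, confirmation_days: int):
    """Value at the first visit >= confirmation_days after visit i, or None."""
    for j in range(i + 1, len(values)):
        if (dates[j] - dates[i]).days >= confirmation_days:
            return None if np.isnan(values[j]) else float(values[j])
    return None


def _sustained_events(dates: np.ndarray, values: np.ndarray,
                      step_fn, relapse_dates,
                      confirmation_days: int,
                      before_days: int, after_days: int) -> list[int]:
    """Indices of relapse-free increases over the confirmed roving reference
    that are themselves confirmed at the next visit >= confirmation_days
    later.  Confirmed improvements reset the reference downwards."""
    events = []
    ref = float(values[0]) if not np.isnan(values[0]) else np.nan
    for i in range(1, len(values)):
        if np.isnan(values[i]):
            continue
        if np.isnan(ref):
            ref = float(values[i])
            continue
        step = step_fn(ref)
        if values[i] >= ref + step:
            conf = _confirming_value(dates, values, i, confirmation_days)
            if conf is not None and conf >= ref + step \
                    and _relapse_free(dates[i], relapse_dates,
                                      before_days, after_days):
                events.append(i)
                ref = float(values[i])  # baseline roves up after confirmation
        elif values[i] < ref:
            conf = _confirming_value(dates, values, i, confirmation_days)
            if conf is not None and conf <= values[i]:
                ref = float(values[i])  # confirmed improvement roves down
    return events


def _first_increase_onset(visits: pd.DataFrame, event_date: pd.Timestamp,
                          relapse_dates, before_days, after_days
                          ) -> pd.Timestamp:
    """Earliest relapse-free increase (EDSS or any FSS) at or before the
    qualifying event; falls back to the event date itself."""
    candidates = []
    for col in ("edss",) + FSS_COLUMNS:
        if col not in visits.columns:
            continue
        sub = visits.dropna(subset=[col])
        vals = sub[col].to_numpy(dtype=float)
        dts = pd.to_datetime(sub["date"]).to_numpy()
        for i in range(1, len(vals)):
            if vals[i] > np.nanmin(vals[:i]):
                d = pd.Timestamp(dts[i])
                if d <= event_date and _relapse_free(d, relapse_dates,
                                                     before_days, after_days):
                    candidates.append(d)
                    break
    return min(candidates) if candidates else pd.Timestamp(event_date)


def classify_spms(visits: pd.DataFrame,
                  confirmation_days: int = CONFIRMATION_DAYS_DEFAULT,
                  relapse_before_days: int = RELAPSE_WINDOW_BEFORE_DAYS,
                  relapse_after_days: int = RELAPSE_WINDOW_AFTER_DAYS
                  ) -> PhenotypeCall:
    """Classify a single patient's visit series.

    ``visits`` must carry ``date``, ``edss``, ``relapse`` and may carry
    the seven FSS columns.  Requires at least two visits with EDSS.
    """
    visits = visits.sort_values("date").reset_index(drop=True)
    pid = str(visits["patient_id"].iloc[0]) if "patient_id" in visits.columns else ""
    edss = visits.dropna(subset=["edss"])
    if len(edss) < 2:
        raise ValueError(f"patient {pid!r}: need >= 2 visits with EDSS")
    if "relapse" in visits.columns:
        relapse_dates = pd.to_datetime(
            visits.loc[visits["relapse"].astype(bool), "date"]).tolist()
    else:
        relapse_dates = []

    dates = pd.to_datetime(edss["date"]).to_numpy()
    dates = np.array([pd.Timestamp(d) for d in dates], dtype=object)
    values = edss["edss"].to_numpy(dtype=float)

    # pathway (a): sustained relapse-free EDSS increase reaching EDSS > 4
    edss_events = _sustained_events(dates, values, _edss_step, relapse_dates,
                                    confirmation_days, relapse_before_days,
                                    relapse_after_days)
    for i in edss_events:
        if np.nanmax(values[i:]) > 4.0:
            onset = _first_increase_onset(visits, dates[i], relapse_dates,
                                          relapse_before_days, relapse_after_days)
            return PhenotypeCall(pid, True, onset, "edss_gt4")

    # pathway (b): any FSS increasing by >= 2 steps, relapse-free, sustained
    for col in FSS_COLUMNS:
        if col not in visits.columns:
            continue
        sub = visits.dropna(subset=[col])
        if len(sub) < 2:
            continue
        f_dates = np.array([pd.Timestamp(d) for d in
                            pd.to_datetime(sub["date"]).to_numpy()], dtype=object)
        f_vals = sub[col].to_numpy(dtype=float)
        events = _sustained_events(f_dates, f_vals, lambda ref: 2.0,
                                   relapse_dates, confirmation_days,
                                   relapse_before_days, relapse_after_days)
        if events:
            onset = _first_increase_onset(visits, f_dates[events[0]],
                                          relapse_dates, relapse_before_days,
                                          relapse_after_days)
            return PhenotypeCall(pid, True, onset, "fss_two_step")

    return PhenotypeCall(pid, False, None, "none")


def classify_cohort(clinical: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Classify every patient; returns a frame with columns
    ``patient_id, progressing, onset_date, pathway``."""
    rows = []
    for pid, sub in clinical.groupby("patient_id", sort=True):
        call = classify_spms(sub, **kwargs)
        rows.append({"patient_id": pid, "progressing": call.progressing,
                     "onset_date": call.onset_date, "pathway": call.pathway})
    return pd.DataFrame(rows)
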