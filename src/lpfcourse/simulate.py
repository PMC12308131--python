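"""Synthetic longitudinal MS cohort generator.

Emulates the statistical structure the LPF analysis assumes, so every
downstream stage is testable without patient data:

* per-patient visit schedules over five-plus years, with clinical and
  MRI dates on separate grids and jittered against each other;
* punctate lesion accrual per subcompartment: a homogeneous Poisson
  process per compartment with lognormal per-lesion volumes (lesions,
  once formed, are permanent, so lesion volume is a nondecreasing step
  function); accrual starts years before the observation window (the
  pre-baseline disease duration), and a per-patient frailty multiplier
  spreads overall burden across patients, so between-patient burden
  variation dominates within-patient growth the way it does in an
  established-MS cohort;
* monotone-trending parenchymal decline with small measurement noise;
* EDSS and FSS trajectories driven by a latent weighted-LPF-percentile
  signal with compartment weights favouring cord > infratentorial >
  cerebral, quantized to the EDSS grid and clipped;
* progressing vs non-progressing phenotypes with a generative onset
  change point (elevated cord + infratentorial lesion rates and faster
  decline after onset);
* missing cord scans and a relapse flag stream.

Phenotype labels in :class:`SyntheticTruth` are ground truth of the
noiseless latent process: each patient's trajectory is re-drawn (with
escalated or damped rates) until the latent EDSS/FSS series classifies
to the designated phenotype under the same relapse-free progression
rules :func:`lpfcourse.phenotype.classify_spms` applies to observed
data.  Progressing patients additionally reach a latent EDSS peak of at
least 5.0, and non-progressing patients may neither combine a peak
above 4.0 with a latent run-up close to the progression step nor reach
the narrow-step EDSS >= 6 regime, so phenotypes are separated by a
margin rather than sitting on the decision boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import lpf, phenotype
from .config import CohortConfig, ConfigError
from .io import (
    BRAIN_MRI_COLUMNS,
    CEREBRAL_SUBCOMPARTMENTS,
    CLINICAL_COLUMNS,
    COMPARTMENTS,
    CORD_MRI_COLUMNS,
    CORD_SUBCOMPARTMENTS,
    EDSS_GRID,
    INFRATENTORIAL_SUBCOMPARTMENTS,
)

DAYS_PER_YEAR = 365.25

#: Baseline parenchymal measures: normalized volumes (ml) for the brain
#: compartments, mucca (mm^2) for the cord.
PARENCHYMA_BASELINE_MEAN = {"cereb": 1050.0, "infra": 155.0, "cord": 72.0}
PARENCHYMA_BASELINE_SD = {"cereb": 45.0, "infra": 8.0, "cord": 5.0}

#: Lognormal shape parameter of per-lesion volumes.
LESION_VOLUME_SIGMA = 0.6

#: True quadratic map from brain-T1-derived mucca b to cord-MRI mucca:
#: cord = C0 + C1*b + C2*b^2 (the calibration the pipeline re-estimates).
MUCCA_CAL_TRUTH = (5.0, 0.85, 0.0008)
MUCCA_BRAIN_NOISE_SD = 0.6

SUBCOMPARTMENTS = {
    "cereb": CEREBRAL_SUBCOMPARTMENTS,
    "infra": INFRATENTORIAL_SUBCOMPARTMENTS,
    "cord": CORD_SUBCOMPARTMENTS,
}
_DIRICHLET_ALPHA = {
    "cereb": (2.0, 3.0, 3.0),
    "infra": (1.0, 2.0, 1.0, 2.0),
    "cord": (2.0, 2.0),
}

_EDSS_GRID_ARR = np.asarray(EDSS_GRID, dtype=float)

#: FSS generated from the latent per-compartment contribution s_k:
#: (fss column, compartment, multiplier, max score).  Pyramidal, sensory
#: and bowel/bladder map to the cord, brainstem and cerebellar to the
#: infratentorium, mental to the cerebrum; visual has no MRI correlate.
_FSS_MAP = (
    ("fss_pyramidal", "cord", 1.1, 6),
    ("fss_sensory", "cord", 0.9, 6),
    ("fss_bowel_bladder", "cord", 0.7, 6),
    ("fss_brainstem", "infra", 0.9, 5),
    ("fss_cerebellar", "infra", 1.0, 5),
    ("fss_mental", "cereb", 0.9, 5),
)

#: Pre-baseline disease duration (years of lesion accrual and decline
#: before the observation window), drawn uniformly per phenotype.
DISEASE_DURATION_RANGE = {True: (2.0, 16.0), False: (2.0, 15.0)}
#: Lognormal sigma of the per-patient lesion-rate frailty multiplier
#: (mean 1); spreads cross-sectional burden across orders of magnitude.
LESION_FRAILTY_SIGMA = 0.9
DECLINE_FRAILTY_SIGMA = 0.4

MAX_REDRAW_ATTEMPTS = 10
MAX_COHORT_ROUNDS = 4
#: phenotype margins on the latent EDSS series
PROGRESSING_LATENT_PEAK_MIN = 5.0
NONPROGRESSING_BOUNDARY_PEAK = 4.0
NONPROGRESSING_BOUNDARY_RUNUP = 0.75
#: non-progressing patients stay out of the EDSS >= 6 regime, where the
#: progression step narrows to 0.5 and the decision boundary is thin
NONPROGRESSING_LATENT_PEAK_MAX = 5.5


def snap_to_edss_grid(values) -> np.ndarray:
    """Snap to the nearest valid EDSS value (ties toward the lower value)
    and clip to [0, 10]."""
    v = np.atleast_1d(np.asarray(values, dtype=float))
    v = np.clip(v, 0.0, 10.0)
    idx = np.searchsorted(_EDSS_GRID_ARR, v)
    idx = np.clip(idx, 1, len(_EDSS_GRID_ARR) - 1)
    lo = _EDSS_GRID_ARR[idx - 1]
    hi = _EDSS_GRID_ARR[idx]
    out = np.where(v - lo <= hi - v, lo, hi)
    out[v <= _EDSS_GRID_ARR[0]] = _EDSS_GRID_ARR[0]
    return out if np.ndim(values) else float(out[0])


@dataclass
class SyntheticTruth:
    """Generative ground truth of a synthetic cohort."""

    true_weights: dict[str, float]
    progressing: dict[str, bool] = field(default_factory=dict)
    onset_date: dict[str, "pd.Timestamp | None"] = field(default_factory=dict)
    latent_edss: dict[str, "pd.Series"] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_weights": self.true_weights,
            "patients": {
                pid: {
                    "progressing": bool(self.progressing[pid]),
                    "onset_date": (self.onset_date[pid].strftime("%Y-%m-%d")
                                   if self.onset_date[pid] is not None else None),
                    "latent_edss": {
                        d.strftime("%Y-%m-%d"): float(v)
                        for d, v in self.latent_edss[pid].items()},
                }
                for pid in sorted(self.progressing)
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        truth = cls(true_weights=payload["true_weights"])
        for pid, entry in payload["patients"].items():
            truth.progressing[pid] = bool(entry["progressing"])
            truth.onset_date[pid] = (pd.Timestamp(entry["onset_date"])
                                     if entry["onset_date"] else None)
            series = pd.Series({pd.Timestamp(k): float(v)
                                for k, v in entry["latent_edss"].items()})
            truth.latent_edss[pid] = series.sort_index()
        return truth


@dataclass
class PatientParams:
    """Static (re-draw-invariant) parameters of one synthetic patient."""

    pid: str
    progressing: bool
    followup_years: float
    disease_duration_years: float           # years of disease before baseline
    lesion_frailty: float                   # per-patient lesion-rate multiplier
    decline_frailty: float                  # per-patient decline multiplier
    baseline_age: float
    baseline_date: pd.Timestamp
    onset_years: float | None               # change point, years from baseline
    clinical_dates: pd.DatetimeIndex
    mri_dates: pd.DatetimeIndex
    cord_dates: pd.DatetimeIndex            # subset of mri_dates with a cord scan
    scanners: list[str]
    shares: dict[str, np.ndarray]           # subcompartment split per compartment
    p0: dict[str, float]
    visual_fss: int
    relapse_dates: pd.DatetimeIndex


@dataclass
class PatientTrajectory:
    """One realization of a patient's lesion/parenchymal process."""

    params: PatientParams
    lesion_events: dict[str, tuple[np.ndarray, np.ndarray]]  # times (yr), volumes
    parenchyma_noise: dict[str, np.ndarray]                  # per MRI date factor
    mucca_brain_noise: np.ndarray

    def lesion_volume(self, comp: str, t_years) -> np.ndarray:
        """Cumulative lesion volume (ml): nondecreasing step function."""
        times, vols = self.lesion_events[comp]
        t = np.atleast_1d(np.asarray(t_years, dtype=float))
        out = np.array([vols[times <= ti].sum() for ti in t])
        return out if np.ndim(t_years) else float(out[0])

    def parenchyma_true(self, comp: str, t_years) -> np.ndarray:
        """Noise-free parenchymal measure: exponential-style decline running
        since disease onset (pre-baseline duration included), with an
        accelerated rate after the progression change point."""
        p = self.params
        cfg_decline = self._decline[comp]
        t = np.atleast_1d(np.asarray(t_years, dtype=float))
        if p.onset_years is None:
            exponent_pre, exponent_post = t, np.zeros_like(t)
        else:
            exponent_pre = np.minimum(t, p.onset_years)
            exponent_post = np.maximum(t - p.onset_years, 0.0)
        base = (1.0 - cfg_decline) ** (exponent_pre + p.disease_duration_years)
        accel = (1.0 - cfg_decline * self._decline_mult) ** exponent_post
        out = p.p0[comp] * base * accel
        return out if np.ndim(t_years) else float(out[0])

    # set by the generator
    _decline: dict[str, float] = field(default_factory=dict)
    _decline_mult: float = 1.0


# --------------------------------------------------------------------------
# Static patient parameters
# --------------------------------------------------------------------------

def _jittered_grid(baseline: pd.Timestamp, interval_months: float,
                   followup_years: float, jitter_days: int,
                   rng: np.random.Generator) -> pd.DatetimeIndex:
    n = int(np.floor(followup_years * 12.0 / interval_months)) + 1
    offsets_days = np.round(np.arange(n) * interval_months / 12.0 * DAYS_PER_YEAR)
    if jitter_days > 0:
        offsets_days = offsets_days + rng.integers(-jitter_days, jitter_days + 1,
                                                   size=n)
    offsets_days = np.maximum(offsets_days, 0)
    dates = baseline + pd.to_timedelta(np.sort(offsets_days), unit="D")
    return pd.DatetimeIndex(sorted(set(dates)))


def _draw_patient_params(i: int, progressing: bool, no_cord: bool,
                         config: CohortConfig) -> PatientParams:
    rng = np.random.default_rng(np.random.SeedSequence([_seed_key(config), i, 0]))
    pid = f"P{i + 1:03d}"
    followup = rng.uniform(*config.followup_years_range)
    duration = rng.uniform(*DISEASE_DURATION_RANGE[progressing])
    lesion_frailty = float(rng.lognormal(-LESION_FRAILTY_SIGMA ** 2 / 2.0,
                                         LESION_FRAILTY_SIGMA))
    decline_frailty = float(rng.lognormal(-DECLINE_FRAILTY_SIGMA ** 2 / 2.0,
                                          DECLINE_FRAILTY_SIGMA))
    baseline_age = rng.uniform(*config.baseline_age_range)
    baseline_date = (pd.Timestamp("2011-01-01")
                     + pd.to_timedelta(int(rng.integers(0, 1096)), unit="D"))
    onset_years = float(rng.uniform(0.25, 0.6) * followup) if progressing else None

    clinical_dates = _jittered_grid(baseline_date,
                                    config.clinical_visit_interval_months,
                                    followup, config.date_jitter_days, rng)
    mri_dates = _jittered_grid(baseline_date, config.mri_interval_months,
                               followup, config.date_jitter_days, rng)
    if no_cord:
        cord_dates = pd.DatetimeIndex([])
    elif config.cord_scan_availability >= 1.0:
        cord_dates = mri_dates
    else:
        keep = rng.random(len(mri_dates)) < config.cord_scan_availability
        if not keep.any():
            keep[rng.integers(0, len(mri_dates))] = True
        cord_dates = mri_dates[keep]

    scanners = [f"scanner_{int(rng.integers(0, config.n_scanners)) + 1}"
                for _ in range(len(mri_dates))]
    shares = {comp: rng.dirichlet(_DIRICHLET_ALPHA[comp]) for comp in COMPARTMENTS}
    p0 = {comp: float(rng.normal(PARENCHYMA_BASELINE_MEAN[comp],
                                 PARENCHYMA_BASELINE_SD[comp]))
          for comp in COMPARTMENTS}
    p0 = {c: max(v, 0.5 * PARENCHYMA_BASELINE_MEAN[c]) for c, v in p0.items()}
    visual_fss = int(rng.random() < 0.2)

    n_relapses = rng.poisson(config.relapse_rate_per_year * followup)
    relapse_times = np.sort(rng.uniform(0.0, followup, size=n_relapses))
    relapse_dates = baseline_date + pd.to_timedelta(
        np.round(relapse_times * DAYS_PER_YEAR), unit="D")

    return PatientParams(
        pid=pid, progressing=progressing, followup_years=followup,
        disease_duration_years=duration, lesion_frailty=lesion_frailty,
        decline_frailty=decline_frailty,
        baseline_age=baseline_age, baseline_date=baseline_date,
        onset_years=onset_years, clinical_dates=clinical_dates,
        mri_dates=mri_dates, cord_dates=cord_dates, scanners=scanners,
        shares=shares, p0=p0, visual_fss=visual_fss,
        relapse_dates=pd.DatetimeIndex(relapse_dates),
    )


def _seed_key(config: CohortConfig) -> int:
    return int(config.seed) % (2 ** 31)


# --------------------------------------------------------------------------
# Trajectory realization
# --------------------------------------------------------------------------

def generate_patient_trajectory(params: PatientParams, config: CohortConfig,
                                rng: np.random.Generator,
                                rate_scale: float = 1.0,
                                decline_scale: float = 1.0) -> PatientTrajectory:
    """Draw one lesion/parenchymal realization for a patient.

    Lesion accrual per compartment is a homogeneous Poisson process with
    lognormal per-lesion volumes; for progressing patients the cord and
    infratentorial rates are multiplied by the progression multiplier
    after the onset change point.  ``rate_scale``/``decline_scale``
    escalate or damp the process on phenotype re-draws.
    """
    if len(params.clinical_dates) < 1:
        raise ValueError("follow-up must contain at least one clinical visit")
    T = params.followup_years
    start = -params.disease_duration_years   # accrual since disease onset
    events: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for comp in COMPARTMENTS:
        base_rate = (getattr(config.lesion_rate_per_year, comp)
                     * params.lesion_frailty * rate_scale)
        segments = []
        if params.progressing and comp in ("cord", "infra"):
            onset = params.onset_years
            post_rate = base_rate * config.progression_rate_multiplier
            segments = [(start, onset, base_rate), (onset, T, post_rate)]
        else:
            segments = [(start, T, base_rate)]
        times = []
        for lo, hi, rate in segments:
            n = rng.poisson(rate * (hi - lo))
            times.append(rng.uniform(lo, hi, size=n))
        times = np.sort(np.concatenate(times)) if times else np.empty(0)
        mean_vol = getattr(config.lesion_size_mean_ml, comp)
        mu = np.log(mean_vol) - LESION_VOLUME_SIGMA ** 2 / 2.0
        vols = rng.lognormal(mu, LESION_VOLUME_SIGMA, size=len(times))
        events[comp] = (times, vols)

    noise = {comp: 1.0 + rng.normal(0.0, config.parenchyma_noise_frac,
                                    size=len(params.mri_dates))
             for comp in COMPARTMENTS}
    mucca_brain_noise = rng.normal(0.0, MUCCA_BRAIN_NOISE_SD,
                                   size=len(params.mri_dates))

    traj = PatientTrajectory(params=params, lesion_events=events,
                             parenchyma_noise=noise,
                             mucca_brain_noise=mucca_brain_noise)
    decline = config.parenchyma_decline_per_year.as_dict()
    traj._decline = {c: min(v * params.decline_frailty * decline_scale, 0.5)
                     for c, v in decline.items()}
    traj._decline_mult = (config.progression_decline_multiplier
                          if params.progressing else 1.0)
    return traj


def _years_from(baseline: pd.Timestamp, dates: pd.DatetimeIndex) -> np.ndarray:
    return (dates - baseline).days.to_numpy() / DAYS_PER_YEAR


def _brain_t1_mucca_from_true(true_mucca: np.ndarray,
                              noise: np.ndarray) -> np.ndarray:
    """Invert the true calibration map so that the quadratic fit of cord
    mucca on brain-T1 values recovers :data:`MUCCA_CAL_TRUTH`."""
    c0, c1, c2 = MUCCA_CAL_TRUTH
    disc = c1 ** 2 - 4.0 * c2 * (c0 - true_mucca)
    b = (-c1 + np.sqrt(disc)) / (2.0 * c2)
    return b + noise


# --------------------------------------------------------------------------
# Observed per-patient measurement tables
# --------------------------------------------------------------------------

def _measured_series(traj: PatientTrajectory) -> dict[str, pd.Series]:
    """Observed lesion totals and parenchymal measures per compartment at
    their scan dates (cord measures only at cord-scan dates)."""
    p = traj.params
    t_mri = _years_from(p.baseline_date, p.mri_dates)
    out: dict[str, pd.Series] = {}
    for comp in ("cereb", "infra"):
        out[f"l_{comp}"] = pd.Series(traj.lesion_volume(comp, t_mri),
                                     index=p.mri_dates)
        out[f"p_{comp}"] = pd.Series(
            traj.parenchyma_true(comp, t_mri) * traj.parenchyma_noise[comp],
            index=p.mri_dates)
    cord_mask = p.mri_dates.isin(p.cord_dates)
    t_cord = t_mri[cord_mask]
    out["l_cord"] = pd.Series(traj.lesion_volume("cord", t_cord),
                              index=p.mri_dates[cord_mask])
    out["p_cord"] = pd.Series(
        traj.parenchyma_true("cord", t_cord)
        * traj.parenchyma_noise["cord"][cord_mask],
        index=p.mri_dates[cord_mask])
    return out


def _fill_at(series: pd.Series, dates: pd.DatetimeIndex, mode: str,
             fallback: pd.Series | None = None) -> np.ndarray:
    """Value the analysis pipeline would see at ``dates``: forward-fill for
    lesions, backward-fill for parenchyma, nearest-scan fallback at the
    edges (before the first / after the last measurement)."""
    if series.empty:
        series = fallback if fallback is not None else series
    if series.empty:
        return np.full(len(dates), np.nan)
    series = series.sort_index()
    out = np.empty(len(dates))
    s_dates = series.index.to_numpy()
    s_vals = series.to_numpy(dtype=float)
    for k, d in enumerate(dates):
        d64 = np.datetime64(d)
        if mode == "ffill":
            pos = np.flatnonzero(s_dates <= d64)
            out[k] = s_vals[pos[-1]] if len(pos) else s_vals[0]
        else:
            pos = np.flatnonzero(s_dates >= d64)
            out[k] = s_vals[pos[0]] if len(pos) else s_vals[-1]
    return out


def _latent_features(traj: PatientTrajectory) -> dict[str, np.ndarray]:
    """Raw LPF and parenchymal values driving the latent disability signal
    at the patient's clinical dates, mirroring the pipeline's fill rules
    (measured lesion forward-filled, measured parenchyma back-filled);
    unmeasured streams fall back to the true underlying process."""
    p = traj.params
    series = _measured_series(traj)
    t_clin = _years_from(p.baseline_date, p.clinical_dates)
    out: dict[str, np.ndarray] = {}
    for comp in COMPARTMENTS:
        l_true = pd.Series(traj.lesion_volume(comp, t_clin), index=p.clinical_dates)
        p_true = pd.Series(traj.parenchyma_true(comp, t_clin), index=p.clinical_dates)
        l_obs = _fill_at(series[f"l_{comp}"], p.clinical_dates, "ffill",
                         fallback=l_true)
        p_obs = _fill_at(series[f"p_{comp}"], p.clinical_dates, "bfill",
                         fallback=p_true)
        out[f"l_{comp}"] = l_obs
        out[f"p_{comp}"] = p_obs
        out[f"lpf_{comp}"] = l_obs / p_obs
    return out


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

def _latent_edss_and_fss(features: dict[str, np.ndarray],
                         reference: dict[str, np.ndarray],
                         params: PatientParams, config: CohortConfig
                         ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Latent EDSS (continuous, unquantized) and FSS at clinical dates."""
    w = config.true_weights.as_dict()
    contrib = {}
    for comp in COMPARTMENTS:
        if config.link == "lpf":
            pct = lpf.percentile_of(features[f"lpf_{comp}"],
                                    reference[f"lpf_{comp}"])
            contrib[comp] = w[comp] * np.atleast_1d(pct)
        else:  # pv link: disability driven by parenchymal loss alone
            pct = lpf.percentile_of(features[f"p_{comp}"],
                                    reference[f"p_{comp}"])
            contrib[comp] = w[comp] * (100.0 - np.atleast_1d(pct))
    age0 = params.baseline_age + (params.clinical_dates[0]
                                  - params.baseline_date).days / DAYS_PER_YEAR
    latent = (config.edss_intercept + config.age_coeff * age0
              + sum(contrib.values()))
    fss = {}
    for col, comp, mult, top in _FSS_MAP:
        fss[col] = np.clip(np.round(mult * contrib[comp]), 0, top)
    fss["fss_visual"] = np.full(len(params.clinical_dates),
                                params.visual_fss, dtype=float)
    return latent, fss


def _latent_visit_frame(params: PatientParams, latent: np.ndarray,
                        fss: dict[str, np.ndarray],
                        config: CohortConfig) -> pd.DataFrame:
    edss = snap_to_edss_grid(latent) if config.quantize_edss \
        else np.clip(latent, 0.0, 10.0)
    frame = pd.DataFrame({"patient_id": params.pid,
                          "date": params.clinical_dates, "edss": edss})
    for col, values in fss.items():
        frame[col] = values
    frame["relapse"] = False
    return frame


def _latent_acceptable(params: PatientParams, latent: np.ndarray,
                       fss: dict[str, np.ndarray],
                       config: CohortConfig) -> bool:
    """True iff the noiseless latent series classifies (under the clinical
    progression rules) to the designated phenotype with a margin.

    Progressing patients must classify as progressing with a latent peak
    of at least 5.0.  Non-progressing patients must classify as
    non-progressing and may not sit near the decision boundary: a latent
    peak above EDSS 4 combined with a latent run-up close to the 1.0
    progression step is rejected, because measurement noise could then
    tip the observed classification."""
    frame = _latent_visit_frame(params, latent, fss, config)
    if len(frame.dropna(subset=["edss"])) < 2:
        return False
    call = phenotype.classify_spms(frame)
    peak = float(np.max(latent))
    if params.progressing:
        return call.progressing and peak >= PROGRESSING_LATENT_PEAK_MIN
    runup = float(np.max(latent - np.minimum.accumulate(latent)))
    near_boundary = ((peak > NONPROGRESSING_BOUNDARY_PEAK
                      and runup >= NONPROGRESSING_BOUNDARY_RUNUP)
                     or peak >= NONPROGRESSING_LATENT_PEAK_MAX)
    return (not call.progressing) and not near_boundary


def _pooled_reference(all_features: dict[str, dict[str, np.ndarray]]
                      ) -> dict[str, np.ndarray]:
    keys = [f"lpf_{c}" for c in COMPARTMENTS] + [f"p_{c}" for c in COMPARTMENTS]
    return {k: np.concatenate([f[k] for f in all_features.values()])
            for k in keys}


def generate_cohort(config: CohortConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                               SyntheticTruth]:
    """Generate (clinical, brain_mri, cord_mri, truth) for a full cohort.

    Deterministic under (config, seed): identical inputs yield
    byte-identical tables.
    """
    if config.cord_scan_availability <= 0.0 and config.frac_patients_without_cord < 1.0:
        raise ConfigError(
            "cord_scan_availability: must be positive (a cohort without any "
            "cord scans has no calibration anchor for cord modelling)")
    n = int(config.n_patients)
    seed_key = _seed_key(config)
    assign_rng = np.random.default_rng(np.random.SeedSequence([seed_key, 10 ** 6]))
    n_prog = int(round(config.frac_progressing * n))
    order = assign_rng.permutation(n)
    progressing_ids = set(order[:n_prog])
    n_no_cord = int(round(config.frac_patients_without_cord * n))
    no_cord_ids = set(assign_rng.permutation(n)[:n_no_cord])

    params_list = [
        _draw_patient_params(i, i in progressing_ids, i in no_cord_ids, config)
        for i in range(n)
    ]

    def draw(i: int, attempt: int) -> PatientTrajectory:
        rng = np.random.default_rng(
            np.random.SeedSequence([seed_key, i, 1 + attempt]))
        if params_list[i].progressing:
            scale, dscale = 1.6 ** attempt, 1.3 ** attempt
        else:
            scale, dscale = 0.55 ** attempt, 0.8 ** attempt
        return generate_patient_trajectory(params_list[i], config, rng,
                                           rate_scale=scale,
                                           decline_scale=dscale)

    attempts = [0] * n
    trajectories = [draw(i, 0) for i in range(n)]
    feats = {i: _latent_features(trajectories[i]) for i in range(n)}

    for _ in range(MAX_COHORT_ROUNDS):
        reference = _pooled_reference(feats)
        mismatched = []
        for i in range(n):
            latent, fss = _latent_edss_and_fss(feats[i], reference,
                                               params_list[i], config)
            if not _latent_acceptable(params_list[i], latent, fss, config):
                mismatched.append(i)
        if not mismatched:
            break
        for i in mismatched:
            for attempt in range(attempts[i] + 1, MAX_REDRAW_ATTEMPTS + 1):
                candidate = draw(i, attempt)
                cand_feats = _latent_features(candidate)
                latent, fss = _latent_edss_and_fss(cand_feats, reference,
                                                   params_list[i], config)
                if _latent_acceptable(params_list[i], latent, fss, config):
                    trajectories[i], feats[i], attempts[i] = candidate, cand_feats, attempt
                    break
            else:
                trajectories[i] = draw(i, MAX_REDRAW_ATTEMPTS)
                feats[i] = _latent_features(trajectories[i])
                attempts[i] = MAX_REDRAW_ATTEMPTS

    # final latent pass against the final pooled reference
    reference = _pooled_reference(feats)
    truth = SyntheticTruth(true_weights=config.true_weights.as_dict())
    clinical_rows, brain_rows, cord_rows = [], [], []
    for i in range(n):
        p = params_list[i]
        traj = trajectories[i]
        latent, fss = _latent_edss_and_fss(feats[i], reference, p, config)
        noise_rng = np.random.default_rng(np.random.SeedSequence([seed_key, i, 999]))
        noisy = latent + noise_rng.normal(0.0, config.edss_noise_sd,
                                          size=len(latent))
        edss = snap_to_edss_grid(noisy) if config.quantize_edss \
            else np.clip(noisy, 0.0, 10.0)

        truth.progressing[p.pid] = p.progressing
        truth.onset_date[p.pid] = (
            p.baseline_date + pd.to_timedelta(
                round(p.onset_years * DAYS_PER_YEAR), unit="D")
            if p.onset_years is not None else None)
        truth.latent_edss[p.pid] = pd.Series(latent, index=p.clinical_dates)

        ages = p.baseline_age + _years_from(p.baseline_date, p.clinical_dates)
        for k, date in enumerate(p.clinical_dates):
            row = {"patient_id": p.pid, "date": date, "age": float(ages[k]),
                   "edss": float(edss[k]),
                   "ambulation_affected": bool(edss[k] >= 4.0),
                   "relapse": bool(np.any(np.abs(
                       (p.relapse_dates - date).days) <= 45))
                   if len(p.relapse_dates) else False}
            for col in fss:
                row[col] = float(fss[col][k])
            clinical_rows.append(row)

        t_mri = _years_from(p.baseline_date, p.mri_dates)
        series = _measured_series(traj)
        true_mucca_at_mri = traj.parenchyma_true("cord", t_mri)
        brain_mucca = _brain_t1_mucca_from_true(true_mucca_at_mri,
                                                traj.mucca_brain_noise)
        for k, date in enumerate(p.mri_dates):
            row = {"patient_id": p.pid, "date": date,
                   "scanner_id": p.scanners[k]}
            for comp in ("cereb", "infra"):
                total = float(series[f"l_{comp}"].iloc[k])
                for sub, share in zip(SUBCOMPARTMENTS[comp], p.shares[comp]):
                    row[sub] = total * float(share)
            row["p_cereb"] = float(series["p_cereb"].iloc[k])
            row["p_infra"] = float(series["p_infra"].iloc[k])
            row["mucca_brain_t1_mm2"] = float(brain_mucca[k])
            brain_rows.append(row)
            if date in p.cord_dates:
                crow = {"patient_id": p.pid, "date": date,
                        "scanner_id": p.scanners[k]}
                total = float(series["l_cord"].loc[date])
                for sub, share in zip(SUBCOMPARTMENTS["cord"], p.shares["cord"]):
                    crow[sub] = total * float(share)
                crow["mucca_mm2"] = float(series["p_cord"].loc[date])
                cord_rows.append(crow)

    clinical = pd.DataFrame(clinical_rows, columns=list(CLINICAL_COLUMNS))
    brain = pd.DataFrame(brain_rows, columns=list(BRAIN_MRI_COLUMNS))
    cord = pd.DataFrame(cord_rows, columns=list(CORD_MRI_COLUMNS))
    for frame in (clinical, brain, cord):
        frame.sort_values(["patient_id", "date"], kind="stable", inplace=True,
                          ignore_index=True)
    return clinical, brain, cord, truth


# --------------------------------------------------------------------------
# Standalone missingness injection
# --------------------------------------------------------------------------

def inject_missingness(clinical: pd.DataFrame, brain: pd.DataFrame,
                       cord: pd.DataFrame, config: CohortConfig,
                       rng: np.random.Generator | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Remove cord-MRI rows for a fraction ``1 - cord_scan_availability`` of
    cord-scan dates, never removing a retained patient's last cord row.

    :func:`generate_cohort` already applies cord missingness; this
    standalone operation supports degrading an existing cohort further.
    """
    if config.cord_scan_availability <= 0.0:
        raise ConfigError(
            "cord_scan_availability: must be positive (no calibration anchor "
            "would remain for cord modelling)")
    if config.cord_scan_availability >= 1.0:
        return clinical, brain, cord
    rng = rng or np.random.default_rng(
        np.random.SeedSequence([_seed_key(config), 2 ** 20]))
    keep_rows = np.ones(len(cord), dtype=bool)
    for pid, sub in cord.groupby("patient_id"):
        drop = rng.random(len(sub)) >= config.cord_scan_availability
        if drop.all() and len(sub):
            drop[rng.integers(0, len(sub))] = False
        keep_rows[cord.index.get_indexer(sub.index)] &= ~drop
    return clinical, brain.copy(), cord[keep_rows].reset_index(drop=True)
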