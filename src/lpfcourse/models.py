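"""Linear EDSS-decoding models under leave-one-patient-out cross-validation.

Four model families describe the measured EDSS at each matched time
point as a linear combination of percentile-scaled MRI features plus
baseline age:

* ``LPF``: lesion parenchymal fraction percentile per compartment,
* ``LPV``: lesion volume and parenchymal volume percentiles per
  compartment (the reference model),
* ``LV``: lesion volume percentiles only,
* ``PV``: parenchymal volume percentiles only.

Every model is fitted by ordinary least squares with an intercept
(percentile predictors have mean near 50, so an intercept-free fit
would be badly biased; pass ``intercept=False`` for the literal
intercept-free equations).  Evaluation uses leave-one-patient-out
cross-validation: for each patient, the model is fitted on all other
patients and applied to the held-out patient's time points; metrics are
computed over the pooled held-out predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .io import COMPARTMENTS

MODEL_NAMES: tuple[str, ...] = ("LPF", "LPV", "LV", "PV")

_TERMS = {
    "LPF": ["lpf_cereb_pct", "lpf_infra_pct", "lpf_cord_pct", "age0"],
    "LPV": ["l_cereb_pct", "p_cereb_pct", "l_infra_pct", "p_infra_pct",
            "l_cord_pct", "p_cord_pct", "age0"],
    "LV": ["l_cereb_pct", "l_infra_pct", "l_cord_pct", "age0"],
    "PV": ["p_cereb_pct", "p_infra_pct", "p_cord_pct", "age0"],
}

#: LPF-model term per compartment, used for coefficient summaries.
LPF_COMPARTMENT_TERMS = {"cereb": "lpf_cereb_pct", "infra": "lpf_infra_pct",
                         "cord": "lpf_cord_pct"}


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; message names the collinear terms."""


@dataclass(frozen=True)
class ModelSpec:
    name: str
    terms: tuple[str, ...]

    @classmethod
    def named(cls, name: str, brain_only: bool = False) -> "ModelSpec":
        """Standard spec by name; ``brain_only`` drops the cord terms to give
        the brain-MRI-only variant."""
        if name not in _TERMS:
            raise KeyError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
        terms = [t for t in _TERMS[name] if not (brain_only and "cord" in t)]
        suffix = "_brain" if brain_only else ""
        return cls(name + suffix, tuple(terms))


@dataclass(frozen=True)
class FoldCoefficients:
    held_out_patient_id: str
    coefficients: dict[str, float]  # term -> value, including "intercept"


@dataclass(frozen=True)
class EvaluationReport:
    model: str
    pearson_r: float
    rmse: float
    mae_no_bias: float
    n_timepoints: int
    n_patients: int

    def to_dict(self) -> dict:
        return {"model": self.model, "pearson_r": self.pearson_r,
                "rmse": self.rmse, "mae_no_bias": self.mae_no_bias,
                "n_timepoints": self.n_timepoints, "n_patients": self.n_patients}

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(**d)


@dataclass
class CoefficientSummary:
    """Descriptive statistics of per-fold compartment coefficients.

    ``ratios`` scale each compartment's mean coefficient by the cerebral
    mean (cerebral == 1 by convention); ``density`` holds a Gaussian-kernel
    density curve per compartment (grid, value), or a spike marker when
    the fold coefficients are degenerate.
    """

    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    ratios: dict[str, float] | None = None
    density: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


# --------------------------------------------------------------------------
# Design and fitting
# --------------------------------------------------------------------------

def build_design(features: pd.DataFrame, spec: ModelSpec, intercept: bool = True
                 ) -> tuple[pd.DataFrame, np.ndarray, pd.Index]:
    """Design matrix for a model spec: columns in term order (plus an
    intercept column), response = measured EDSS, restricted to rows
    complete for the spec's terms."""
    needed = list(spec.terms) + ["edss"]
    complete = features[needed].notna().all(axis=1)
    rows = features[complete]
    if not len(rows):
        raise ValueError(f"no usable rows for model {spec.name}")
    X = rows[list(spec.terms)].astype(float).copy()
    if intercept:
        X["intercept"] = 1.0
    y = rows["edss"].to_numpy(dtype=float)
    return X, y, rows.index


def fit_least_squares(X: pd.DataFrame | np.ndarray, y: np.ndarray) -> np.ndarray:
    """Ordinary least squares, deterministic; raises
    :class:`RankDeficiencyError` naming collinear columns on a
    rank-deficient design."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(arr.shape[1])]
    # QR with column pivoting localizes the dependent columns
    from scipy.linalg import qr
    _, R, piv = qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(arr.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < arr.shape[1]:
        collinear = sorted(names[p] for p in piv[rank:])
        raise RankDeficiencyError(
            f"design is rank deficient (rank {rank} < {arr.shape[1]}); "
            f"collinear term(s): {collinear}")
    coef, *_ = np.linalg.lstsq(arr, np.asarray(y, dtype=float), rcond=None)
    return coef


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------

def rmse(y, y_hat) -> float:
    """Root mean squared error."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or len(y) < 2:
        raise ValueError("rmse needs two equal-length vectors of length >= 2")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def pearson(y, y_hat) -> float:
    """Pearson correlation; errors on zero-variance input."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or len(y) < 2:
        raise ValueError("pearson needs two equal-length vectors of length >= 2")
    if np.std(y) == 0 or np.std(y_hat) == 0:
        raise ValueError("pearson undefined for zero-variance input")
    yc = y - y.mean()
    hc = y_hat - y_hat.mean()
    return float(np.sum(yc * hc) / np.sqrt(np.sum(yc ** 2) * np.sum(hc ** 2)))


def mae_without_patient_bias(y, y_hat, patient_ids) -> float:
    """Mean absolute error after removing each patient's mean signed error.

    For patient p with rows R_p, bias_p = mean(y_hat - y over R_p); the
    statistic is the mean over all rows of |(y_hat - y) - bias_p|.  It
    measures how well within-patient *changes* are matched, ignoring a
    constant per-patient offset.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    pid = np.asarray(patient_ids)
    if not (len(y) == len(y_hat) == len(pid)):
        raise ValueError("inputs must share length")
    err = y_hat - y
    centered = np.empty_like(err)
    for p in np.unique(pid):
        mask = pid == p
        centered[mask] = err[mask] - err[mask].mean()
    return float(np.mean(np.abs(centered)))


# --------------------------------------------------------------------------
# Leave-one-patient-out cross-validation
# --------------------------------------------------------------------------

def loo_cv(features: pd.DataFrame, spec: ModelSpec, intercept: bool = True,
           clip_predictions: bool = False
           ) -> tuple[pd.DataFrame, list[FoldCoefficients]]:
    """One fold per patient: fit on all other patients, predict the held-out
    patient's usable time points.

    Returns (predictions, fold coefficients); predictions carry
    ``patient_id, date, edss, edss_hat``.  A fold whose training design
    is rank deficient is skipped with a warning.  Predicted EDSS is not
    clipped to [0, 10] unless ``clip_predictions`` is set.
    """
    import logging
    logger = logging.getLogger(__name__)

    X, y, idx = build_design(features, spec, intercept=intercept)
    pid = features.loc[idx, "patient_id"].to_numpy()
    patients = sorted(pd.unique(pid))
    if len(patients) < 3:
        raise ValueError("leave-one-patient-out needs >= 3 patients")
    pred_rows = []
    folds: list[FoldCoefficients] = []
    X_arr = X.to_numpy(dtype=float)
    for p in patients:
        test = pid == p
        train = ~test
        try:
            coef = fit_least_squares(
                pd.DataFrame(X_arr[train], columns=X.columns), y[train])
        except RankDeficiencyError as exc:
            logger.warning("fold %s skipped: %s", p, exc)
            continue
        y_hat = X_arr[test] @ coef
        if clip_predictions:
            y_hat = np.clip(y_hat, 0.0, 10.0)
        folds.append(FoldCoefficients(
            held_out_patient_id=str(p),
            coefficients={name: float(c) for name, c in zip(X.columns, coef)}))
        sub = features.loc[idx[test]]
        for (_, row), yh in zip(sub.iterrows(), y_hat):
            pred_rows.append({"patient_id": p, "date": row["date"],
                              "edss": float(row["edss"]), "edss_hat": float(yh)})
    predictions = pd.DataFrame(pred_rows,
                               columns=["patient_id", "date", "edss", "edss_hat"])
    return predictions, folds


def evaluate_predictions(predictions: pd.DataFrame, model: str) -> EvaluationReport:
    y = predictions["edss"].to_numpy(dtype=float)
    y_hat = predictions["edss_hat"].to_numpy(dtype=float)
    pid = predictions["patient_id"].to_numpy()
    return EvaluationReport(
        model=model,
        pearson_r=pearson(y, y_hat),
        rmse=rmse(y, y_hat),
        mae_no_bias=mae_without_patient_bias(y, y_hat, pid),
        n_timepoints=len(y),
        n_patients=len(np.unique(pid)),
    )


def summarize_coefficients(folds: list[FoldCoefficients],
                           compartment_terms: dict[str, str] | None = None
                           ) -> CoefficientSummary:
    """Mean/sd, cerebral-relative ratios, and Gaussian-kernel density curves
    (Silverman bandwidth) of the per-fold compartment coefficients."""
    if len(folds) < 2:
        raise ValueError("need >= 2 folds to summarize coefficients")
    terms = compartment_terms or LPF_COMPARTMENT_TERMS
    summary = CoefficientSummary()
    for comp, term in terms.items():
        values = np.array([f.coefficients[term] for f in folds], dtype=float)
        summary.mean[comp] = float(values.mean())
        summary.sd[comp] = float(values.std(ddof=1))
        if np.ptp(values) == 0:
            # degenerate distribution: represent as a spike at the value
            grid = np.array([values[0], values[0]])
            summary.density[comp] = (grid, np.array([np.inf, np.inf]))
        else:
            kde = gaussian_kde(values, bw_method="silverman")
            lo, hi = values.min(), values.max()
            pad = 0.5 * (hi - lo)
            grid = np.linspace(lo - pad, hi + pad, 256)
            summary.density[comp] = (grid, kde(grid))
    cereb_mean = summary.mean.get("cereb", 0.0)
    if cereb_mean != 0.0:
        summary.ratios = {c: summary.mean[c] / cereb_mean for c in terms}
    else:
        summary.ratios = None
    return summary


def compare_models(features: pd.DataFrame,
                   names: tuple[str, ...] = MODEL_NAMES,
                   intercept: bool = True
                   ) -> tuple[list[EvaluationReport], dict[str, pd.DataFrame]]:
    """Fit and evaluate the model family on identical time points.

    Rows are restricted to the intersection of usable rows across all
    specs so the comparison is not driven by differing completeness.
    Returns reports sorted by ascending RMSE plus the per-model held-out
    predictions.
    """
    specs = [ModelSpec.named(n) for n in names]
    usable = None
    for spec in specs:
        complete = features[list(spec.terms) + ["edss"]].notna().all(axis=1)
        usable = complete if usable is None else (usable & complete)
    shared = features[usable].reset_index(drop=True)
    reports = []
    predictions = {}
    for spec in specs:
        preds, _ = loo_cv(shared, spec, intercept=intercept)
        reports.append(evaluate_predictions(preds, spec.name))
        predictions[spec.name] = preds
    reports.sort(key=lambda r: r.rmse)
    return reports, predictions


def save_reports(reports: list[EvaluationReport], path: str | Path) -> None:
    Path(path).write_text(json.dumps([r.to_dict() for r in reports], indent=2))


def load_reports(path: str | Path) -> list[EvaluationReport]:
    return [EvaluationReport.from_dict(d) for d in json.loads(Path(path).read_text())]
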