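"""End-to-end orchestration: cohort tables -> matched time points ->
feature table -> fitted models.

Thin glue over the stage modules so the command line, the tests and the
reproduction script all run the identical path.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import lpf, matching, models
from .lpf import ExclusionReport, MuccaCalibration


@dataclass
class FeatureResult:
    matched: pd.DataFrame
    provenance_counts: pd.DataFrame
    features: pd.DataFrame
    exclusions: ExclusionReport
    calibration: MuccaCalibration


def build_features(clinical: pd.DataFrame, brain: pd.DataFrame,
                   cord: pd.DataFrame,
                   window_days: int = matching.WINDOW_DAYS_DEFAULT,
                   clinical_window_days: int = matching.CLINICAL_WINDOW_DAYS_DEFAULT
                   ) -> FeatureResult:
    """Resolve mucca (calibrating brain-T1 values where no cord scan
    exists), match the visit streams, and build the percentile feature
    table."""
    mucca_by_patient, calibration = lpf.resolve_mucca(
        brain, cord, pair_window_days=window_days)
    matched, counts = matching.match_cohort(
        clinical, brain, cord, mucca_by_patient=mucca_by_patient,
        window_days=window_days, clinical_window_days=clinical_window_days)
    features, exclusions = lpf.build_feature_table(matched)
    return FeatureResult(matched=matched, provenance_counts=counts,
                         features=features, exclusions=exclusions,
                         calibration=calibration)


def fit_all_models(features: pd.DataFrame, intercept: bool = True):
    """Compare the four model families and summarize the LPF-model
    coefficients; returns (reports, predictions, lpf_folds, summary)."""
    reports, predictions = models.compare_models(features, intercept=intercept)
    _, folds = models.loo_cv(features, models.ModelSpec.named("LPF"),
                             intercept=intercept)
    summary = models.summarize_coefficients(folds)
    return reports, predictions, folds, summary
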