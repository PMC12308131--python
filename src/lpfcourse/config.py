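"""Generative configuration of a synthetic longitudinal MS cohort.

The defaults emulate the structure of a modelling cohort of 78 RRMS
patients, half of whom transition to secondary progressive MS, followed
for at least five years with roughly six-monthly clinical visits and
yearly MRI, a minority of MRI time points lacking a cord scan, and
clinical/MRI visit dates jittered against each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .io import CompartmentTriple


class ConfigError(ValueError):
    """An invalid configuration field; the message names the field."""


def _triple(cord: float, infra: float, cereb: float) -> CompartmentTriple:
    return CompartmentTriple(cord=cord, infra=infra, cereb=cereb)


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Rates are events per year, sizes in ml, parenchymal decline as a
    fraction per year of the compartment's baseline measure (volume for
    the brain compartments, cord cross-sectional area for the cord).
    ``true_weights`` are the coefficients of the latent link
    ``EDSS = intercept + sum_k w_k * LPFpct_k + age_coeff * age0 + noise``
    with LPF percentiles taken against the cohort being generated; the
    default 0.038 : 0.025 : 0.010 encodes a cord > infratentorial >
    cerebral impact ratio of 3.8 : 2.5 : 1 on a scale where the weighted
    sum spans the EDSS range.
    """

    n_patients: int = 78
    frac_progressing: float = 0.5
    followup_years_range: tuple[float, float] = (6.0, 10.0)
    clinical_visit_interval_months: float = 6.0
    mri_interval_months: float = 12.0
    cord_scan_availability: float = 0.8
    lesion_rate_per_year: CompartmentTriple = field(
        default_factory=lambda: _triple(cord=0.35, infra=0.5, cereb=2.0))
    lesion_size_mean_ml: CompartmentTriple = field(
        default_factory=lambda: _triple(cord=0.06, infra=0.09, cereb=0.25))
    parenchyma_decline_per_year: CompartmentTriple = field(
        default_factory=lambda: _triple(cord=0.006, infra=0.004, cereb=0.005))
    true_weights: CompartmentTriple = field(
        default_factory=lambda: _triple(cord=0.038, infra=0.025, cereb=0.010))
    edss_noise_sd: float = 0.3
    date_jitter_days: int = 7
    n_scanners: int = 3
    seed: int = 0
    # latent-link constants
    edss_intercept: float = 0.0
    age_coeff: float = 0.01
    quantize_edss: bool = True
    link: str = "lpf"  # "lpf" or "pv" (EDSS driven by parenchymal loss only)
    # clinical event stream and phenotype structure
    relapse_rate_per_year: float = 0.3
    progression_rate_multiplier: float = 3.0
    progression_decline_multiplier: float = 2.0
    frac_patients_without_cord: float = 0.0
    baseline_age_range: tuple[float, float] = (25.0, 50.0)
    parenchyma_noise_frac: float = 0.002

    def __post_init__(self):
        for name in ("lesion_rate_per_year", "lesion_size_mean_ml",
                     "parenchyma_decline_per_year", "true_weights"):
            setattr(self, name, CompartmentTriple.from_any(getattr(self, name)))
        self.followup_years_range = tuple(float(v) for v in self.followup_years_range)
        self.baseline_age_range = tuple(float(v) for v in self.baseline_age_range)
        self.validate()

    def validate(self) -> None:
        if int(self.n_patients) != self.n_patients or self.n_patients < 1:
            raise ConfigError("n_patients: must be a positive integer")
        if not 0.0 <= self.frac_progressing <= 1.0:
            raise ConfigError("frac_progressing: must lie in [0, 1]")
        lo, hi = self.followup_years_range
        if lo <= 0 or hi < lo:
            raise ConfigError("followup_years_range: need 0 < lower <= upper")
        if self.clinical_visit_interval_months <= 0:
            raise ConfigError("clinical_visit_interval_months: must be positive")
        if self.mri_interval_months <= 0:
            raise ConfigError("mri_interval_months: must be positive")
        if not 0.0 <= self.cord_scan_availability <= 1.0:
            raise ConfigError("cord_scan_availability: must lie in [0, 1]")
        for name in ("lesion_rate_per_year", "lesion_size_mean_ml",
                     "parenchyma_decline_per_year", "true_weights"):
            triple = getattr(self, name)
            for comp, value in triple.as_dict().items():
                if value < 0:
                    raise ConfigError(f"{name}.{comp}: must be nonnegative")
        for comp, value in self.lesion_size_mean_ml.as_dict().items():
            if value <= 0:
                raise ConfigError(f"lesion_size_mean_ml.{comp}: must be positive")
        if self.edss_noise_sd < 0:
            raise ConfigError("edss_noise_sd: must be nonnegative")
        if int(self.date_jitter_days) != self.date_jitter_days or self.date_jitter_days < 0:
            raise ConfigError("date_jitter_days: must be a nonnegative integer")
        if int(self.n_scanners) != self.n_scanners or self.n_scanners < 1:
            raise ConfigError("n_scanners: must be a positive integer")
        if int(self.seed) != self.seed:
            raise ConfigError("seed: must be an integer")
        if self.link not in ("lpf", "pv"):
            raise ConfigError("link: must be 'lpf' or 'pv'")
        if self.relapse_rate_per_year < 0:
            raise ConfigError("relapse_rate_per_year: must be nonnegative")
        if self.progression_rate_multiplier < 1:
            raise ConfigError("progression_rate_multiplier: must be >= 1")
        if self.progression_decline_multiplier < 1:
            raise ConfigError("progression_decline_multiplier: must be >= 1")
        if not 0.0 <= self.frac_patients_without_cord <= 1.0:
            raise ConfigError("frac_patients_without_cord: must lie in [0, 1]")
        a_lo, a_hi = self.baseline_age_range
        if a_lo < 18 or a_hi < a_lo:
            raise ConfigError("baseline_age_range: need 18 <= lower <= upper")
        if self.parenchyma_noise_frac < 0:
            raise ConfigError("parenchyma_noise_frac: must be nonnegative")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for name in ("lesion_rate_per_year", "lesion_size_mean_ml",
                     "parenchyma_decline_per_year", "true_weights"):
            d[name] = getattr(self, name).as_dict()
        d["followup_years_range"] = list(self.followup_years_range)
        d["baseline_age_range"] = list(self.baseline_age_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
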