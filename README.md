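# lpfcourse

Lesion parenchymal fraction (LPF) analysis of multiple sclerosis disease
course, with a built-in synthetic cohort generator for end-to-end testing.

In MS, the clinical impact of a T2 lesion depends on where it sits: a small
spinal-cord lesion disables far more than the same volume of cerebral white
matter. The **lesion parenchymal fraction** captures this by dividing the
regional lesion volume by the regional parenchymal volume, per compartment —
spinal cord, infratentorial, and cerebral. Expressed as within-study
percentiles and combined linearly, the three compartment LPFs track the EDSS
(Expanded Disability Status Scale) far better than raw lesion volumes or
atrophy alone, and the fitted weights quantify how much more each cord and
infratentorial unit matters than a cerebral one (roughly 3.8x and 2.5x in
the reference analysis this package models).

The package provides:

- a **synthetic cohort generator** whose default configuration is the study
  condition: 78 patients, half progressing to secondary-progressive MS,
  with irregular clinical/brain-MRI/cord-MRI schedules, scanner labels,
  EDSS quantization, and missing cord scans;
- **schema-validated I/O** for the three CSV tables plus a
  Kolmogorov–Smirnov scanner-effect check;
- **temporal matching** of the three visit streams onto one per-patient
  time line with full provenance flags (nearest-within-±15-days,
  lesion forward-fill, parenchyma backward-fill, clinical
  nearest-within-274-days);
- **LPF features**: Hazen percentiles of lesion volume, parenchymal volume,
  and LPF per compartment, pooled over the study sample, with MUCCA
  (mean upper cervical cord area) calibration from brain T1 for patients
  lacking cord scans;
- **four EDSS models** (LPF, LPV, LV, PV) under leave-one-patient-out
  cross-validation with RMSE, Pearson r, and patient-bias-corrected MAE;
- **phenotype classification** (progressing vs non-progressing) using
  confirmed, relapse-vetoed EDSS/FSS worsening with a roving reference;
- **four-panel trajectory figures** per patient (EDSS, weighted cumulative
  LPF bands, lesion volumes at measured MRI dates, parenchymal volumes).

## Worked example

Simulate the default 78-patient cohort, validate it, build features, fit and
compare models, classify phenotypes, and render figures:

```
$ lpfcourse simulate --out-dir demo/cohort --seed 7
$ lpfcourse validate --in-dir demo/cohort
valid: 78 patients, 1282 clinical visits, 658 brain MRIs, 522 cord MRIs

$ lpfcourse qc-scanners --in-dir demo/cohort
...
no harmonization needed

$ lpfcourse features --in-dir demo/cohort --out demo/features.csv
rows kept 1785/1872; patients kept 78/78

$ lpfcourse phenotype --clinical demo/cohort/clinical.csv --out demo/phenotype.csv
40/78 progressing

$ lpfcourse fit --features demo/features.csv --model LPF --out-dir demo/fit
{
  "model": "LPF",
  "pearson_r": 0.9805346535493447,
  "rmse": 0.37686932311542454,
  "mae_no_bias": 0.2703890228520317,
  "n_timepoints": 1785,
  "n_patients": 78
}

$ lpfcourse compare --features demo/features.csv --out demo/model_comparison.json
[
  {"model": "LPF", "rmse": 0.3769, ...},
  {"model": "LPV", "rmse": 0.3863, ...},
  {"model": "LV",  "rmse": 0.4066, ...},
  {"model": "PV",  "rmse": 1.7902, ...}
]

$ lpfcourse render --in-dir demo/cohort --out-dir demo/figures
rendered 78/78 patients
```

The LPF model wins the comparison, and its cross-validated coefficients
recover the generating weights — the first rows of
`demo/fit/coefficients.csv`:

```
held_out_patient_id,lpf_cereb_pct,lpf_infra_pct,lpf_cord_pct,age0,intercept
P001,0.009113864398259773,0.02493968148772734,0.03797755140301634,...
P002,0.009137361232713314,0.024870726324108913,0.03801085948446519,...
```

i.e. coefficient ratios of about 4.2 (cord) and 2.7 (infratentorial)
relative to cerebral for this seed.

The same stages are importable as a library:

```python
from lpfcourse import simulate, pipeline, models, phenotype
from lpfcourse.config import CohortConfig

clinical, brain, cord, truth = simulate.generate_cohort(CohortConfig(seed=7))
result = pipeline.build_features(clinical, brain, cord)
reports, predictions = models.compare_models(result.features)
calls = phenotype.classify_cohort(clinical)
```

## Reproduction

All quantities are recomputed from scratch; nothing is cached or hard-coded.

```
pip install --no-build-isolation -e .
python -m pytest -q                       # full suite, ~7 minutes
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` simulates a default cohort at the given seed and
writes the headline quantities (per-model CV metrics, LPF coefficient means
and ratios, phenotype sensitivity/specificity against the simulated ground
truth, scanner-QC flag counts) as JSON, one `{"value": ..., "n": ...}` entry
per quantity. Runs are fully deterministic for a given seed.

See `docs/methods.md` for the models, the matching rules, the generator
design, and the package's limitations.
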