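# Methods

This document records the models, assumptions, and numerical choices
implemented in `lpfcourse`. The analysis follows the published
lesion-parenchymal-fraction (LPF) approach to depicting MS disease course;
the synthetic generator exists to exercise that analysis end to end, not to
be a biophysical simulator.

## Data model

Three CSV tables per cohort, one row per patient-date:

- `clinical.csv` — `patient_id, date, age, edss`, seven functional-system
  scores (`fss_*`, integers; most 0–6, cerebellar/bowel-bladder/visual
  capped per the FSS definitions), `ambulation_affected`, `relapse`.
- `brain_mri.csv` — `scanner_id`, three cerebral lesion subcompartments
  (`juxtacortical_ml`, `deep_white_matter_ml`, `periventricular_ml`), four
  infratentorial ones (`medulla_ml`, `pons_ml`, `midbrain_ml`,
  `cerebellum_ml`), parenchymal volumes `p_cereb`, `p_infra`, and
  `mucca_brain_t1_mm2` (cord area estimated from the brain T1).
- `cord_mri.csv` — `high_cervical_ml`, `low_cervical_ml`, `mucca_mm2`.

Validation is strict (unknown/missing columns, duplicates, EDSS off the
0, 1.0, 1.5 … 10 grid, non-integral FSS, negative volumes) and errors name
the table, row, and field. Numeric parsing uses Python `float()`, which is
correctly rounded, so a write–read–write cycle is byte-identical.

## Scanner QC

`ks_scanner_check` runs two-sample Kolmogorov–Smirnov tests for every
measure across every scanner pair, Holm-adjusted *within* measure, and
flags pairs at the adjusted level. The exact two-sample KS p-value is
discrete and conservative at small n; with ~150 observations per scanner
the null flag rate is close to nominal (measured ≈ 0.04 at α = 0.05).
Groups under `min_group` observations are skipped with a warning.

## Temporal matching and provenance

Each patient's clinical, brain-MRI, and cord-MRI dates are unioned into
one time line. Each measure is then filled in stages, and every cell
carries a provenance flag:

1. `measured` — value observed on that date.
2. `nearest_15d` — nearest observation within ±15 days (inclusive at 15;
   ties resolve to the earlier date).
3. `forward_filled` (lesion volumes only) — last prior observation;
   lesions are treated as non-decreasing between scans.
4. `backward_filled` (parenchymal volumes only) — next later observation;
   atrophy is slow, so the next measurement is the better stand-in.
5. `clinical_filled_9m` (clinical scores only) — nearest visit within 274
   days (inclusive at 274).
6. `missing` — nothing applicable.

The boundaries are hard: 15 days fills, 16 does not; 274 fills, 275 does
not. The unit tests pin these with a hand-derived five-date fixture.

## MUCCA calibration

Patients without any cord scan get their mean upper cervical cord area
from the brain T1 estimate, mapped through a quadratic calibration fitted
on patients who have both measurements within the matching window
(fallback to linear, then identity, when the pairs cannot support the
degree). Calibrated values are labelled `calibrated_brain_t1` so they are
distinguishable from `cord_mri` measurements downstream.

## LPF features

Per compartment c ∈ {cord, infra, cereb}: lesion volume L_c (sum of
subcompartments, missing propagates), parenchymal volume P_c, and
LPF_c = L_c / P_c. Each of the nine quantities is converted to percentiles
pooled over the *entire* study sample (all patients, all time points) using
the Hazen definition, 100·(rank − 0.5)/n, with midranks for ties; missing
values are ignored and stay missing. Pooling over the whole sample is what
lets a patient's percentile trajectory rise only if they worsen relative to
the cohort. `age0` (age at first feature row) is carried as a covariate.

## EDSS models

Four ordinary-least-squares model families, each with intercept and `age0`:

- **LPF** — the three LPF percentiles (primary model),
- **LPV** — lesion and parenchymal percentiles separately,
- **LV** — lesion percentiles only,
- **PV** — parenchymal percentiles only (atrophy alone).

Fitting uses QR with column pivoting; rank deficiency raises an error
naming the collinear columns rather than silently pseudo-inverting.
Evaluation is leave-one-patient-out cross-validation (all of a patient's
rows held out together, so no within-patient leakage), with three metrics:

- RMSE of held-out predictions,
- Pearson r,
- `mae_no_bias` — MAE after removing each patient's mean residual,
  isolating trajectory-shape error from patient-level offset.

`compare_models` restricts all models to the identical row intersection so
completeness differences cannot drive the ranking. Coefficient summaries
report per-fold means, SDs, ratios relative to the cerebral mean, and
Gaussian-KDE (Silverman) density curves.

## Phenotype classification

A patient is *progressing* if a confirmed, relapse-independent worsening
event occurs through either pathway:

- **edss_gt4** — EDSS increase of ≥ 1.0 (≥ 0.5 if the reference is ≥ 6.0)
  with all subsequent EDSS > 4.0;
- **fss_two_step** — a ≥ 2.0-step increase in a functional-system score.

Events use a **confirmed roving reference** (MSBase-style): the reference
starts at the first score and moves only on confirmed changes — a
confirmed improvement (next visit ≥ 91 days later at or below the dip)
lowers it, a confirmed progression raises it. Single noisy visits
therefore cannot move the reference. Candidate events must themselves be
confirmed at ≥ 91 days and are vetoed if any relapse falls within
[−90, +30] days of the event visit. Onset is backdated to the first
increase of the run that produced the event.

## Synthetic generator

Defaults are the study condition (78 patients, 50 % designated
progressing, 6-monthly clinical visits, yearly MRIs with jittered dates,
70 % cord-scan availability, three scanners, EDSS quantized to its grid
with noise SD 0.3). Design choices that matter for the analysis:

- **Pre-baseline disease duration** (uniform, ~2–16 y) plus lognormal
  per-patient *frailty* multipliers on lesion accrual (σ = 0.9) and
  parenchymal decline (σ = 0.4). Between-patient burden variation must
  dominate within-patient growth, otherwise pooled percentiles rise for
  every patient and the cohort has no cross-sectional spread to rank.
- **Link**: the latent EDSS is a weighted sum of the three LPF percentiles
  (true weights 0.038 / 0.025 / 0.010 for cord / infra / cereb) plus an
  age term — or of parenchymal percentiles when `link="pv"`, used to check
  that the model ranking follows the generative truth rather than the LPF
  model being favoured unconditionally.
- **Phenotype consistency by rejection sampling**: a drawn patient is kept
  only if their noise-free latent trajectory classifies to the designated
  phenotype with a margin (progressing patients must peak ≥ 5.0 EDSS;
  non-progressing must stay clearly away from the boundary: no
  (peak > 4.0 and cumulative run-up ≥ 0.75) and peak < 5.5). The margins
  were fixed before the test suite was written, from the observed
  misclassification modes at the boundary.
- Lesion counts are Poisson per interval, volumes lognormal, strictly
  accumulating; parenchyma declines geometrically from an age- and
  duration-dependent baseline; MUCCA-from-brain-T1 is the cord MUCCA
  passed through a noisy quadratic, so calibration has something real to
  recover.

## Determinism

All randomness flows from `numpy.random.SeedSequence([seed_key, i,
attempt])` substreams — per patient and per rejection attempt — so a
cohort is bit-reproducible for a seed, independent of patient order or
how many rejections other patients consumed. Two end-to-end runs produce
byte-identical prediction and coefficient CSVs.

## Visualization

Per patient, a four-panel figure: EDSS trajectory (relapses marked),
cumulative weighted LPF percentile bands (default weights 3.8 / 2.5 / 1,
or re-derived from the fitted model), lesion volumes drawn as bars *only*
at dates where the MRI was actually measured (provenance `measured`), and
parenchymal volumes. Band heights are conservation-checked: the stacked
bands sum to the weighted top line to 1e-9 at every rendered date, and
rows with missing LPFs leave gaps rather than wedging to zero.

## Limitations

- The generator is a calibration instrument, not a disease model: no
  relapse-remitting lesion dynamics, no treatment effects, no measurement
  drift between scanners beyond the labels themselves.
- Percentile features make the models invariant to monotone rescaling of
  volumes but also mean coefficients are per-percentile-point, not
  per-mL; ratios between compartments are the interpretable output.
- OLS treats repeated rows of a patient as independent within a fold;
  patient-level correlation is only addressed by the CV split and the
  bias-corrected MAE, not by a mixed model.
- The SPMS classifier sees scheduled visits only; onset dating is limited
  by visit spacing, and the 91-day confirmation is approximated by the
  next qualifying visit.
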