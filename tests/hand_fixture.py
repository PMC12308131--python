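"""Hand-built five-date matching fixture with a hand-derived provenance
table.

One patient, five distinct dates in the unified time line:

========  ==========  =====================================================
label     date        content
========  ==========  =====================================================
D1        2020-01-01  clinical visit (EDSS 2.0, age 40.0)
B1        2020-01-16  brain MRI — 15 days after D1 (inclusive boundary)
C1        2020-02-01  cord MRI — 16 days after B1 (exclusive boundary)
B2        2020-10-01  brain MRI — 274 days after D1 (9-month inclusive)
C2        2020-10-02  cord MRI — 275 days after D1 (9-month exclusive),
                      1 day after B2
========  ==========  =====================================================

The expected provenance per representative measure was derived by hand
from the fill rules (nearest within +/-15 days, tie to the earlier date;
lesions forward-filled; parenchyma backward-filled; clinical scores
nearest within 274 days):

* brain lesion (e.g. periventricular_ml):
  D1 nearest_15d (B1 at +15), B1 measured, C1 forward_filled (B1 is 16
  days away, outside the window), B2 measured, C2 nearest_15d (B2 at -1).
* brain parenchyma (p_cereb):
  D1 nearest_15d, B1 measured, C1 backward_filled (from B2), B2
  measured, C2 nearest_15d.
* cord lesion (high_cervical_ml):
  D1 missing (no cord scan within 15 days and none earlier), B1 missing
  (C1 is 16 days away), C1 measured, B2 nearest_15d (C2 at +1), C2
  measured.
* cord parenchyma (mucca_mm2):
  D1 backward_filled (from C1), B1 backward_filled, C1 measured, B2
  nearest_15d (C2 at +1), C2 measured.
* edss:
  D1 measured, B1 clinical_filled_9m (15 days), C1 clinical_filled_9m
  (31 days), B2 clinical_filled_9m (274 days, inclusive), C2 missing
  (275 days, exclusive).
"""

from __future__ import annotations

import pandas as pd

D1, B1, C1, B2, C2 = (pd.Timestamp(d) for d in
                      ("2020-01-01", "2020-01-16", "2020-02-01",
                       "2020-10-01", "2020-10-02"))
UNIFIED_DATES = [D1, B1, C1, B2, C2]


def build_tables():
    """(clinical, brain, cord) tables for the fixture patient."""
    clinical = pd.DataFrame([{
        "patient_id": "H1", "date": D1, "age": 40.0, "edss": 2.0,
        "fss_pyramidal": 1, "fss_cerebellar": 0, "fss_brainstem": 0,
        "fss_sensory": 0, "fss_bowel_bladder": 0, "fss_visual": 0,
        "fss_mental": 0, "ambulation_affected": False, "relapse": False,
    }])
    brain = pd.DataFrame([
        {"patient_id": "H1", "date": B1, "scanner_id": "s1",
         "periventricular_ml": 1.0, "deep_white_matter_ml": 0.5,
         "juxtacortical_ml": 0.2, "medulla_ml": 0.10, "pons_ml": 0.10,
         "midbrain_ml": 0.05, "cerebellum_ml": 0.15,
         "p_cereb": 1000.0, "p_infra": 150.0, "mucca_brain_t1_mm2": 80.0},
        {"patient_id": "H1", "date": B2, "scanner_id": "s1",
         "periventricular_ml": 1.2, "deep_white_matter_ml": 0.6,
         "juxtacortical_ml": 0.2, "medulla_ml": 0.10, "pons_ml": 0.12,
         "midbrain_ml": 0.05, "cerebellum_ml": 0.18,
         "p_cereb": 990.0, "p_infra": 149.0, "mucca_brain_t1_mm2": 79.0},
    ])
    cord = pd.DataFrame([
        {"patient_id": "H1", "date": C1, "scanner_id": "s1",
         "high_cervical_ml": 0.05, "low_cervical_ml": 0.02, "mucca_mm2": 70.0},
        {"patient_id": "H1", "date": C2, "scanner_id": "s1",
         "high_cervical_ml": 0.06, "low_cervical_ml": 0.03, "mucca_mm2": 69.0},
    ])
    return clinical, brain, cord


#: hand-derived provenance per (measure, date); order follows UNIFIED_DATES
EXPECTED_PROVENANCE = {
    "periventricular_ml": ["nearest_15d", "measured", "forward_filled",
                           "measured", "nearest_15d"],
    "p_cereb": ["nearest_15d", "measured", "backward_filled",
                "measured", "nearest_15d"],
    "high_cervical_ml": ["missing", "missing", "measured",
                         "nearest_15d", "measured"],
    "mucca_mm2": ["backward_filled", "backward_filled", "measured",
                  "nearest_15d", "measured"],
    "edss": ["measured", "clinical_filled_9m", "clinical_filled_9m",
             "clinical_filled_9m", "missing"],
}

#: hand-derived values for the same cells (NaN encoded as None)
EXPECTED_VALUES = {
    "periventricular_ml": [1.0, 1.0, 1.0, 1.2, 1.2],
    "p_cereb": [1000.0, 1000.0, 990.0, 990.0, 990.0],
    "high_cervical_ml": [None, None, 0.05, 0.06, 0.06],
    "mucca_mm2": [70.0, 70.0, 70.0, 69.0, 69.0],
    "edss": [2.0, 2.0, 2.0, 2.0, None],
}
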