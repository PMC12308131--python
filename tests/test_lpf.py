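import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lpfcourse import lpf

from oracles import naive_percentiles


def test_hazen_percentiles_distinct_values():
    # n = 4 distinct values: ranks 1..4 -> 100 * (r - 0.5) / 4
    out = lpf.to_percentiles([10.0, 20.0, 30.0, 40.0])
    np.testing.assert_allclose(out, [12.5, 37.5, 62.5, 87.5])


def test_hazen_percentiles_midranks_on_ties():
    # values 5, 5 share midrank 1.5; value 9 has rank 3
    out = lpf.to_percentiles([5.0, 5.0, 9.0])
    np.testing.assert_allclose(out, [100 * (1.5 - 0.5) / 3,
                                     100 * (1.5 - 0.5) / 3,
                                     100 * (3.0 - 0.5) / 3])


def test_percentiles_ignore_missing_and_stay_missing():
    out = lpf.to_percentiles([1.0, np.nan, 2.0, 3.0])
    assert np.isnan(out[1])
    np.testing.assert_allclose(np.delete(out, 1),
                               naive_percentiles([1.0, 2.0, 3.0]))


def test_percentiles_error_on_too_few_values():
    with pytest.raises(ValueError):
        lpf.to_percentiles([1.0, np.nan])


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.lists(st.integers(min_value=-5, max_value=5), min_size=2, max_size=40))
def test_percentiles_match_oracle_and_bounds(values):
    values = [float(v) for v in values]
    out = lpf.to_percentiles(values)
    np.testing.assert_allclose(out, naive_percentiles(values), atol=1e-12)
    assert (out > 0).all() and (out < 100).all()


def test_percentile_of_consistent_with_to_percentiles():
    ref = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0])
    np.testing.assert_allclose(lpf.percentile_of(ref, ref),
                               lpf.to_percentiles(ref), atol=1e-12)


def test_compute_lpf_basic_and_errors():
    np.testing.assert_allclose(lpf.compute_lpf(np.array([1.0]),
                                               np.array([4.0])), [0.25])
    # missing lesion or parenchyma propagates, it does not error
    assert np.isnan(lpf.compute_lpf(np.array([np.nan]), np.array([4.0]))[0])
    assert np.isnan(lpf.compute_lpf(np.array([1.0]), np.array([np.nan]))[0])
    with pytest.raises(ValueError):
        lpf.compute_lpf(np.array([1.0]), np.array([0.0]))


def test_aggregate_subcompartments_sums():
    frame = pd.DataFrame({
        "periventricular_ml": [1.0], "deep_white_matter_ml": [0.5],
        "juxtacortical_ml": [0.25],
        "medulla_ml": [0.1], "pons_ml": [0.2], "midbrain_ml": [0.3],
        "cerebellum_ml": [0.4],
        "high_cervical_ml": [0.05], "low_cervical_ml": [0.07],
        "mucca_mm2": [70.0], "p_cereb": [1000.0], "p_infra": [150.0],
    })
    agg = lpf.aggregate_subcompartments(frame)
    assert agg.loc[0, "l_cereb"] == pytest.approx(1.75)
    assert agg.loc[0, "l_infra"] == pytest.approx(1.0)
    assert agg.loc[0, "l_cord"] == pytest.approx(0.12)
    assert agg.loc[0, "p_cord"] == pytest.approx(70.0)


def test_aggregate_missing_subcompartment_propagates():
    frame = pd.DataFrame({
        "periventricular_ml": [1.0], "deep_white_matter_ml": [np.nan],
        "juxtacortical_ml": [0.25],
        "medulla_ml": [0.1], "pons_ml": [0.2], "midbrain_ml": [0.3],
        "cerebellum_ml": [0.4],
        "high_cervical_ml": [0.05], "low_cervical_ml": [0.07],
        "mucca_mm2": [70.0], "p_cereb": [1000.0], "p_infra": [150.0],
    })
    agg = lpf.aggregate_subcompartments(frame)
    assert np.isnan(agg.loc[0, "l_cereb"])
    # the other compartments are unaffected by the cerebral gap
    assert agg.loc[0, "l_infra"] == pytest.approx(1.0)


def test_mucca_calibration_recovers_quadratic():
    rng = np.random.default_rng(0)
    b = rng.uniform(60, 100, 40)
    c0, c1, c2 = 5.0, 0.85, 0.0008
    pairs = np.column_stack([b, c0 + c1 * b + c2 * b ** 2])
    cal = lpf.fit_mucca_calibration(pairs, degree=2)
    np.testing.assert_allclose([cal.c0, cal.c1, cal.c2], [c0, c1, c2],
                               rtol=1e-6, atol=1e-8)
    assert cal.residual_rmse == pytest.approx(0.0, abs=1e-9)


def test_mucca_calibration_fallback_chain():
    # two distinct x values cannot support a quadratic; linear works
    pairs = [(60.0, 56.0), (80.0, 73.0), (60.0, 56.0)]
    cal = lpf.fit_mucca_calibration_with_fallback(pairs)
    assert cal.kind == "linear"
    # a single point falls through to the identity
    cal = lpf.fit_mucca_calibration_with_fallback([(60.0, 56.0)])
    assert cal.kind == "identity"


def test_resolve_mucca_calibrates_patients_without_cord(small_cohort):
    _, clinical, brain, cord, _ = small_cohort
    dropped = sorted(set(cord["patient_id"]))[0]
    cord2 = cord[cord["patient_id"] != dropped]
    mucca, cal = lpf.resolve_mucca(brain, cord2)
    series, source = mucca[dropped]
    assert series.notna().any()
    assert set(source.dropna()) == {"calibrated_brain_t1"}
    # patients with cord scans keep their measured values on those dates
    kept = sorted(set(cord2["patient_id"]))[0]
    series_k, source_k = mucca[kept]
    assert "cord_mri" in set(source_k.dropna())


def test_build_feature_table_shapes(small_features):
    features = small_features.features
    for col in lpf.REQUIRED_FEATURE_COLUMNS:
        assert col in features.columns
    # percentiles live strictly inside (0, 100)
    for col in lpf.FEATURE_PCT_COLUMNS:
        present = features[col].dropna()
        assert ((present > 0) & (present < 100)).all()
    # age0 is constant per patient and equals the patient's minimum age
    for _, sub in features.groupby("patient_id"):
        assert sub["age0"].nunique() == 1
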