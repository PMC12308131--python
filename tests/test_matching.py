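import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lpfcourse import matching

import hand_fixture
from hand_fixture import build_tables


@pytest.fixture(scope="module")
def matched_fixture():
    clinical, brain, cord = build_tables()
    matched, counts = matching.match_cohort(clinical, brain, cord)
    return matched, counts


def test_unified_dates(matched_fixture):
    matched, _ = matched_fixture
    assert list(matched["date"]) == hand_fixture.UNIFIED_DATES


def test_hand_derived_provenance_table(matched_fixture):
    matched, _ = matched_fixture
    for measure, expected in hand_fixture.EXPECTED_PROVENANCE.items():
        got = list(matched[measure + "_src"])
        assert got == expected, f"{measure}: {got} != {expected}"


def test_hand_derived_values(matched_fixture):
    matched, _ = matched_fixture
    for measure, expected in hand_fixture.EXPECTED_VALUES.items():
        got = matched[measure].to_numpy(dtype=float)
        for g, e in zip(got, expected):
            if e is None:
                assert np.isnan(g), f"{measure}: expected missing, got {g}"
            else:
                assert g == pytest.approx(e), measure


def test_window_boundaries_inclusive_15_exclusive_16():
    targets = pd.DatetimeIndex(["2020-02-01"])
    inside = pd.Series([1.0], index=pd.DatetimeIndex(["2020-02-16"]))  # +15
    outside = pd.Series([1.0], index=pd.DatetimeIndex(["2020-02-17"]))  # +16
    v_in, s_in = matching.nearest_fill(inside, targets)
    v_out, s_out = matching.nearest_fill(outside, targets)
    assert s_in.iloc[0] == "nearest_15d" and v_in.iloc[0] == 1.0
    assert s_out.iloc[0] == "missing" and np.isnan(v_out.iloc[0])


def test_clinical_boundary_inclusive_274_exclusive_275():
    targets = pd.DatetimeIndex(["2020-01-01"])
    inside = pd.Series([3.0], index=pd.DatetimeIndex(["2020-10-01"]))  # +274
    outside = pd.Series([3.0], index=pd.DatetimeIndex(["2020-10-02"]))  # +275
    v_in, s_in = matching.fill_clinical(inside, targets)
    v_out, s_out = matching.fill_clinical(outside, targets)
    assert s_in.iloc[0] == "clinical_filled_9m" and v_in.iloc[0] == 3.0
    assert s_out.iloc[0] == "missing" and np.isnan(v_out.iloc[0])


def test_equidistant_tie_resolves_to_earlier_date():
    targets = pd.DatetimeIndex(["2020-06-15"])
    measured = pd.Series([1.0, 2.0],
                         index=pd.DatetimeIndex(["2020-06-05", "2020-06-25"]))
    values, src = matching.nearest_fill(measured, targets)
    assert values.iloc[0] == 1.0
    assert src.iloc[0] == "nearest_15d"


def test_exact_date_match_is_measured():
    targets = pd.DatetimeIndex(["2020-06-05"])
    measured = pd.Series([1.0], index=targets)
    values, src = matching.nearest_fill(measured, targets)
    assert src.iloc[0] == "measured"


def test_forward_fill_never_fills_before_first_observation():
    dates = pd.DatetimeIndex(["2020-01-01", "2020-02-01", "2020-03-01"])
    values = pd.Series([np.nan, 1.0, np.nan], index=dates)
    src = pd.Series(["missing", "measured", "missing"], index=dates)
    out, out_src = matching.forward_fill_lesions(values, src)
    assert np.isnan(out.iloc[0]) and out_src.iloc[0] == "missing"
    assert out.iloc[2] == 1.0 and out_src.iloc[2] == "forward_filled"


def test_backward_fill_never_fills_after_last_observation():
    dates = pd.DatetimeIndex(["2020-01-01", "2020-02-01", "2020-03-01"])
    values = pd.Series([np.nan, 1.0, np.nan], index=dates)
    src = pd.Series(["missing", "measured", "missing"], index=dates)
    out, out_src = matching.backward_fill_parenchyma(values, src)
    assert out.iloc[0] == 1.0 and out_src.iloc[0] == "backward_filled"
    assert np.isnan(out.iloc[2]) and out_src.iloc[2] == "missing"


def test_fills_are_idempotent():
    dates = pd.DatetimeIndex(["2020-01-01", "2020-02-01", "2020-03-01"])
    values = pd.Series([np.nan, 1.0, np.nan], index=dates)
    src = pd.Series(["missing", "measured", "missing"], index=dates)
    once = matching.forward_fill_lesions(values, src)
    twice = matching.forward_fill_lesions(*once)
    pd.testing.assert_series_equal(once[0], twice[0])
    pd.testing.assert_series_equal(once[1], twice[1])


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.lists(st.one_of(st.none(), st.floats(0, 100, allow_nan=False)),
                min_size=1, max_size=20))
def test_stage_monotonicity_missing_to_value_only(raw):
    """Fill stages only convert missing -> value, never change a value."""
    dates = pd.date_range("2020-01-01", periods=len(raw), freq="37D")
    values = pd.Series([np.nan if v is None else v for v in raw],
                       index=dates, dtype=float)
    src = pd.Series(np.where(values.notna(), "measured", "missing"),
                    index=dates, dtype=object)
    for fill in (matching.forward_fill_lesions, matching.backward_fill_parenchyma):
        out, out_src = fill(values, src)
        changed = values.notna() & (out != values)
        assert not changed.any()
        assert (out_src[values.notna()] == "measured").all()


def test_relapse_flags_are_never_filled(matched_fixture):
    matched, _ = matched_fixture
    assert matched["relapse"].dtype == bool
    assert not matched["relapse"].any()  # fixture has no relapses


def test_age_defined_at_every_unified_date(matched_fixture):
    matched, _ = matched_fixture
    assert matched["age"].notna().all()
    d0 = matched["date"].iloc[0]
    expected = 40.0 + (matched["date"] - d0).dt.days / 365.25
    np.testing.assert_allclose(matched["age"], expected)


def test_match_cohort_order_insensitive():
    clinical, brain, cord = build_tables()
    a, _ = matching.match_cohort(clinical, brain, cord)
    b, _ = matching.match_cohort(clinical.iloc[::-1], brain.iloc[::-1],
                                 cord.iloc[::-1])
    pd.testing.assert_frame_equal(a, b)


def test_provenance_counts_tabulate_all_rows(matched_fixture):
    matched, counts = matched_fixture
    assert counts.loc["edss"].sum() == len(matched)
    assert counts.loc["edss", "measured"] == 1
    assert counts.loc["edss", "clinical_filled_9m"] == 3
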