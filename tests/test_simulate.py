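import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lpfcourse import io, simulate
from lpfcourse.config import CohortConfig, ConfigError


def test_generation_is_deterministic(small_cohort):
    config, clinical, brain, cord, truth = small_cohort
    clinical2, brain2, cord2, truth2 = simulate.generate_cohort(config)
    pd.testing.assert_frame_equal(clinical, clinical2)
    pd.testing.assert_frame_equal(brain, brain2)
    pd.testing.assert_frame_equal(cord, cord2)
    assert truth.progressing == truth2.progressing
    assert truth.onset_date == truth2.onset_date


def test_different_seeds_differ():
    a = simulate.generate_cohort(CohortConfig(n_patients=4, seed=1))[0]
    b = simulate.generate_cohort(CohortConfig(n_patients=4, seed=2))[0]
    assert not a["edss"].equals(b["edss"])


def test_tables_pass_schema_validation(small_cohort):
    _, clinical, brain, cord, _ = small_cohort
    io.validate_clinical(clinical)
    io.validate_brain_mri(brain)
    io.validate_cord_mri(cord)


def test_truth_counts_match_designation(small_cohort):
    config, clinical, _, _, truth = small_cohort
    n_prog = sum(truth.progressing.values())
    assert n_prog == round(config.frac_progressing * config.n_patients)
    assert set(truth.progressing) == set(clinical["patient_id"])
    for pid, prog in truth.progressing.items():
        assert (truth.onset_date[pid] is not None) == prog


def test_lesion_volume_is_nondecreasing_step_function(small_cohort):
    _, _, brain, cord, _ = small_cohort
    lesion_cols = {
        "brain": list(io.CEREBRAL_SUBCOMPARTMENTS
                      + io.INFRATENTORIAL_SUBCOMPARTMENTS),
        "cord": list(io.CORD_SUBCOMPARTMENTS),
    }
    for frame, cols in ((brain, lesion_cols["brain"]), (cord, lesion_cols["cord"])):
        for _, sub in frame.groupby("patient_id"):
            sub = sub.sort_values("date")
            for col in cols:
                diffs = sub[col].diff().dropna()
                assert (diffs >= -1e-12).all()


def test_parenchyma_declines(small_cohort):
    _, _, brain, cord, _ = small_cohort
    # allow for the small multiplicative measurement noise
    for frame, col in ((brain, "p_cereb"), (brain, "p_infra"),
                       (cord, "mucca_mm2")):
        for _, sub in frame.groupby("patient_id"):
            sub = sub.sort_values("date")
            first, last = sub[col].iloc[0], sub[col].iloc[-1]
            if len(sub) >= 3:
                assert last <= first * 1.01


def test_edss_on_grid_and_fss_in_range(small_cohort):
    _, clinical, _, _, _ = small_cohort
    grid = np.asarray(io.EDSS_GRID)
    assert np.isclose(clinical["edss"].to_numpy()[:, None], grid).any(axis=1).all()
    for col, top in io.FSS_RANGES.items():
        assert clinical[col].between(0, top).all()
        assert np.isclose(clinical[col] % 1.0, 0.0).all()


def test_lesion_counts_consistent_with_poisson_rates():
    """Noiseless-rate check: with frailty fixed to 1 via a large sample of
    patients, total pre-onset cerebral lesion *count* stays within a wide
    (99.9%) interval of the configured Poisson rate."""
    config = CohortConfig(n_patients=30, seed=5)
    rng = np.random.default_rng(0)
    counts = []
    years = 0.0
    for i in range(30):
        params = simulate._draw_patient_params(i, False, False, config)
        traj = simulate.generate_patient_trajectory(params, config, rng)
        times, _ = traj.lesion_events["cereb"]
        counts.append(len(times))
        years += params.followup_years + params.disease_duration_years
    total = sum(counts)
    lam = config.lesion_rate_per_year.cereb * years
    # frailty (mean 1) widens the spread; test against a generous bound
    assert 0.3 * lam < total < 3.0 * lam


def test_mucca_brain_t1_inverts_true_calibration():
    c0, c1, c2 = simulate.MUCCA_CAL_TRUTH
    true = np.array([60.0, 70.0, 80.0])
    b = simulate._brain_t1_mucca_from_true(true, np.zeros(3))
    np.testing.assert_allclose(c0 + c1 * b + c2 * b ** 2, true, rtol=1e-12)


def test_snap_to_edss_grid():
    assert simulate.snap_to_edss_grid(0.4) == 0.0
    assert simulate.snap_to_edss_grid(0.6) == 1.0
    assert simulate.snap_to_edss_grid(3.74) == 3.5
    assert simulate.snap_to_edss_grid(3.75) == 3.5  # tie goes down
    assert simulate.snap_to_edss_grid(11.0) == 10.0
    assert simulate.snap_to_edss_grid(-1.0) == 0.0
    out = simulate.snap_to_edss_grid([1.2, 6.8])
    np.testing.assert_allclose(out, [1.0, 7.0])


def test_config_validation_errors_name_fields():
    with pytest.raises(ConfigError, match="n_patients"):
        CohortConfig(n_patients=0).validate()
    with pytest.raises(ConfigError, match="frac_progressing"):
        CohortConfig(frac_progressing=1.5).validate()
    with pytest.raises(ConfigError, match="cord_scan_availability"):
        simulate.generate_cohort(CohortConfig(cord_scan_availability=0.0))


def test_config_yaml_roundtrip(tmp_path):
    config = CohortConfig(n_patients=7, seed=3, link="pv")
    config.to_yaml(tmp_path / "c.yaml")
    back = CohortConfig.from_yaml(tmp_path / "c.yaml")
    assert back == config


def test_truth_json_roundtrip(tmp_path, small_cohort):
    _, _, _, _, truth = small_cohort
    truth.to_json(tmp_path / "truth.json")
    back = simulate.SyntheticTruth.from_json(tmp_path / "truth.json")
    assert back.progressing == truth.progressing
    assert back.onset_date == truth.onset_date
    for pid in truth.latent_edss:
        np.testing.assert_allclose(back.latent_edss[pid].to_numpy(),
                                   truth.latent_edss[pid].to_numpy(),
                                   atol=1e-9)


def test_inject_missingness_keeps_last_cord_anchor(small_cohort):
    config, clinical, brain, cord, _ = small_cohort
    import dataclasses
    degraded_cfg = dataclasses.replace(config, cord_scan_availability=0.3)
    _, _, cord2 = simulate.inject_missingness(clinical, brain, cord, degraded_cfg)
    assert len(cord2) < len(cord)
    assert set(cord2["patient_id"]) == set(cord["patient_id"])
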