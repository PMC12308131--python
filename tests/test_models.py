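import numpy as np
import pandas as pd
import pytest

from lpfcourse import models

from oracles import (
    naive_mae_without_patient_bias,
    naive_pearson,
    naive_rmse,
)


def _linear_features(n_patients=8, per_patient=6, seed=0, noise=0.0):
    """Feature table whose EDSS is exactly affine in the LPF terms."""
    rng = np.random.default_rng(seed)
    rows = []
    w = {"lpf_cereb_pct": 0.01, "lpf_infra_pct": 0.025, "lpf_cord_pct": 0.038}
    for i in range(n_patients):
        pid = f"P{i:02d}"
        age0 = rng.uniform(25, 50)
        for k in range(per_patient):
            x = {t: rng.uniform(0, 100) for t in w}
            edss = 0.5 + sum(w[t] * x[t] for t in w) + 0.01 * age0
            edss += rng.normal(0, noise)
            rows.append({"patient_id": pid,
                         "date": pd.Timestamp("2020-01-01")
                         + pd.Timedelta(days=30 * k),
                         "age0": age0, "edss": edss, **x})
    return pd.DataFrame(rows), w


def test_loo_recovers_exact_linear_model():
    features, w = _linear_features()
    preds, folds = models.loo_cv(features, models.ModelSpec.named("LPF"))
    np.testing.assert_allclose(preds["edss_hat"], preds["edss"], atol=1e-9)
    for fold in folds:
        for term, value in w.items():
            assert fold.coefficients[term] == pytest.approx(value, abs=1e-9)
        assert fold.coefficients["intercept"] == pytest.approx(0.5, abs=1e-7)


def test_loo_holds_out_each_patient_once():
    features, _ = _linear_features(noise=0.2)
    preds, folds = models.loo_cv(features, models.ModelSpec.named("LPF"))
    assert sorted(f.held_out_patient_id for f in folds) == \
        sorted(features["patient_id"].unique())
    assert len(preds) == len(features)


def test_held_out_patient_does_not_influence_its_fold():
    features, _ = _linear_features(noise=0.3)
    _, folds = models.loo_cv(features, models.ModelSpec.named("LPF"))
    fold0 = next(f for f in folds if f.held_out_patient_id == "P00")
    # refit by hand without P00; coefficients must agree exactly
    rest = features[features["patient_id"] != "P00"]
    X, y, _ = models.build_design(rest, models.ModelSpec.named("LPF"))
    coef = models.fit_least_squares(X, y)
    for name, c in zip(X.columns, coef):
        assert fold0.coefficients[name] == pytest.approx(float(c), abs=1e-12)


def test_rank_deficiency_names_collinear_column():
    features, _ = _linear_features(noise=0.1)
    features["lpf_cereb_pct"] = 2.0 * features["lpf_cord_pct"]
    X, y, _ = models.build_design(features, models.ModelSpec.named("LPF"))
    with pytest.raises(models.RankDeficiencyError, match="lpf_c"):
        models.fit_least_squares(X, y)


def test_metrics_match_oracles():
    rng = np.random.default_rng(0)
    y = rng.normal(3, 1, 40)
    y_hat = y + rng.normal(0, 0.5, 40)
    pid = rng.integers(0, 5, 40)
    assert models.rmse(y, y_hat) == pytest.approx(naive_rmse(y, y_hat))
    assert models.pearson(y, y_hat) == pytest.approx(naive_pearson(y, y_hat))
    assert models.mae_without_patient_bias(y, y_hat, pid) == pytest.approx(
        naive_mae_without_patient_bias(list(y), list(y_hat), list(pid)))


def test_mae_without_bias_ignores_constant_patient_offsets():
    y = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    y_hat = y + np.array([5.0] * 3 + [-2.0] * 3)  # pure per-patient offsets
    pid = np.array(["a"] * 3 + ["b"] * 3)
    assert models.mae_without_patient_bias(y, y_hat, pid) == pytest.approx(0.0)


def test_pearson_errors_on_zero_variance():
    with pytest.raises(ValueError):
        models.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_model_specs():
    assert models.ModelSpec.named("LPF").terms == (
        "lpf_cereb_pct", "lpf_infra_pct", "lpf_cord_pct", "age0")
    brain_only = models.ModelSpec.named("LPF", brain_only=True)
    assert "lpf_cord_pct" not in brain_only.terms
    assert brain_only.name == "LPF_brain"
    with pytest.raises(KeyError):
        models.ModelSpec.named("XXX")


def test_summarize_coefficients_ratios_and_density():
    features, w = _linear_features(noise=0.4)
    _, folds = models.loo_cv(features, models.ModelSpec.named("LPF"))
    summary = models.summarize_coefficients(folds)
    assert summary.ratios["cereb"] == pytest.approx(1.0)
    assert summary.ratios["cord"] > summary.ratios["infra"] > 1.0
    for comp, (grid, dens) in summary.density.items():
        assert len(grid) == len(dens)
        assert np.all(dens >= 0)


def test_compare_models_ranks_by_rmse(small_features):
    reports, predictions = models.compare_models(small_features.features)
    rmses = [r.rmse for r in reports]
    assert rmses == sorted(rmses)
    assert {r.model for r in reports} == set(models.MODEL_NAMES)
    # identical rows across models
    sizes = {name: len(p) for name, p in predictions.items()}
    assert len(set(sizes.values())) == 1


def test_reports_roundtrip(tmp_path, small_features):
    reports, _ = models.compare_models(small_features.features)
    models.save_reports(reports, tmp_path / "r.json")
    back = models.load_reports(tmp_path / "r.json")
    assert back == reports
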