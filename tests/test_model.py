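"""Regression fitting, cross-validation machinery and classification metrics."""

import numpy as np
import pandas as pd
import pytest

from dnabind.energetics import FEATURE_NAMES
from dnabind.model import (
    DatasetError, MLRModel, classify_deleterious, cross_validate,
    curate_dataset, evaluate, fit_mlr, matthews_cc, multicollinearity,
    predict_ddg, select_threshold_er,
)
from dnabind.synthetic import (
    DEFAULT_COEFFICIENTS, DEFAULT_INTERCEPT, generate_feature_dataset,
)


# --------------------------------------------------------------------------
# curation
# --------------------------------------------------------------------------

def test_curation_averages_duplicates():
    df = pd.DataFrame({
        "complex_id": ["c1", "c1"], "chain": ["A", "A"], "wt": ["R", "R"],
        "pos": [124, 124], "mut": ["A", "A"], "ddg_exp": [1.0, 2.0],
    })
    out = curate_dataset(df)
    assert len(out) == 1
    assert out["ddg_exp"].iloc[0] == pytest.approx(1.5)


def test_curation_drops_multi_mutations():
    df = pd.DataFrame({
        "complex_id": ["c1", "c1"], "chain": ["A", "A"],
        "wt": ["R", "R"], "pos": [124, 130],
        "mut": ["A", "A+K130A"], "ddg_exp": [1.0, 2.0],
    })
    out = curate_dataset(df)
    assert len(out) == 1 and out["pos"].iloc[0] == 124
    df2 = pd.DataFrame({"complex_id": ["c1", "c2"],
                        "mutation": ["R124A", "R124A+K130A"],
                        "chain": "A", "ddg_exp": [0.5, 1.5]})
    out2 = curate_dataset(df2)
    assert len(out2) == 1 and out2["complex_id"].iloc[0] == "c1"


def test_curation_clean_table_unchanged(synth_dataset):
    out = curate_dataset(synth_dataset)
    assert len(out) == len(synth_dataset)
    assert set(out.columns) == set(synth_dataset.columns)


def test_curation_rejects_bad_mutation_spec():
    df = pd.DataFrame({"complex_id": ["c1"], "mutation": ["??"],
                       "chain": "A", "ddg_exp": [0.5]})
    with pytest.raises(DatasetError, match="row 0"):
        curate_dataset(df)


# --------------------------------------------------------------------------
# fitting and prediction
# --------------------------------------------------------------------------

def test_noiseless_recovery_to_1e8():
    df = generate_feature_dataset(n=200, noise_sd=0.0, seed=5)
    model = fit_mlr(df)
    for k in FEATURE_NAMES:
        assert model.coefficients[k] == pytest.approx(
            DEFAULT_COEFFICIENTS[k], abs=1e-8)
    assert model.intercept == pytest.approx(DEFAULT_INTERCEPT, abs=1e-8)
    assert model.training_rmse == pytest.approx(0.0, abs=1e-8)
    assert model.training_r == pytest.approx(1.0, abs=1e-8)
    # residuals orthogonal to every feature column
    pred = model.predict_frame(df)
    resid = df["ddg_exp"].to_numpy() - pred
    x = df[list(FEATURE_NAMES)].to_numpy()
    assert np.abs(x.T @ resid).max() < 1e-6


def test_constant_feature_rejected(synth_dataset):
    df = synth_dataset.copy()
    df["ddg_solv"] = 0.0
    with pytest.raises(DatasetError, match="rank-deficient"):
        fit_mlr(df)


def test_too_few_rows_rejected(synth_dataset):
    with pytest.raises(DatasetError, match="at least"):
        fit_mlr(synth_dataset.head(8))


def test_standardized_coefficients_scale_invariant(synth_dataset):
    m1 = fit_mlr(synth_dataset)
    scaled = synth_dataset.copy()
    scaled["ddg_solv"] = scaled["ddg_solv"] * 1000.0 + 7.0
    m2 = fit_mlr(scaled)
    for k in FEATURE_NAMES:
        assert m2.std_coefficients[k] == pytest.approx(
            m1.std_coefficients[k], abs=1e-8)


def test_significant_features_have_small_pvalues(synth_dataset):
    model = fit_mlr(synth_dataset)
    # features with strong true signal relative to noise must be significant
    for k in ("d_e_fold", "nhbond_wt_site_all", "dd_evdw_site_all"):
        assert model.p_values[k] < 0.01


def test_predict_paths_and_errors(synth_dataset):
    model = fit_mlr(synth_dataset)
    row = synth_dataset.iloc[0]
    by_dict = predict_ddg(model, {k: row[k] for k in FEATURE_NAMES})
    by_arr = float(model.predict(row[list(FEATURE_NAMES)].to_numpy()))
    manual = model.intercept + sum(
        model.coefficients[k] * row[k] for k in FEATURE_NAMES)
    assert by_dict == pytest.approx(manual, rel=1e-12)
    assert by_arr == pytest.approx(manual, rel=1e-12)
    zeros = {k: 0.0 for k in FEATURE_NAMES}
    assert predict_ddg(model, zeros) == pytest.approx(model.intercept)
    with pytest.raises(KeyError, match="missing"):
        model.predict({"ddg_solv": 1.0})


def test_model_json_roundtrip(tmp_path, synth_dataset):
    model = fit_mlr(synth_dataset)
    path = tmp_path / "m.json"
    model.to_json(path)
    back = MLRModel.from_json(str(path))
    assert back.coefficients == model.coefficients
    assert back.intercept == model.intercept
    # byte-identical re-serialization (reproducible persistence)
    assert back.to_json() == model.to_json()


def test_classification_boundary():
    assert classify_deleterious(1.10) is True
    assert classify_deleterious(1.0999) is False
    assert classify_deleterious(-0.5) is False
    assert classify_deleterious(5.0, threshold=10.0) is False


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def test_mcc_printed_formula():
    assert matthews_cc(3, 3, 1, 1) == pytest.approx(0.5, abs=1e-12)
    assert matthews_cc(5, 5, 0, 0) == 1.0
    assert matthews_cc(0, 0, 5, 5) == -1.0
    assert matthews_cc(0, 5, 0, 5) == 0.0   # degenerate: no positives called


def test_evaluate_perfect_separation():
    exp = np.array([2.0, 3.0, 2.5, 0.0, -1.0, 0.5])
    pred = exp * 0.9
    rep = evaluate(pred, exp)
    assert rep.auc_roc == 1.0
    assert rep.mcc == 1.0


def test_evaluate_random_scores_auc_half(rng):
    n = 10_000
    exp = rng.normal(1.0, 1.0, n)
    pred = rng.normal(0.0, 1.0, n)       # independent of the labels
    rep = evaluate(pred, exp)
    assert rep.auc_roc == pytest.approx(0.5, abs=0.02)


def test_evaluate_rejects_single_class():
    with pytest.raises(ValueError, match="single-class"):
        evaluate([0.1, 0.2, 0.3], [5.0, 6.0, 7.0])


def test_evaluate_monotone_transform_invariance(rng):
    exp = rng.normal(1.0, 1.2, 300)
    pred = exp + rng.normal(0, 0.8, 300)
    a = evaluate(pred, exp).auc_roc
    b = evaluate(np.exp(pred / 2.0), exp).auc_roc
    assert a == pytest.approx(b, abs=1e-12)


def test_er_threshold_equals_bruteforce_scan():
    fpr = np.array([0.0, 0.1, 0.2, 0.5, 1.0])
    tpr = np.array([0.0, 0.6, 0.8, 0.9, 1.0])
    thr = np.array([np.inf, 2.0, 1.5, 0.7, 0.1])
    er = np.sqrt((1 - tpr) ** 2 + fpr ** 2)
    best = thr[np.isfinite(thr) & (er <= er.min())].max()
    assert select_threshold_er(fpr, tpr, thr) == best


def test_er_threshold_tie_prefers_larger():
    fpr = np.array([0.0, 0.1, 0.1, 1.0])
    tpr = np.array([0.0, 0.9, 0.9, 1.0])
    thr = np.array([np.inf, 3.0, 1.0, 0.2])
    assert select_threshold_er(fpr, tpr, thr) == 3.0


def test_er_threshold_degenerate_same_scores():
    # all predictions identical: the only finite threshold is that score
    exp = np.array([2.0, 0.0, 2.0, 0.0])
    pred = np.array([1.0, 1.0, 1.0, 1.0])
    from sklearn.metrics import roc_curve
    fpr, tpr, thr = roc_curve(exp >= 1.0, pred)
    assert select_threshold_er(fpr, tpr, thr) == 1.0


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

def test_cv3_grouping_property():
    df = generate_feature_dataset(n=60, n_complexes=5, seed=3)
    res = cross_validate(df, scheme="CV3")
    assert len(res.per_fold_rmse) == df["complex_id"].nunique()
    for fold_tag, grp in res.predictions.groupby("fold"):
        rows = grp["row"].to_numpy()
        test_complexes = set(df.iloc[rows]["complex_id"])
        assert test_complexes == {fold_tag}
    # every mutation appears exactly once as a test point
    assert sorted(res.predictions["row"]) == list(range(len(df)))


def test_cv1_cv2_split_sizes(synth_dataset):
    n = len(synth_dataset)
    for scheme, frac in (("CV1", 0.5), ("CV2", 0.8)):
        res = cross_validate(synth_dataset, scheme=scheme, n_repeats=4,
                             seed=7)
        n_test = n - int(round(frac * n))
        assert len(res.predictions) == 4 * n_test
        for _tag, grp in res.predictions.groupby("fold"):
            assert len(grp) == n_test


def test_cv_seed_determinism(synth_dataset):
    a = cross_validate(synth_dataset, scheme="CV1", n_repeats=3, seed=42)
    b = cross_validate(synth_dataset, scheme="CV1", n_repeats=3, seed=42)
    pd.testing.assert_frame_equal(a.predictions, b.predictions)
    c = cross_validate(synth_dataset, scheme="CV1", n_repeats=3, seed=43)
    assert not a.predictions.equals(c.predictions)


def test_cv3_single_complex_rejected():
    df = generate_feature_dataset(n=30, n_complexes=2, seed=1)
    df["complex_id"] = "only_one"
    with pytest.raises(DatasetError, match="two complexes"):
        cross_validate(df, scheme="CV3")


def test_cv_recovers_signal(synth_dataset):
    res = cross_validate(synth_dataset, scheme="CV3")
    assert res.pooled.r > 0.5
    assert res.pooled.rmse < 1.5
    assert set(res.coefficient_mean) == set(FEATURE_NAMES) | {"intercept"}


def test_unknown_scheme_rejected(synth_dataset):
    with pytest.raises(ValueError, match="unknown scheme"):
        cross_validate(synth_dataset, scheme="CV9")


# --------------------------------------------------------------------------
# multicollinearity
# --------------------------------------------------------------------------

def test_vif_orthogonal_features(rng):
    # columns mutually orthogonal and orthogonal to the intercept column
    n = 64
    raw = np.column_stack([np.ones(n), rng.normal(size=(n, 9))])
    q, _ = np.linalg.qr(raw)
    x = q[:, 1:]
    df = pd.DataFrame(x, columns=list(FEATURE_NAMES))
    df["complex_id"] = "c"
    df["ddg_exp"] = 1.0
    rep = multicollinearity(df)
    for k in FEATURE_NAMES:
        assert rep.vif[k] == pytest.approx(1.0, abs=1e-6)


def test_vif_collinear_pair_flagged(rng):
    df = generate_feature_dataset(n=200, seed=9)
    df["ddg_solv"] = df["dd_evdw_site_all"] + rng.normal(0, 1e-4, 200)
    rep = multicollinearity(df)
    assert rep.vif["ddg_solv"] > 3.0
    assert rep.vif["dd_evdw_site_all"] > 3.0


def test_vif_independent_normals_near_one(rng):
    x = rng.normal(size=(10_000, 9))
    df = pd.DataFrame(x, columns=list(FEATURE_NAMES))
    rep = multicollinearity(df)
    assert all(v < 1.1 for v in rep.vif.values())


def test_vif_constant_feature_flagged(synth_dataset):
    df = synth_dataset.copy()
    df["location_mut"] = 1.0
    rep = multicollinearity(df)
    assert "location_mut" in rep.flagged
    assert np.isnan(rep.vif["location_mut"])
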