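"""Feature extraction, closed-form ridge mapping, CV and subset experiments."""

import numpy as np
import pandas as pd
import pytest

from densvar import mapping_analysis as ma
from densvar import synthetic_data as sd
from densvar.evaluation import spearman


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("backbone_cls", [ma.TextureBackbone,
                                          ma.FilterBankBackbone])
def test_feature_matrix_shape_and_bias_column(preprocessed_images,
                                              backbone_cls):
    backbone = backbone_cls()
    feats = ma.extract_features(preprocessed_images[:5], backbone=backbone)
    assert feats.values.shape == (5, backbone.n_features + 1)
    np.testing.assert_array_equal(feats.values[:, -1], 1.0)


def test_duplicated_image_gives_identical_rows(preprocessed_images):
    iid, px = preprocessed_images[0]
    feats = ma.extract_features([(iid, px), ("copy", px.copy())])
    np.testing.assert_array_equal(feats.values[0], feats.values[1])


def test_feature_rows_independent_of_batch_and_order(preprocessed_images):
    imgs = preprocessed_images[:12]
    a = ma.extract_features(imgs, batch_size=4)
    order = list(reversed(range(12)))
    b = ma.extract_features([imgs[i] for i in order], batch_size=5)
    for i, j in enumerate(order):
        np.testing.assert_allclose(b.values[i], a.values[j], atol=1e-12)


def test_backbone_dimension_contract(preprocessed_images):
    with pytest.raises(ValueError):
        ma.extract_features(preprocessed_images[:3], expected_dim=7)


def test_feature_matrix_rejects_bad_bias():
    with pytest.raises(ValueError):
        ma.FeatureMatrix(np.array([[1.0, 2.0]]), ["a"])


# ---------------------------------------------------------------------------
# Ridge mapping
# ---------------------------------------------------------------------------

def _cg_ridge_oracle(X, y, lam, tol=1e-12):
    """Independent iterative least-squares solver: conjugate gradients on
    the ridge normal equations, run to convergence."""
    A = X.T @ X + lam * np.eye(X.shape[1])
    b = X.T @ y
    w = np.zeros(X.shape[1])
    r = b - A @ w
    p = r.copy()
    rs = r @ r
    for _ in range(10 * X.shape[1]):
        Ap = A @ p
        alpha = rs / (p @ Ap)
        w += alpha * p
        r -= alpha * Ap
        rs_new = r @ r
        if np.sqrt(rs_new) < tol * (1 + np.linalg.norm(b)):
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    return w


def test_ridge_matches_iterative_oracle(rng):
    for _ in range(10):
        n, p = rng.integers(20, 80), rng.integers(5, 15)
        X = np.hstack([rng.normal(size=(n, p)), np.ones((n, 1))])
        y = rng.normal(size=n) * 50
        w = ma.fit_ridge(X, y, lambda2=1.0).w
        np.testing.assert_allclose(w, _cg_ridge_oracle(X, y, 1.0), atol=1e-6)


def test_ridge_interpolates_square_full_rank(rng):
    X = rng.normal(size=(6, 5))
    X = np.hstack([X, np.ones((6, 1))])
    y = rng.normal(size=6) * 30
    w = ma.fit_ridge(X, y, lambda2=0.0)
    np.testing.assert_allclose(ma.predict_linear(X, w), y, atol=1e-8)


def test_ridge_heavy_penalty_shrinks_to_zero(rng):
    X = np.hstack([rng.normal(size=(30, 4)), np.ones((30, 1))])
    y = rng.uniform(0, 100, size=30)
    w = ma.fit_ridge(X, y, lambda2=1e9)
    assert np.linalg.norm(w.w) < 1e-3
    assert np.abs(ma.predict_linear(X, w)).max() < 0.1


def test_ridge_singular_design_names_remedy(rng):
    col = rng.normal(size=(20, 1))
    X = np.hstack([col, col, np.ones((20, 1))])  # exactly collinear
    with pytest.raises(ma.SingularMatrixError, match="lambda2 > 0"):
        ma.fit_ridge(X, rng.normal(size=20), lambda2=0.0)


def test_ridge_rejects_negative_penalty(rng):
    X = np.ones((3, 1))
    with pytest.raises(ValueError):
        ma.fit_ridge(X, np.zeros(3), lambda2=-1.0)


@pytest.mark.parametrize("case", ["zero_w", "bias_only"])
def test_predict_linear_direct_cases(case, rng):
    if case == "zero_w":
        X = np.hstack([rng.normal(size=(4, 3)), np.ones((4, 1))])
        w = ma.RidgeWeights(np.zeros(4), 1.0)
        np.testing.assert_array_equal(ma.predict_linear(X, w), np.zeros(4))
    else:
        X = np.ones((5, 1))
        w = ma.RidgeWeights(np.array([42.0]), 1.0)
        np.testing.assert_array_equal(ma.predict_linear(X, w),
                                      np.full(5, 42.0))


def test_predict_linear_dimension_mismatch(rng):
    with pytest.raises(ValueError):
        ma.predict_linear(np.ones((3, 4)), ma.RidgeWeights(np.ones(3), 1.0))


# ---------------------------------------------------------------------------
# Fold planning / CV
# ---------------------------------------------------------------------------

def test_plan_folds_partitions_subjects_evenly():
    plan = ma.plan_folds([f"s{i}" for i in range(10)], k=5, seed=0)
    sizes = pd.Series(plan).value_counts()
    assert sorted(plan.values()) == sorted([0, 1, 2, 3, 4] * 2)
    assert (sizes == 2).all()


def test_plan_folds_keeps_subject_images_together(metadata):
    plan = ma.plan_folds(metadata["subject_id"], k=5, seed=1)
    folds = metadata["subject_id"].map(plan)
    assert folds.notna().all()
    per_subject_folds = folds.groupby(metadata["subject_id"]).nunique()
    assert (per_subject_folds == 1).all()


def test_plan_folds_needs_enough_subjects():
    with pytest.raises(ValueError):
        ma.plan_folds(["a", "b"], k=5)


def test_plan_folds_seeds_give_different_valid_partitions():
    subjects = [f"s{i}" for i in range(20)]
    p1 = ma.plan_folds(subjects, k=5, seed=1)
    p2 = ma.plan_folds(subjects, k=5, seed=2)
    assert p1 != p2
    for p in (p1, p2):
        assert set(p) == set(subjects)
        assert set(p.values()) == {0, 1, 2, 3, 4}


def test_cv_predictions_cover_every_image_once(features, label_table,
                                               metadata):
    wide = ma.pivot_labels(label_table)
    ids = wide["image_id"].tolist()
    X = features.subset(ids).values
    subjects = metadata.set_index("image_id").loc[ids, "subject_id"].tolist()
    plan = ma.plan_folds(subjects, k=5, seed=0)
    preds = ma.cv_predict(X, wide["averaged"].to_numpy(), subjects, plan, 1.0)
    assert preds.shape == (len(ids),)
    assert np.isfinite(preds).all()


# ---------------------------------------------------------------------------
# Subset experiments
# ---------------------------------------------------------------------------

def test_degenerate_identical_readers_make_all_grid_cells_equal(small_cohort,
                                                                metadata,
                                                                features):
    """If both readers give identical scores, Av and Ind labels coincide and
    all four train/test cells must be identical."""
    ident = [sd.ReaderProfile("a"), sd.ReaderProfile("b")]
    labels = sd.assign_reader_pairs(small_cohort, ident, seed=2)
    grid = ma.trts_grid(features, labels, metadata, n_boot=20, seed=0)
    ref = {e.name: e.value for e in grid[("Av", "Av")].entries}
    for cell, report in grid.items():
        got = {e.name: e.value for e in report.entries}
        for name in ref:
            assert got[name] == pytest.approx(ref[name], abs=1e-8), cell


def test_subset_below_threshold_reports_exclusion(features, label_table,
                                                  metadata):
    reader = label_table["reader_id"].iloc[0]
    spec = ma.SubsetSpec(mode="individual", reader_ids=(reader,),
                         min_images=10**6)
    res = ma.run_subset_experiment(features, label_table, metadata, spec)
    assert res.excluded
    assert "threshold" in res.reason
    assert res.predictions is None


def test_individual_subset_runs_and_reports(features, label_table, metadata):
    counts = label_table["reader_id"].value_counts()
    reader = counts.idxmax()
    spec = ma.SubsetSpec(mode="individual", reader_ids=(reader,),
                         min_images=20)
    res = ma.run_subset_experiment(features, label_table, metadata, spec,
                                   n_boot=30)
    assert not res.excluded
    assert len(res.predictions) == counts.max()
    assert {e.name for e in res.report.entries} == {"rank_corr", "rmse"}


def test_subset_spec_validation():
    with pytest.raises(ValueError):
        ma.SubsetSpec(mode="individual", reader_ids=("a", "b"))
    with pytest.raises(ValueError):
        ma.SubsetSpec(mode="pair", reader_ids=("a",))
    with pytest.raises(ValueError):
        ma.SubsetSpec(mode="banana")


def test_monotone_warp_of_labels_preserves_rank_metric(features, label_table,
                                                       metadata):
    """Spearman between predictions and warped labels equals Spearman against
    the raw labels — rank metrics see through distribution differences."""
    wide = ma.pivot_labels(label_table)
    ids = wide["image_id"].tolist()
    X = features.subset(ids).values
    subjects = metadata.set_index("image_id").loc[ids, "subject_id"].tolist()
    plan = ma.plan_folds(subjects, k=5, seed=0)
    y = wide["averaged"].to_numpy()
    preds = ma.cv_predict(X, y, subjects, plan, 1.0)
    warped = 100.0 * (y / 100.0) ** 2
    assert spearman(preds, warped) == pytest.approx(spearman(preds, y),
                                                    abs=1e-12)
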