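"""Fixed-feature ridge mapping and the label-variability subset experiments.

This implements the transfer-learning arm of the study: images pass through
a frozen feature extractor, a bias column is appended, and density scores
are predicted by the closed-form ridge solution

    w = (X_tr^T X_tr + lambda2 I)^(-1) X_tr^T y_tr,   y_hat = X w

fitted with subject-level k-fold cross-validation so every image receives
exactly one held-out prediction.  Because the mapping is deterministic and
optimal for a linear combination of the features, any change in the metrics
between label regimes is attributable to the labels, not to training noise.

The subset experiments isolate the effect of inter-reader variability on
this mapping:

* the **Tr/Ts grid** trains and tests on averaged vs individual reader
  labels (four cells);
* **per-reader subsets** train and test on a single reader's scores;
* **per-pair subsets** train and test on the averaged scores of one reader
  pair, over images that pair jointly read.

Subsets below a configurable image-count inclusion threshold are reported
as excluded rather than silently dropped.

The default backbone (:class:`TextureBackbone`) combines morphological
dense-clump statistics with a seeded fixed convolutional filter bank —
deterministic, training-free, and carrying enough texture signal for the
linear mapping to learn density.  Any callable mapping a batch of images
to a feature matrix can be plugged in instead (e.g. a pretrained deep
feature extractor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import evaluation
from .evaluation import MetricsReport, rmse, score_report, spearman

__all__ = [
    "FeatureMatrix",
    "RidgeWeights",
    "SubsetSpec",
    "SubsetResult",
    "FilterBankBackbone",
    "TextureBackbone",
    "extract_features",
    "fit_ridge",
    "predict_linear",
    "plan_folds",
    "cv_predict",
    "run_subset_experiment",
    "trts_grid",
    "pivot_labels",
    "SingularMatrixError",
]


class SingularMatrixError(np.linalg.LinAlgError):
    pass


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """n x (p+1) design matrix; the last column is the constant bias 1."""

    values: np.ndarray
    row_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError("feature matrix must be 2-D with n >= 1 rows")
        if len(self.row_ids) != self.values.shape[0]:
            raise ValueError("row_ids must align with rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        if not np.allclose(self.values[:, -1], 1.0):
            raise ValueError("last column must be the constant bias 1")

    def subset(self, image_ids: Sequence[str]) -> "FeatureMatrix":
        index = {rid: i for i, rid in enumerate(self.row_ids)}
        rows = [index[i] for i in image_ids]
        return FeatureMatrix(self.values[rows], list(image_ids))


@dataclass
class RidgeWeights:
    w: np.ndarray
    lambda2: float


@dataclass
class SubsetSpec:
    """Which slice of the label table an experiment runs on.

    mode="individual": one reader, that reader's own scores as labels.
    mode="pair": two readers, labels are their per-image average over the
    images both read.  mode="all": every image, with ``label_rule`` choosing
    averaged or individual (per-score-row) labels.
    """

    mode: str
    reader_ids: tuple[str, ...] = ()
    min_images: int = 400
    label_rule: str = "individual"

    def __post_init__(self) -> None:
        if self.mode not in ("individual", "pair", "all"):
            raise ValueError(f"unknown subset mode {self.mode!r}")
        if self.mode == "individual":
            if len(self.reader_ids) != 1 or self.label_rule != "individual":
                raise ValueError("individual mode needs one reader and "
                                 "label_rule='individual'")
        if self.mode == "pair":
            if len(self.reader_ids) != 2:
                raise ValueError("pair mode needs exactly two readers")
            self.label_rule = "averaged"


@dataclass
class SubsetResult:
    spec: SubsetSpec
    excluded: bool
    n_images: int
    predictions: pd.DataFrame | None = None   # image_id, prediction, label
    report: MetricsReport | None = None
    reason: str = ""


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def _grid_pool(response: np.ndarray, g: int) -> np.ndarray:
    h, w = response.shape
    ys = np.linspace(0, h, g + 1).astype(int)
    xs = np.linspace(0, w, g + 1).astype(int)
    return np.array([response[ys[i]:ys[i + 1], xs[j]:xs[j + 1]].mean()
                     for i in range(g) for j in range(g)])


class FilterBankBackbone:
    """Seeded fixed convolutional filter bank with grid pooling.

    Each image is convolved with ``n_filters`` random zero-mean kernels; the
    rectified responses are average-pooled over a ``pool_grid x pool_grid``
    partition of the image, and the raw image itself contributes the same
    pooled-intensity features.  Output dimension:
    ``(n_filters + 1) * pool_grid**2``.
    """

    def __init__(self, n_filters: int = 15, filter_size: int = 5,
                 pool_grid: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        k = rng.standard_normal((n_filters, filter_size, filter_size))
        self.kernels = k - k.mean(axis=(1, 2), keepdims=True)
        self.pool_grid = pool_grid
        self.n_features = (n_filters + 1) * pool_grid**2

    def __call__(self, images: Sequence[np.ndarray]) -> np.ndarray:
        from scipy.signal import fftconvolve

        out = np.empty((len(images), self.n_features))
        for i, im in enumerate(images):
            feats = [_grid_pool(im, self.pool_grid)]
            for kern in self.kernels:
                resp = np.maximum(fftconvolve(im, kern, mode="same"), 0.0)
                feats.append(_grid_pool(resp, self.pool_grid))
            out[i] = np.concatenate(feats)
        return out


class TextureBackbone:
    """Fixed texture-statistics extractor: the package's default backbone.

    Histogram equalization flattens per-image intensity histograms, so the
    density signal that survives preprocessing is *morphological*: dense
    tissue forms contiguous clumps.  For a ladder of intensity thresholds
    this backbone measures the candidate dense region's area fraction,
    component count, boundary length, and mean/largest component size, and
    appends coarse pooled intensities plus a small seeded random filter
    bank for residual texture.  Dimension: ``20 + pool_grid^2 * (n_filters
    + 1)`` (default 56).  Deterministic per image; no training.
    """

    THRESHOLDS = (0.1, 0.2, 0.3, 0.4)

    def __init__(self, n_filters: int = 8, filter_size: int = 5,
                 pool_grid: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        k = rng.standard_normal((n_filters, filter_size, filter_size))
        self.kernels = k - k.mean(axis=(1, 2), keepdims=True)
        self.pool_grid = pool_grid
        self.n_features = (5 * len(self.THRESHOLDS)
                           + (n_filters + 1) * pool_grid**2)

    def _morphology(self, im: np.ndarray) -> list[float]:
        from scipy import ndimage

        feats: list[float] = []
        for tau in self.THRESHOLDS:
            binary = im < tau  # dense candidates are dark after inversion
            if binary.any():
                labelled, n = ndimage.label(binary)
                eroded = ndimage.binary_erosion(binary)
                boundary = int((binary & ~eroded).sum())
                sizes = np.bincount(labelled.ravel())[1:]
                feats += [float(binary.mean()), n / 100.0,
                          boundary / im.size,
                          float(sizes.mean()) / im.size,
                          float(sizes.max()) / im.size]
            else:
                feats += [0.0] * 5
        return feats

    def __call__(self, images: Sequence[np.ndarray]) -> np.ndarray:
        from scipy.signal import fftconvolve

        out = np.empty((len(images), self.n_features))
        for i, im in enumerate(images):
            feats = [np.asarray(self._morphology(im)),
                     _grid_pool(im, self.pool_grid)]
            for kern in self.kernels:
                resp = np.maximum(fftconvolve(im, kern, mode="same"), 0.0)
                feats.append(_grid_pool(resp, self.pool_grid))
            out[i] = np.concatenate(feats)
        return out


def extract_features(
    images,
    backbone: Callable[[Sequence[np.ndarray]], np.ndarray] | None = None,
    batch_size: int = 64,
    expected_dim: int | None = None,
) -> FeatureMatrix:
    """Run images through the backbone in batches and append the bias column.

    ``images`` is a sequence of objects with ``image_id`` and ``pixels``
    attributes (or ``(image_id, pixels)`` pairs).  The backbone must be
    deterministic in inference mode, so a row depends only on its image and
    never on batch composition — violated batching is a backbone bug this
    contract makes testable.
    """
    backbone = backbone or TextureBackbone()
    ids, grids = [], []
    for item in images:
        if hasattr(item, "pixels"):
            ids.append(item.image_id)
            grids.append(np.asarray(item.pixels, dtype=float))
        else:
            iid, px = item
            ids.append(iid)
            grids.append(np.asarray(px, dtype=float))
    blocks = []
    for start in range(0, len(grids), batch_size):
        blocks.append(np.asarray(backbone(grids[start:start + batch_size])))
    feats = np.vstack(blocks)
    if expected_dim is not None and feats.shape[1] != expected_dim:
        raise ValueError(
            f"backbone produced {feats.shape[1]} features, declared "
            f"{expected_dim}")
    design = np.hstack([feats, np.ones((feats.shape[0], 1))])
    return FeatureMatrix(design, ids)


# ---------------------------------------------------------------------------
# Closed-form ridge mapping
# ---------------------------------------------------------------------------

def fit_ridge(X: FeatureMatrix | np.ndarray, y: Sequence[float],
              lambda2: float = 1.0) -> RidgeWeights:
    """Closed-form L2-penalized least squares with the bias penalized too.

    Minimizes ||X w - y||^2 + lambda2 ||w||^2, the unique solution of the
    normal equations (X^T X + lambda2 I) w = X^T y, solved by a Cholesky
    factorization rather than an explicit inverse.  With ``lambda2 = 0`` a
    rank-deficient design raises :class:`SingularMatrixError`.
    """
    A = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if A.shape[0] != y.shape[0]:
        raise ValueError("X rows and y must align")
    if lambda2 < 0:
        raise ValueError("lambda2 must be >= 0")
    p = A.shape[1]
    gram = A.T @ A + lambda2 * np.eye(p)
    rhs = A.T @ y
    try:
        from scipy.linalg import cho_factor, cho_solve

        w = cho_solve(cho_factor(gram), rhs)
    except np.linalg.LinAlgError as exc:
        raise SingularMatrixError(
            "normal equations are singular (rank-deficient design with "
            "lambda2 = 0); set lambda2 > 0 to regularize") from exc
    if not np.all(np.isfinite(w)):
        raise SingularMatrixError(
            "non-finite ridge solution; set lambda2 > 0 to regularize")
    return RidgeWeights(w=w, lambda2=float(lambda2))


def predict_linear(X: FeatureMatrix | np.ndarray, w: RidgeWeights) -> np.ndarray:
    """Apply the linear mapping: X w.  Predictions are reported unclipped."""
    A = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if A.shape[1] != w.w.shape[0]:
        raise ValueError(
            f"feature dimension {A.shape[1]} != weight dimension {w.w.shape[0]}")
    return A @ w.w


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def plan_folds(subject_ids, k: int = 5, seed: int = 0) -> dict[str, int]:
    """Assign each subject to one of k folds (sizes differ by <= 1 subject).

    Splitting is by subject, never by image, so all views of a woman share a
    fold and no model is tested on a woman it trained on.
    """
    uniq = sorted(set(subject_ids))
    if len(uniq) < k:
        raise ValueError(f"need >= {k} subjects for {k}-fold CV, have {len(uniq)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(uniq))
    return {uniq[j]: int(i % k) for i, j in enumerate(perm)}


def cv_predict(
    X: np.ndarray,
    y: np.ndarray,
    image_subjects: Sequence[str],
    fold_plan: dict[str, int],
    lambda2: float,
    train_X: np.ndarray | None = None,
    train_y: np.ndarray | None = None,
    train_subjects: Sequence[str] | None = None,
) -> np.ndarray:
    """Held-out predictions for every row of X under the subject fold plan.

    When the training design differs from the evaluation design (e.g.
    individual-label training duplicates images as one row per reader
    score), pass it via ``train_X``/``train_y``/``train_subjects``; rows of
    the held-out fold's subjects are excluded from training in either case.
    """
    if train_X is None:
        train_X, train_y, train_subjects = X, y, image_subjects
    folds = np.array([fold_plan[s] for s in image_subjects])
    train_folds = np.array([fold_plan[s] for s in train_subjects])
    preds = np.empty(X.shape[0])
    for f in np.unique(folds):
        w = fit_ridge(train_X[train_folds != f], train_y[train_folds != f],
                      lambda2)
        preds[folds == f] = predict_linear(X[folds == f], w)
    return preds


# ---------------------------------------------------------------------------
# Label-table helpers
# ---------------------------------------------------------------------------

def pivot_labels(labels: pd.DataFrame) -> pd.DataFrame:
    """Wide per-image label view: image_id, reader_1, reader_2, score_1,
    score_2, averaged.  Reader order within an image is lexicographic."""
    df = labels.sort_values(["image_id", "reader_id"]).reset_index(drop=True)
    counts = df.groupby("image_id").size()
    if not (counts == 2).all():
        bad = counts[counts != 2].index[:3].tolist()
        raise ValueError(f"every image needs exactly two reader scores: {bad}")
    first = df.groupby("image_id").nth(0).reset_index(drop=True)
    second = df.groupby("image_id").nth(1).reset_index(drop=True)
    return pd.DataFrame({
        "image_id": first["image_id"].to_numpy(),
        "reader_1": first["reader_id"].to_numpy(),
        "reader_2": second["reader_id"].to_numpy(),
        "score_1": first["score"].to_numpy(),
        "score_2": second["score"].to_numpy(),
        "averaged": (first["score"].to_numpy() + second["score"].to_numpy()) / 2.0,
    })


def _subjects_for(image_ids, metadata: pd.DataFrame) -> list[str]:
    lookup = dict(zip(metadata["image_id"], metadata["subject_id"]))
    return [lookup[i] for i in image_ids]


# ---------------------------------------------------------------------------
# Subset experiments
# ---------------------------------------------------------------------------

def run_subset_experiment(
    features: FeatureMatrix,
    labels: pd.DataFrame,
    metadata: pd.DataFrame,
    spec: SubsetSpec,
    lambda2: float = 1.0,
    k: int = 5,
    seed: int = 0,
    n_boot: int = 1000,
) -> SubsetResult:
    """Fit the ridge mapping on one subset of the labels and report metrics.

    Returns held-out predictions for every image of the subset (CC and MLO
    predictions pooled into one evaluation set) together with Spearman/RMSE
    and bootstrap CIs.  Subsets smaller than ``spec.min_images`` are
    reported as excluded, mirroring the reader inclusion threshold.
    """
    if spec.mode == "individual":
        sub = labels[labels["reader_id"] == spec.reader_ids[0]]
        image_ids = sub["image_id"].tolist()
        y = sub["score"].to_numpy()
    elif spec.mode == "pair":
        wide = pivot_labels(labels)
        pair = set(spec.reader_ids)
        m = wide[[set(t) == pair for t in
                  zip(wide["reader_1"], wide["reader_2"])]]
        image_ids = m["image_id"].tolist()
        y = m["averaged"].to_numpy()
    else:  # all
        wide = pivot_labels(labels)
        if spec.label_rule == "averaged":
            image_ids = wide["image_id"].tolist()
            y = wide["averaged"].to_numpy()
        else:
            image_ids = labels["image_id"].tolist()
            y = labels["score"].to_numpy()

    n_images = len(set(image_ids))
    if n_images < spec.min_images:
        return SubsetResult(spec, True, n_images,
                            reason=f"subset has {n_images} images, below the "
                                   f"inclusion threshold {spec.min_images}")
    if n_images == 0:
        return SubsetResult(spec, True, 0, reason="empty subset")

    Xs = features.subset(image_ids)
    subjects = _subjects_for(image_ids, metadata)
    plan = plan_folds(subjects, k=k, seed=seed)
    preds = cv_predict(Xs.values, y, subjects, plan, lambda2)
    report = score_report(preds, y, n_boot=n_boot, seed=seed,
                          mode=spec.mode, readers="+".join(spec.reader_ids))
    pred_df = pd.DataFrame({"image_id": image_ids, "prediction": preds,
                            "label": y})
    return SubsetResult(spec, False, n_images, pred_df, report)


def trts_grid(
    features: FeatureMatrix,
    labels: pd.DataFrame,
    metadata: pd.DataFrame,
    lambda2: float = 1.0,
    k: int = 5,
    seed: int = 0,
    n_boot: int = 1000,
) -> dict[tuple[str, str], MetricsReport]:
    """Train/test on averaged (Av) vs individual (Ind) labels: 4 metric cells.

    Av training uses one row per image with the two readers' mean score as
    the target; Ind training uses each (image, reader score) pair as an
    independent training row.  Av testing compares the per-image prediction
    with the averaged label; Ind testing compares it with *both* reader
    scores (the prediction enters twice).  Cells are keyed (train, test)
    with values "Av"/"Ind".
    """
    wide = pivot_labels(labels)
    image_ids = wide["image_id"].tolist()
    subjects = _subjects_for(image_ids, metadata)
    plan = plan_folds(subjects, k=k, seed=seed)
    X = features.subset(image_ids).values
    y_av = wide["averaged"].to_numpy()
    # individual training design: two rows per image; the penalty is scaled
    # by the duplication factor so regularization per *image* matches the
    # averaged-label cell and the comparison isolates the labels
    X_ind = np.repeat(X, 2, axis=0)
    y_ind = np.column_stack([wide["score_1"], wide["score_2"]]).ravel()
    subj_ind = list(np.repeat(subjects, 2))

    preds = {
        "Av": cv_predict(X, y_av, subjects, plan, lambda2),
        "Ind": cv_predict(X, y_av, subjects, plan, 2.0 * lambda2,
                          train_X=X_ind, train_y=y_ind,
                          train_subjects=subj_ind),
    }
    grid: dict[tuple[str, str], MetricsReport] = {}
    for tr, pred in preds.items():
        grid[(tr, "Av")] = score_report(pred, y_av, n_boot=n_boot, seed=seed,
                                        train=tr, test="Av")
        pred2 = np.repeat(pred, 2)
        grid[(tr, "Ind")] = score_report(pred2, y_ind, n_boot=n_boot,
                                         seed=seed, train=tr, test="Ind")
    return grid


def reader_subset_summary(
    features: FeatureMatrix,
    labels: pd.DataFrame,
    metadata: pd.DataFrame,
    reader_ids: Sequence[str] | None = None,
    min_images: int = 400,
    lambda2: float = 1.0,
    k: int = 5,
    seed: int = 0,
    n_boot: int = 200,
) -> dict:
    """Per-reader subset experiments with Av1/Av2 aggregates.

    Runs one individual-reader experiment per included reader and aggregates
    the per-reader Spearman/RMSE into Av1 (mean across readers, SD) and Av2
    (metric on the pooled prediction/label pairs).  Excluded readers are
    listed with their image counts.
    """
    if reader_ids is None:
        reader_ids = sorted(labels["reader_id"].unique())
    per_rc, per_rmse, excluded = [], [], []
    pooled_pred, pooled_lab = [], []
    results = {}
    for rid in reader_ids:
        spec = SubsetSpec(mode="individual", reader_ids=(rid,),
                          min_images=min_images)
        res = run_subset_experiment(features, labels, metadata, spec,
                                    lambda2=lambda2, k=k, seed=seed,
                                    n_boot=n_boot)
        results[rid] = res
        if res.excluded:
            excluded.append((rid, res.n_images))
            continue
        p = res.predictions["prediction"].to_numpy()
        l = res.predictions["label"].to_numpy()
        per_rc.append((rid, spearman(p, l), len(p)))
        per_rmse.append((rid, rmse(p, l), len(p)))
        pooled_pred.append(p)
        pooled_lab.append(l)
    if not per_rc:
        return {"results": results, "excluded": excluded}
    pooled = (np.concatenate(pooled_pred), np.concatenate(pooled_lab))
    return {
        "results": results,
        "excluded": excluded,
        "rank_corr": evaluation.aggregate_reader_metrics(
            per_rc, pooled, spearman, n_boot=n_boot, seed=seed),
        "rmse": evaluation.aggregate_reader_metrics(
            per_rmse, pooled, rmse, n_boot=n_boot, seed=seed),
    }


def pair_subset_summary(
    features: FeatureMatrix,
    labels: pd.DataFrame,
    metadata: pd.DataFrame,
    min_images: int = 400,
    lambda2: float = 1.0,
    k: int = 5,
    seed: int = 0,
    n_boot: int = 200,
) -> dict:
    """Per-reader-pair subset experiments (averaged pair labels) + Av1/Av2."""
    wide = pivot_labels(labels)
    pair_counts = wide.groupby(["reader_1", "reader_2"]).size()
    per_rc, per_rmse, excluded = [], [], []
    pooled_pred, pooled_lab = [], []
    results = {}
    for (r1, r2), count in pair_counts.items():
        key = f"{r1}+{r2}"
        spec = SubsetSpec(mode="pair", reader_ids=(r1, r2),
                          min_images=min_images)
        res = run_subset_experiment(features, labels, metadata, spec,
                                    lambda2=lambda2, k=k, seed=seed,
                                    n_boot=n_boot)
        results[key] = res
        if res.excluded:
            excluded.append((key, res.n_images))
            continue
        p = res.predictions["prediction"].to_numpy()
        l = res.predictions["label"].to_numpy()
        per_rc.append((key, spearman(p, l), len(p)))
        per_rmse.append((key, rmse(p, l), len(p)))
        pooled_pred.append(p)
        pooled_lab.append(l)
    if not per_rc:
        return {"results": results, "excluded": excluded}
    pooled = (np.concatenate(pooled_pred), np.concatenate(pooled_lab))
    return {
        "results": results,
        "excluded": excluded,
        "rank_corr": evaluation.aggregate_reader_metrics(
            per_rc, pooled, spearman, n_boot=n_boot, seed=seed),
        "rmse": evaluation.aggregate_reader_metrics(
            per_rmse, pooled, rmse, n_boot=n_boot, seed=seed),
    }
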