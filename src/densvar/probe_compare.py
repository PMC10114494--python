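"""Linear-probe comparison of learned representations.

To ask whether label variability altered the *representation* (rather than
the final mapping), each trained model is stripped to its penultimate
feature vector and the identical closed-form ridge mapping from the
fixed-feature analysis is fitted on top, with the same subject-level CV
discipline and the same regularization for every model.  Any difference in
probe metrics then comes from the representations alone.

Three representations are compared: the single-predictor trunk, the
multi-predictor trunk, and an untrained (seeded) trunk as the baseline
control.  When a genuinely pretrained backbone is plugged in it takes the
control role instead.

Label regimes for the probe:

* ``Av``  — train and test the mapping on averaged reader labels;
* ``Ind1`` — train one mapping per reader on that reader's own scores, test
  each against the averaged labels, then average the metrics across readers
  (with across-reader SD);
* ``Ind2`` — same per-reader mappings, but metrics computed on the pooled
  concatenation of all per-reader predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import MetricsReport, bootstrap_ci, rmse, score_report, spearman
from .mapping_analysis import FeatureMatrix, cv_predict, pivot_labels, plan_folds

__all__ = [
    "RepresentationMatrix",
    "extract_representation",
    "probe_fit_eval",
    "probe_predictions",
    "compare_predictions",
]


@dataclass
class RepresentationMatrix:
    values: np.ndarray          # (n, feature_dim)
    model_tag: str              # e.g. "single", "multi", "untrained"
    row_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("representation contains non-finite values")
        if len(self.row_ids) != self.values.shape[0]:
            raise ValueError("row_ids must align with rows")

    def design(self) -> FeatureMatrix:
        """Append the bias column, yielding the probe's design matrix."""
        ones = np.ones((self.values.shape[0], 1))
        return FeatureMatrix(np.hstack([self.values, ones]), list(self.row_ids))


def extract_representation(model, images, model_tag: str = "",
                           batch_size: int = 64) -> RepresentationMatrix:
    """Penultimate features for each image, batch-composition independent.

    ``model`` must expose ``features(batch) -> (B, feature_dim)`` in
    deterministic inference mode (the trunk here has no stochastic layers;
    a plug-in backbone with train-time dropout/batch-norm must be switched
    to inference before use).  ``images`` is a sequence of (image_id, grid)
    pairs or objects with those attributes.
    """
    ids, grids = [], []
    for item in images:
        if hasattr(item, "pixels"):
            ids.append(item.image_id)
            grids.append(np.asarray(item.pixels, dtype=float))
        else:
            iid, px = item
            ids.append(iid)
            grids.append(np.asarray(px, dtype=float))
    values = model.features(np.stack(grids), batch_size=batch_size)
    return RepresentationMatrix(values, model_tag, ids)


# ---------------------------------------------------------------------------
# Probe fitting and evaluation
# ---------------------------------------------------------------------------

def probe_predictions(
    rep: RepresentationMatrix,
    labels: pd.DataFrame,
    metadata: pd.DataFrame,
    lambda2: float = 1.0,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Held-out probe predictions on averaged labels for every image.

    Returns a DataFrame (image_id, prediction, label) under the Av regime —
    the vector used for model-to-model prediction comparisons.
    """
    wide = pivot_labels(labels)
    design = rep.design().subset(wide["image_id"].tolist())
    lookup = dict(zip(metadata["image_id"], metadata["subject_id"]))
    subjects = [lookup[i] for i in wide["image_id"]]
    plan = plan_folds(subjects, k=k, seed=seed)
    y = wide["averaged"].to_numpy()
    preds = cv_predict(design.values, y, subjects, plan, lambda2)
    return pd.DataFrame({"image_id": wide["image_id"], "prediction": preds,
                         "label": y})


def probe_fit_eval(
    rep: RepresentationMatrix,
    labels: pd.DataFrame,
    metadata: pd.DataFrame,
    label_rule: str = "Av",
    lambda2: float = 1.0,
    k: int = 5,
    seed: int = 0,
    n_boot: int = 1000,
    min_images_per_reader: int = 30,
) -> MetricsReport:
    """Fit the ridge probe under one label regime and report metrics.

    ``Av`` trains and tests on averaged labels.  ``Ind1``/``Ind2`` train a
    mapping per reader on its own scores and test against averaged labels;
    Ind1 averages metrics across readers (SD as uncertainty), Ind2 pools
    all predictions and bootstraps.  Readers with fewer images than
    ``min_images_per_reader`` are skipped and recorded in the report
    context.
    """
    if label_rule not in ("Av", "Ind1", "Ind2"):
        raise ValueError(f"unknown label rule {label_rule!r}")
    wide = pivot_labels(labels)
    lookup = dict(zip(metadata["image_id"], metadata["subject_id"]))

    if label_rule == "Av":
        pred_df = probe_predictions(rep, labels, metadata, lambda2, k, seed)
        return score_report(pred_df["prediction"], pred_df["label"],
                            n_boot=n_boot, seed=seed,
                            model=rep.model_tag, label_rule="Av")

    averaged = dict(zip(wide["image_id"], wide["averaged"]))
    per_rc, per_rmse = [], []
    pooled_pred, pooled_lab = [], []
    skipped = []
    for rid in sorted(labels["reader_id"].unique()):
        sub = labels[labels["reader_id"] == rid]
        ids = sub["image_id"].tolist()
        if len(ids) < max(min_images_per_reader, k):
            skipped.append(rid)
            continue
        design = rep.design().subset(ids)
        subjects = [lookup[i] for i in ids]
        if len(set(subjects)) < k:
            skipped.append(rid)
            continue
        plan = plan_folds(subjects, k=k, seed=seed)
        preds = cv_predict(design.values, sub["score"].to_numpy(),
                           subjects, plan, lambda2)
        y_av = np.array([averaged[i] for i in ids])
        per_rc.append(spearman(preds, y_av))
        per_rmse.append(rmse(preds, y_av))
        pooled_pred.append(preds)
        pooled_lab.append(y_av)
    if not per_rc:
        raise ValueError("no reader had enough images for the probe")

    report = MetricsReport()
    n_pool = int(sum(len(p) for p in pooled_pred))
    if label_rule == "Ind1":
        rc = np.asarray(per_rc)
        er = np.asarray(per_rmse)
        rc_sd = float(np.std(rc, ddof=1)) if rc.size > 1 else 0.0
        er_sd = float(np.std(er, ddof=1)) if er.size > 1 else 0.0
        report.add("rank_corr", float(rc.mean()),
                   ci=(float(rc.mean() - rc_sd), float(rc.mean() + rc_sd)),
                   n=n_pool, model=rep.model_tag, label_rule="Ind1",
                   n_readers=len(per_rc), skipped=skipped)
        report.add("rmse", float(er.mean()),
                   ci=(float(er.mean() - er_sd), float(er.mean() + er_sd)),
                   n=n_pool, model=rep.model_tag, label_rule="Ind1",
                   n_readers=len(per_rc), skipped=skipped)
        return report
    # Ind2: pooled
    p = np.concatenate(pooled_pred)
    l = np.concatenate(pooled_lab)
    rep_out = score_report(p, l, n_boot=n_boot, seed=seed,
                           model=rep.model_tag, label_rule="Ind2",
                           skipped=skipped)
    return rep_out


def compare_predictions(pred_a: pd.DataFrame | Sequence[float],
                        pred_b: pd.DataFrame | Sequence[float],
                        n_boot: int = 0, seed: int = 0) -> dict:
    """Similarity of two prediction vectors: Spearman + RMSE (symmetric).

    DataFrames must carry aligned ``image_id`` columns; raw vectors are
    assumed aligned.  With ``n_boot > 0`` bootstrap CIs are attached.
    """
    if isinstance(pred_a, pd.DataFrame):
        if not isinstance(pred_b, pd.DataFrame):
            raise TypeError("both inputs must be DataFrames or both vectors")
        if list(pred_a["image_id"]) != list(pred_b["image_id"]):
            raise ValueError("prediction tables have misaligned image ids")
        a = pred_a["prediction"].to_numpy()
        b = pred_b["prediction"].to_numpy()
    else:
        a = np.asarray(pred_a, dtype=float)
        b = np.asarray(pred_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("prediction vectors have different lengths")
    out = {"rank_corr": spearman(a, b), "rmse": rmse(a, b), "n": int(a.size)}
    if n_boot:
        out["rank_corr_ci"] = bootstrap_ci(spearman, a, b, n_boot=n_boot,
                                           seed=seed)
        out["rmse_ci"] = bootstrap_ci(rmse, a, b, n_boot=n_boot, seed=seed + 1)
    return out
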