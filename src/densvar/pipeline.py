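"""Desk-scale study pipelines combining the module stages.

These helpers wire the synthetic cohort, preprocessing, feature extraction,
mapping analysis and end-to-end training into the standard experiment
configurations used by the package's analyses and scripts.  Sizes default
to desk scale (a thousand-image cohort for mapping experiments; a
two-thousand-image cohort at 64 x 64 for representation training) so a full
study runs on one CPU in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import end_to_end as e2e
from . import mapping_analysis as ma
from . import preprocessing as pp
from . import probe_compare as pc
from . import synthetic_data as sd

__all__ = ["StudyData", "build_study", "grid_metrics",
           "subset_vs_pooled_summary", "data_size_rmse",
           "representation_comparison"]


@dataclass
class StudyData:
    cohort: sd.SyntheticCohort
    labels: pd.DataFrame
    metadata: pd.DataFrame
    images: list              # (image_id, preprocessed grid)
    features: ma.FeatureMatrix | None


def build_study(
    n_subjects: int = 250,
    image_size: int = 32,
    m: int = 13,
    noise_sd: float = 8.0,
    warp_strength: float = 0.35,
    bias_scale: float = 4.0,
    seed: int = 0,
    with_features: bool = True,
) -> StudyData:
    """Generate one study realization: cohort, reader pool, labels, features.

    Defaults give ~1,000 images read by two of 13 heterogeneous readers
    (distinct monotone warps, systematic texture biases, random error of
    about 8 VAS points) — the conditions under which the label-variability
    effects are measurable at desk scale.
    """
    cohort = sd.generate_cohort(sd.CohortConfig(
        n_subjects=n_subjects, image_size=image_size, seed=seed))
    readers = sd.make_reader_pool(m=m, seed=seed + 1,
                                  warp_strength=warp_strength,
                                  bias_scale=bias_scale, noise_sd=noise_sd)
    labels = sd.assign_reader_pairs(cohort, readers, seed=seed + 2)
    cfg = pp.PreprocessConfig(target_size=image_size)
    images = [(im.image_id, pp.preprocess_image(im, cfg))
              for im in cohort.images]
    features = ma.extract_features(images) if with_features else None
    return StudyData(cohort, labels, cohort.metadata(), images, features)


def grid_metrics(data: StudyData, lambda2: float = 1.0, k: int = 5,
                 seed: int = 0, n_boot: int = 50) -> dict:
    """Tr/Ts x Av/Ind grid as a flat dict of cell -> metric values."""
    grid = ma.trts_grid(data.features, data.labels, data.metadata,
                        lambda2=lambda2, k=k, seed=seed, n_boot=n_boot)
    out = {}
    for (tr, ts), report in grid.items():
        for e in report.entries:
            out[f"{tr.lower()}_{ts.lower()}_{e.name}"] = e.value
    return out


def subset_vs_pooled_summary(data: StudyData, min_reader_images: int = 100,
                             min_pair_images: int = 100, lambda2: float = 1.0,
                             k: int = 5, seed: int = 0) -> dict:
    """Per-reader and per-pair Av1/Av2 aggregates next to the pooled
    individual-label baseline they are compared against."""
    grid = grid_metrics(data, lambda2=lambda2, k=k, seed=seed, n_boot=20)
    readers = ma.reader_subset_summary(
        data.features, data.labels, data.metadata,
        min_images=min_reader_images, lambda2=lambda2, k=k, seed=seed,
        n_boot=20)
    pairs = ma.pair_subset_summary(
        data.features, data.labels, data.metadata,
        min_images=min_pair_images, lambda2=lambda2, k=k, seed=seed,
        n_boot=20)
    out = {"pooled_ind_ind_rank_corr": grid["ind_ind_rank_corr"],
           "pooled_ind_ind_rmse": grid["ind_ind_rmse"]}
    for tag, summary in (("reader", readers), ("pair", pairs)):
        if "rank_corr" in summary:
            out[f"{tag}_av1_rank_corr"] = summary["rank_corr"]["av1"]
            out[f"{tag}_av2_rank_corr"] = summary["rank_corr"]["av2"]
            out[f"{tag}_av1_rmse"] = summary["rmse"]["av1"]
            out[f"{tag}_av2_rmse"] = summary["rmse"]["av2"]
            out[f"{tag}_n_included"] = summary["rank_corr"]["n_readers"]
    return out


def data_size_rmse(data: StudyData, sizes=(2000, 1000, 500, 200),
                   n_seeds: int = 5, lambda2: float = 1.0, k: int = 5) -> dict:
    """Median Av-Av CV RMSE at decreasing training-set sizes (by subject)."""
    wide = ma.pivot_labels(data.labels)
    lookup = dict(zip(data.metadata["image_id"], data.metadata["subject_id"]))
    ids_all = wide["image_id"].tolist()
    subj_all = np.array([lookup[i] for i in ids_all])
    uniq = np.unique(subj_all)
    y_all = wide["averaged"].to_numpy()
    X_all = data.features.subset(ids_all).values
    per_subject = len(ids_all) / len(uniq)
    out = {}
    for size in sizes:
        vals = []
        for s in range(n_seeds):
            rng = np.random.default_rng(1000 * s + size)
            n_subj = max(int(round(size / per_subject)), k + 1)
            chosen = set(rng.choice(uniq, size=min(n_subj, len(uniq)),
                                    replace=False))
            mask = np.array([sj in chosen for sj in subj_all])
            subs = list(subj_all[mask])
            plan = ma.plan_folds(subs, k=k, seed=s)
            preds = ma.cv_predict(X_all[mask], y_all[mask], subs, plan,
                                  lambda2)
            vals.append(float(np.sqrt(np.mean((preds - y_all[mask]) ** 2))))
        out[size] = float(np.median(vals))
    return out


def representation_comparison(
    n_subjects: int = 500,
    image_size: int = 64,
    m: int = 13,
    epochs: int = 10,
    learning_rates: tuple[float, ...] = (3e-3,),
    seed: int = 0,
    lambda2: float = 1.0,
    n_boot: int = 200,
) -> dict:
    """Train single- and multi-predictors on one cohort and probe all three
    representations (plus the untrained control) on the held-out test set.

    Returns probe metrics per model and pairwise prediction similarities.
    Augmentation uses flips and pixel noise (the rotation knob stays
    available but is off here to keep a full comparison in the minutes
    range on one CPU).
    """
    study = build_study(n_subjects=n_subjects, image_size=image_size, m=m,
                        seed=seed, with_features=False)
    readers = sorted(study.labels["reader_id"].unique())
    data = e2e.build_masked_dataset(study.images, study.labels, readers,
                                    study.metadata)
    splits = pp.split_by_subject(data.subject_ids, (0.7, 0.15, 0.15),
                                 seed=seed)

    def take(part):
        idx = np.array([i for i, s in enumerate(data.subject_ids)
                        if s in splits[part]])
        return e2e.MaskedDataset(
            data.images[idx], data.d[idx], data.phi[idx],
            [data.image_ids[i] for i in idx],
            [data.subject_ids[i] for i in idx], data.reader_order)

    train, val, test = take("train"), take("val"), take("test")
    models = {"untrained": e2e.SmallConvNet(
        train.images.shape[1:], 1, 64, seed=seed + 900)}
    for mode in ("single", "multi"):
        cfg = e2e.TrainConfig(mode=mode, m=len(readers), epochs=epochs,
                              seed=seed, learning_rates=learning_rates,
                              max_rotation_deg=0.0)
        models[mode] = e2e.train_model(train, val, cfg).model

    test_imgs = list(zip(test.image_ids, test.images))
    test_labels = study.labels[study.labels["image_id"].isin(test.image_ids)]
    out: dict = {"n_test_images": len(test_imgs)}
    preds = {}
    for tag, model in models.items():
        rep = pc.extract_representation(model, test_imgs, tag)
        report = pc.probe_fit_eval(rep, test_labels, study.metadata, "Av",
                                   lambda2=lambda2, seed=seed, n_boot=n_boot)
        e = report["rank_corr"]
        out[f"probe_{tag}_rank_corr"] = e.value
        out[f"probe_{tag}_rank_corr_ci"] = (e.ci_low, e.ci_high)
        out[f"probe_{tag}_rmse"] = report["rmse"].value
        preds[tag] = pc.probe_predictions(rep, test_labels, study.metadata,
                                          lambda2=lambda2, seed=seed)
    for a, b in (("single", "multi"), ("single", "untrained"),
                 ("multi", "untrained")):
        cmp = pc.compare_predictions(preds[a], preds[b])
        out[f"{a}_vs_{b}_rank_corr"] = cmp["rank_corr"]
        out[f"{a}_vs_{b}_rmse"] = cmp["rmse"]
    return out
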