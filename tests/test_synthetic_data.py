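"""Cohort generator and reader-variability model, checked against oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from densvar import synthetic_data as sd


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def test_empty_cohort():
    cohort = sd.generate_cohort(sd.CohortConfig(n_subjects=0))
    assert len(cohort) == 0
    assert cohort.metadata().empty


def test_cohort_counts_and_ranges():
    cohort = sd.generate_cohort(
        sd.CohortConfig(n_subjects=10, image_size=32, seed=3))
    assert len(cohort) == 40  # four views per subject, none missing
    for im in cohort.images:
        assert 0.0 <= im.true_density <= 100.0
        assert im.pixels.min() >= 0.0 and im.pixels.max() <= 1.0
        assert im.view in ("CC", "MLO") and im.laterality in ("L", "R")
    per_subject = cohort.metadata().groupby("subject_id").size()
    assert (per_subject == 4).all()


def test_cohort_determinism_bit_identical():
    cfg = sd.CohortConfig(n_subjects=4, image_size=32, seed=42)
    a, b = sd.generate_cohort(cfg), sd.generate_cohort(cfg)
    for ia, ib in zip(a.images, b.images):
        assert ia.image_id == ib.image_id
        assert ia.true_density == ib.true_density
        np.testing.assert_array_equal(ia.pixels, ib.pixels)


def test_missing_view_rate_drops_images():
    cohort = sd.generate_cohort(
        sd.CohortConfig(n_subjects=50, image_size=32,
                        missing_view_rate=0.25, seed=1))
    assert len(cohort) < 200
    assert len(cohort) > 100


def test_within_subject_density_correlation(small_cohort):
    """Four views of one subject share the subject-level density up to the
    configured small jitter."""
    meta = small_cohort.metadata()
    spread = meta.groupby("subject_id")["true_density"].std()
    assert spread.median() < 3 * 2.0  # within_subject_sd default = 2


def test_invalid_configs_raise():
    with pytest.raises(sd.ConfigurationError):
        sd.CohortConfig(n_subjects=-1)
    with pytest.raises(sd.ConfigurationError):
        sd.CohortConfig(image_size=8)
    with pytest.raises(sd.ConfigurationError):
        sd.CohortConfig(missing_view_rate=1.5)


def test_foreground_intensity_tracks_density():
    """Mean breast intensity must rise with latent density (rank corr > 0.9
    at n >= 200 images) — the signal downstream models learn."""
    cohort = sd.generate_cohort(
        sd.CohortConfig(n_subjects=60, image_size=32, seed=5))
    fg = [im.pixels[im.pixels > 0].mean() for im in cohort.images]
    td = [im.true_density for im in cohort.images]
    assert len(fg) >= 200
    assert spearmanr(fg, td).statistic > 0.9


# ---------------------------------------------------------------------------
# Reader model
# ---------------------------------------------------------------------------

def _image_with(density, attrs=np.zeros(3)):
    return sd.SyntheticImage("i0", "s0", "CC", "R",
                             np.zeros((16, 16)), density, np.asarray(attrs))


def test_identity_reader_reproduces_truth():
    reader = sd.ReaderProfile("r")
    assert sd.simulate_reader_score(reader, _image_with(37.5)) == 37.5


def test_monotone_warp_preserves_order():
    # warp(x) = 100 (x/100)^2 is the beta CDF with a=2 (up to normalisation);
    # any beta warp must keep scores strictly increasing in the truth
    reader = sd.ReaderProfile("r", warp_a=2.0, warp_b=1.0)
    truths = np.arange(10.0, 100.0, 10.0)
    scores = [sd.simulate_reader_score(reader, _image_with(t)) for t in truths]
    assert np.all(np.diff(scores) > 0)
    assert spearmanr(truths, scores).statistic == pytest.approx(1.0)
    # the a=2, b=1 beta CDF is exactly the square law
    np.testing.assert_allclose(scores, 100.0 * (truths / 100.0) ** 2,
                               rtol=1e-10)


def test_warp_fixes_endpoints_and_is_strictly_monotone():
    for a, b in [(0.5, 2.0), (3.0, 0.7), (1.0, 1.0)]:
        reader = sd.ReaderProfile("r", warp_a=a, warp_b=b)
        grid = np.linspace(0, 100, 201)
        w = reader.warp(grid)
        assert w[0] == 0.0 and w[-1] == pytest.approx(100.0)
        assert np.all(np.diff(w) > 0)


def test_noise_only_scores_match_monte_carlo_moments():
    """10,000 noisy reads of a mid-scale image: sample mean ~ truth and
    sample SD ~ noise_sd (the [0,100] clip is inactive at truth=50)."""
    reader = sd.ReaderProfile("r", noise_sd=5.0)
    img = _image_with(50.0)
    rng = np.random.default_rng(123)
    draws = np.array([sd.simulate_reader_score(reader, img, seed=rng)
                      for _ in range(10_000)])
    assert draws.mean() == pytest.approx(50.0, abs=0.2)
    assert draws.std() == pytest.approx(5.0, abs=0.2)


def test_bias_weights_dimension_mismatch():
    reader = sd.ReaderProfile("r", bias_weights=np.zeros(5))
    with pytest.raises(ValueError):
        sd.simulate_reader_score(reader, _image_with(10.0))


def test_scores_clipped_to_scale():
    reader = sd.ReaderProfile("r", bias_weights=np.array([1e4, 0, 0]))
    img = _image_with(90.0, attrs=[1.0, 0.0, 0.0])
    assert sd.simulate_reader_score(reader, img) == 100.0


# ---------------------------------------------------------------------------
# Reader-pair assignment
# ---------------------------------------------------------------------------

def test_two_readers_label_every_image(small_cohort):
    readers = [sd.ReaderProfile("a"), sd.ReaderProfile("b")]
    labels = sd.assign_reader_pairs(small_cohort, readers, seed=1)
    per_image = labels.groupby("image_id")["reader_id"].agg(set)
    assert all(s == {"a", "b"} for s in per_image)


def test_zero_weight_reader_never_appears(small_cohort):
    readers = [sd.ReaderProfile("a"), sd.ReaderProfile("b"),
               sd.ReaderProfile("c", workload_weight=0.0)]
    labels = sd.assign_reader_pairs(small_cohort, readers, seed=1)
    assert "c" not in set(labels["reader_id"])


def test_too_few_eligible_readers_raises(small_cohort):
    readers = [sd.ReaderProfile("a"),
               sd.ReaderProfile("b", workload_weight=0.0)]
    with pytest.raises(sd.ConfigurationError):
        sd.assign_reader_pairs(small_cohort, readers, seed=1)


def test_label_table_invariants(label_table):
    counts = label_table.groupby("image_id").size()
    assert (counts == 2).all()
    two_distinct = label_table.groupby("image_id")["reader_id"].nunique()
    assert (two_distinct == 2).all()
    assert label_table["score"].between(0, 100).all()


def test_label_determinism(small_cohort, reader_pool):
    a = sd.assign_reader_pairs(small_cohort, reader_pool, seed=99)
    b = sd.assign_reader_pairs(small_cohort, reader_pool, seed=99)
    pd.testing.assert_frame_equal(a, b)


def test_workload_counts_match_assignment_scheme_oracle():
    """Per-reader assignment counts must fall in the central 99% range of
    the scheme's own sampling distribution, re-simulated independently:
    Dirichlet pair-workload shares (mean proportional to the weight
    product) followed by one categorical pair draw per session."""
    n_subjects, m, per_session = 1250, 13, 6
    rng = np.random.default_rng(21)
    weights = rng.lognormal(0.0, 0.6, size=m)
    readers = [sd.ReaderProfile(f"R{j:02d}", workload_weight=w)
               for j, w in zip(range(m), weights)]
    # lightweight cohort: reuse one rendered image, one image per subject
    base = sd.generate_cohort(sd.CohortConfig(n_subjects=1, image_size=16,
                                              seed=0)).images[0]
    images = [sd.SyntheticImage(f"i{i}", f"s{i}", "CC", "R", base.pixels,
                                base.true_density, base.texture_attributes)
              for i in range(n_subjects)]
    cohort = sd.SyntheticCohort(images=images, subjects=pd.DataFrame(
        {"subject_id": [f"s{i}" for i in range(n_subjects)],
         "density": np.zeros(n_subjects), "age": np.zeros(n_subjects)}))
    labels = sd.assign_reader_pairs(cohort, readers, seed=5,
                                    subjects_per_session=per_session)
    observed = labels["reader_id"].value_counts().reindex(
        [r.reader_id for r in readers], fill_value=0).to_numpy()

    # independent re-simulation of the scheme, 400 replicates
    pairs = np.array([(i, j) for i in range(m) for j in range(i + 1, m)])
    base_p = weights[pairs[:, 0]] * weights[pairs[:, 1]]
    base_p = base_p / base_p.sum()
    alpha = 0.15 * len(pairs) * base_p
    session_sizes = [min(per_session, n_subjects - s)
                     for s in range(0, n_subjects, per_session)]
    orng = np.random.default_rng(777)
    counts = np.zeros((400, m), dtype=int)
    for rep in range(400):
        shares = orng.dirichlet(alpha)
        chosen = orng.choice(len(pairs), size=len(session_sizes), p=shares)
        for k, sz in zip(chosen, session_sizes):
            counts[rep, pairs[k, 0]] += sz
            counts[rep, pairs[k, 1]] += sz
    lo = np.percentile(counts, 0.5, axis=0)
    hi = np.percentile(counts, 99.5, axis=0)
    inside = (observed >= lo) & (observed <= hi)
    # reader counts are positively coupled through their shared pair, so a
    # single extreme pair draw moves two readers out of band together
    assert inside.sum() >= m - 2, (observed, lo, hi)


# ---------------------------------------------------------------------------
# Variability-component properties
# ---------------------------------------------------------------------------

def test_warped_readers_agree_on_order(small_cohort):
    """Two noiseless readers differing only in warp give Spearman 1."""
    r1 = sd.ReaderProfile("a", warp_a=0.6, warp_b=1.8)
    r2 = sd.ReaderProfile("b", warp_a=2.2, warp_b=0.8)
    s1 = [sd.simulate_reader_score(r1, im) for im in small_cohort.images]
    s2 = [sd.simulate_reader_score(r2, im) for im in small_cohort.images]
    assert spearmanr(s1, s2).statistic == pytest.approx(1.0)


def test_paired_noise_rmse_is_sqrt_two_times_sd(small_cohort):
    """With only random error active, the RMSE between the two readers'
    scores of the same images is noise_sd * sqrt(2)."""
    noise_sd = 6.0
    rng = np.random.default_rng(3)
    diffs = []
    for im in small_cohort.images:
        if not (20 < im.true_density < 80):
            continue  # keep the clip inactive
        r = sd.ReaderProfile("x", noise_sd=noise_sd)
        s1 = sd.simulate_reader_score(r, im, seed=rng)
        s2 = sd.simulate_reader_score(r, im, seed=rng)
        diffs.append(s1 - s2)
    # use many repeats for a stable estimate
    for _ in range(30):
        for im in small_cohort.images:
            if not (20 < im.true_density < 80):
                continue
            r = sd.ReaderProfile("x", noise_sd=noise_sd)
            diffs.append(sd.simulate_reader_score(r, im, seed=rng)
                         - sd.simulate_reader_score(r, im, seed=rng))
    observed = np.sqrt(np.mean(np.square(diffs)))
    assert observed == pytest.approx(noise_sd * np.sqrt(2), rel=0.06)


def test_variance_components_add_up(small_cohort):
    """Between-reader score variance on shared images decomposes into the
    warp, bias, and noise contributions when switched on one at a time."""
    rng = np.random.default_rng(8)
    imgs = small_cohort.images
    # noise only: var of (s1 - s2) = 2 sd^2
    sd_n = 5.0
    r = sd.ReaderProfile("n", noise_sd=sd_n)
    d_noise = np.array([
        sd.simulate_reader_score(r, im, seed=rng)
        - sd.simulate_reader_score(r, im, seed=rng)
        for im in imgs for _ in range(10) if 20 < im.true_density < 80])
    assert np.var(d_noise) == pytest.approx(2 * sd_n**2, rel=0.15)

    # bias only: difference equals (b1 - b2) . attrs exactly
    r1 = sd.ReaderProfile("b1", bias_weights=np.array([3.0, -2.0, 1.0]))
    r2 = sd.ReaderProfile("b2", bias_weights=np.array([-1.0, 4.0, 0.0]))
    for im in imgs[:20]:
        delta = (sd.simulate_reader_score(r1, im)
                 - sd.simulate_reader_score(r2, im))
        expected = (r1.bias_weights - r2.bias_weights) @ im.texture_attributes
        assert delta == pytest.approx(expected, abs=1e-9)

    # warp only: difference equals warp1(t) - warp2(t) exactly
    w1 = sd.ReaderProfile("w1", warp_a=0.7, warp_b=1.5)
    w2 = sd.ReaderProfile("w2", warp_a=1.8, warp_b=0.9)
    for im in imgs[:20]:
        delta = (sd.simulate_reader_score(w1, im)
                 - sd.simulate_reader_score(w2, im))
        expected = float(w1.warp(im.true_density) - w2.warp(im.true_density))
        assert delta == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# Case-control subset
# ---------------------------------------------------------------------------

def _subjects_only_cohort(n, seed=0):
    rng = np.random.default_rng(seed)
    return sd.SyntheticCohort(images=[], subjects=pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "density": 100.0 * rng.beta(2.0, 3.5, size=n),
        "age": rng.normal(60, 8, size=n)}))


def test_case_control_group_sizes_exact():
    cohort = _subjects_only_cohort(1500)
    cc = sd.generate_case_control(cohort, risk_slope=0.03, n_cases=338,
                                  controls_per_case=3, seed=1)
    assert cc["is_case"].sum() == 338
    assert (~cc["is_case"]).sum() == 1014
    sizes = cc.groupby("match_group")["is_case"].agg(["sum", "count"])
    assert (sizes["sum"] == 1).all() and (sizes["count"] == 4).all()
    assert cc["subject_id"].is_unique


def test_case_control_insufficient_controls_raises():
    cohort = _subjects_only_cohort(10)
    with pytest.raises(sd.SamplingError):
        sd.generate_case_control(cohort, 0.0, n_cases=5, controls_per_case=3)


def test_case_control_age_matching_tightens_age_gap():
    cohort = _subjects_only_cohort(1200, seed=3)
    cc = sd.generate_case_control(cohort, 0.0, n_cases=50, seed=2)
    gaps = []
    for _, grp in cc.groupby("match_group"):
        case_age = grp.loc[grp["is_case"], "age"].iloc[0]
        gaps.append((grp.loc[~grp["is_case"], "age"] - case_age).abs().mean())
    ages = cohort.subjects["age"].to_numpy()
    random_gap = np.abs(np.subtract.outer(ages, ages)).mean()
    assert np.mean(gaps) < random_gap / 3


def test_case_density_exceeds_controls_under_strong_slope():
    cohort = _subjects_only_cohort(1200, seed=4)
    cc = sd.generate_case_control(cohort, risk_slope=0.25, n_cases=50, seed=5)
    case_mean = cc.loc[cc["is_case"], "density"].mean()
    control_mean = cc.loc[~cc["is_case"], "density"].mean()
    assert case_mean > control_mean + 10
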