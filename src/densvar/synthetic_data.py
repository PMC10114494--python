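"""Synthetic mammogram-like cohorts with simulated expert readers.

Real screening mammograms with paired visual-analogue-scale (VAS) density
scores are not publicly available, so this module generates a cohort with a
*known* latent density and simulates the reader process on top of it.  That
makes every downstream stage — preprocessing, the ridge mapping, end-to-end
training, the case-control risk analysis — testable against ground truth.

The image generator places bright Gaussian "dense tissue" blobs on a darker
breast-shaped mask; the latent density of an image is the percentage of the
mask the generator aims to cover with dense tissue, so mean breast intensity
rises monotonically with density and the signal is genuinely learnable.

Simulated readers embody three distinct sources of inter-reader variability:

1. **Systematic assessment differences** — a per-reader linear response to
   latent texture attributes of the image (blob count, blob size,
   clustering), so two readers can genuinely disagree about the same image.
2. **Distribution differences** — a strictly monotone warp of the density
   scale (a scaled beta CDF), so two readers can use the 0-100 scale
   differently while agreeing on the ranking of images.
3. **Random error** — additive Gaussian noise in VAS points.

A reader's score is ``clip(warp(true_density) + bias·texture + noise, 0, 100)``.
Each image is scored by exactly two readers drawn from a pool by
workload-weighted sampling, mimicking pragmatic assignment in a screening
programme; heavy reader pairs emerge naturally, which the per-pair subset
experiments rely on.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "SyntheticImage",
    "ReaderProfile",
    "SyntheticCohort",
    "CohortConfig",
    "generate_cohort",
    "make_reader_pool",
    "simulate_reader_score",
    "assign_reader_pairs",
    "generate_case_control",
    "write_cohort",
    "ConfigurationError",
    "SamplingError",
]

VIEWS = ("CC", "MLO")
LATERALITIES = ("L", "R")
N_TEXTURE_ATTRIBUTES = 3


class ConfigurationError(ValueError):
    pass


class SamplingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SyntheticImage:
    image_id: str
    subject_id: str
    view: str                      # "CC" or "MLO"
    laterality: str                # "L" or "R"
    pixels: np.ndarray             # 2-D float array in [0, 1]
    true_density: float            # percent, in [0, 100]
    texture_attributes: np.ndarray # latent descriptors driving reader bias


@dataclass
class ReaderProfile:
    """Parameters of one simulated reader.

    ``warp_a``/``warp_b`` parameterise a scaled beta-CDF warp of the density
    scale: strictly monotone on [0, 100] and fixing both endpoints.  With
    ``warp_a == warp_b == 1`` the warp is the identity.
    """

    reader_id: str
    warp_a: float = 1.0
    warp_b: float = 1.0
    bias_weights: np.ndarray = field(
        default_factory=lambda: np.zeros(N_TEXTURE_ATTRIBUTES))
    noise_sd: float = 0.0
    workload_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.warp_a <= 0 or self.warp_b <= 0:
            raise ConfigurationError("warp parameters must be positive")
        if self.noise_sd < 0 or self.workload_weight < 0:
            raise ConfigurationError("noise_sd and workload_weight must be >= 0")
        self.bias_weights = np.asarray(self.bias_weights, dtype=float)

    def warp(self, density):
        """Monotone distribution warp: 100 * BetaCDF(density/100; a, b)."""
        d = np.clip(np.asarray(density, dtype=float), 0.0, 100.0)
        return 100.0 * stats.beta.cdf(d / 100.0, self.warp_a, self.warp_b)


@dataclass
class SyntheticCohort:
    images: list[SyntheticImage]
    subjects: pd.DataFrame         # subject_id, density, age

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "image_id": [im.image_id for im in self.images],
                "subject_id": [im.subject_id for im in self.images],
                "view": [im.view for im in self.images],
                "laterality": [im.laterality for im in self.images],
                "true_density": [im.true_density for im in self.images],
            }
        )

    def image_map(self) -> dict[str, SyntheticImage]:
        return {im.image_id: im for im in self.images}

    def __len__(self) -> int:
        return len(self.images)


@dataclass
class CohortConfig:
    """Cohort-level generator settings.

    ``density_alpha``/``density_beta`` give the Beta distribution of
    subject-level density (scaled to [0, 100]); the default Beta(2, 3.5) is
    right-skewed, as screening populations are.  The four views of a subject
    share the subject-level density with per-view Gaussian jitter of
    ``within_subject_sd`` VAS points.
    """

    n_subjects: int = 100
    image_size: int = 64
    within_subject_sd: float = 2.0
    missing_view_rate: float = 0.0
    density_alpha: float = 2.0
    density_beta: float = 3.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ConfigurationError("n_subjects must be >= 0")
        if self.image_size < 16:
            raise ConfigurationError("image_size must be >= 16")
        if not 0.0 <= self.missing_view_rate < 1.0:
            raise ConfigurationError("missing_view_rate must be in [0, 1)")
        if self.within_subject_sd < 0:
            raise ConfigurationError("within_subject_sd must be >= 0")


# ---------------------------------------------------------------------------
# Image synthesis
# ---------------------------------------------------------------------------

def _breast_mask(size: int, view: str, laterality: str) -> np.ndarray:
    """Half-ellipse breast region anchored to the chest-wall edge."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = size / 2.0
    # MLO projections show a taller breast profile than CC
    ry = 0.46 * size if view == "CC" else 0.58 * size
    rx = 0.85 * size
    cx = 0.0 if laterality == "L" else size - 1.0
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _render_image(size: int, view: str, laterality: str, true_density: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Place Gaussian dense-tissue blobs until the target mask coverage.

    Returns (pixels, texture_attributes).  Dense tissue is bright on a darker
    fatty background, so mean breast intensity increases with density.
    """
    mask = _breast_mask(size, view, laterality)
    mask_area = int(mask.sum())
    background = 0.22 + 0.05 * ndimage.gaussian_filter(
        rng.standard_normal((size, size)), sigma=size / 8.0)

    target = true_density / 100.0
    dense = np.zeros((size, size))
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    ys, xs = np.nonzero(mask)
    centers: list[tuple[float, float]] = []
    sigmas: list[float] = []
    max_blobs = 400
    while centers.__len__() < max_blobs:
        covered = np.count_nonzero(dense[mask] > 0.35) / mask_area
        if covered >= target:
            break
        j = rng.integers(0, ys.size)
        cy, cx = float(ys[j]), float(xs[j])
        sigma = float(rng.uniform(0.035, 0.09)) * size
        dense += np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)))
        centers.append((cy, cx))
        sigmas.append(sigma)

    pixels = background + 0.55 * np.minimum(dense, 1.2) / 1.2
    pixels += 0.01 * rng.standard_normal((size, size))
    pixels = np.clip(pixels, 0.0, 1.0)
    pixels[~mask] = 0.0

    if centers:
        pts = np.asarray(centers)
        if len(centers) > 1:
            diffs = pts[:, None, :] - pts[None, :, :]
            mean_dist = float(np.sqrt((diffs**2).sum(-1)).mean())
        else:
            mean_dist = 0.0
        clustering = 1.0 - min(mean_dist / (0.7 * size), 1.0)
        attrs = np.array([len(centers) / 100.0,
                          float(np.mean(sigmas)) / (0.09 * size),
                          clustering])
    else:
        attrs = np.zeros(N_TEXTURE_ATTRIBUTES)
    return pixels, attrs


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort of four-view subjects with known latent density.

    Each subject contributes up to four images (RCC, LCC, RMLO, LMLO); with a
    positive ``missing_view_rate`` individual views are dropped at random.
    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    densities = 100.0 * rng.beta(config.density_alpha, config.density_beta,
                                 size=config.n_subjects)
    ages = rng.normal(60.0, 8.0, size=config.n_subjects)
    images: list[SyntheticImage] = []
    subject_ids = [f"S{i:05d}" for i in range(config.n_subjects)]
    for i, sid in enumerate(subject_ids):
        for view in VIEWS:
            for lat in LATERALITIES:
                if rng.uniform() < config.missing_view_rate:
                    continue
                td = float(np.clip(
                    densities[i] + rng.normal(0.0, config.within_subject_sd),
                    0.0, 100.0))
                pixels, attrs = _render_image(
                    config.image_size, view, lat, td, rng)
                images.append(SyntheticImage(
                    image_id=f"{sid}_{lat}{view}",
                    subject_id=sid,
                    view=view,
                    laterality=lat,
                    pixels=pixels,
                    true_density=td,
                    texture_attributes=attrs,
                ))
    subjects = pd.DataFrame({"subject_id": subject_ids,
                             "density": densities, "age": ages})
    return SyntheticCohort(images=images, subjects=subjects)


# ---------------------------------------------------------------------------
# Reader simulation
# ---------------------------------------------------------------------------

def make_reader_pool(
    m: int = 13,
    seed: int = 0,
    warp_strength: float = 0.35,
    bias_scale: float = 4.0,
    noise_sd: float = 8.0,
    noise_sd_spread: float = 0.25,
) -> list[ReaderProfile]:
    """Draw a pool of reader profiles with heterogeneous warps, biases, noise.

    ``warp_strength`` is the SD of the log beta-CDF warp parameters (0 means
    every reader uses the identity scale); ``bias_scale`` the SD of the
    per-attribute systematic bias weights in VAS points; ``noise_sd`` the
    typical random-error SD with a multiplicative reader-to-reader spread.
    Workload weights are log-normal, so a few readers dominate assignment as
    they do in practice.
    """
    if m < 2:
        raise ConfigurationError("need at least 2 readers")
    rng = np.random.default_rng(seed)
    readers = []
    for r in range(m):
        readers.append(ReaderProfile(
            reader_id=f"R{r:02d}",
            warp_a=float(np.exp(rng.normal(0.0, warp_strength))),
            warp_b=float(np.exp(rng.normal(0.0, warp_strength))),
            bias_weights=rng.normal(0.0, bias_scale, size=N_TEXTURE_ATTRIBUTES),
            noise_sd=float(noise_sd * np.exp(rng.normal(0.0, noise_sd_spread))),
            workload_weight=float(rng.lognormal(0.0, 0.6)),
        ))
    return readers


def simulate_reader_score(profile: ReaderProfile, image: SyntheticImage,
                          seed: int | np.random.Generator = 0) -> float:
    """One reader's VAS score for one image.

    score = clip(warp(true_density) + bias_weights . texture_attributes
                 + N(0, noise_sd), 0, 100)

    With zero bias weights and no noise the score is exactly the warped true
    density; with the identity warp on top, it is the true density itself.
    """
    if profile.bias_weights.shape != image.texture_attributes.shape:
        raise ValueError(
            f"bias_weights length {profile.bias_weights.size} does not match "
            f"texture_attributes length {image.texture_attributes.size}")
    rng = np.random.default_rng(seed)
    score = float(profile.warp(image.true_density))
    score += float(profile.bias_weights @ image.texture_attributes)
    if profile.noise_sd > 0:
        score += float(rng.normal(0.0, profile.noise_sd))
    return float(np.clip(score, 0.0, 100.0))


def pair_workload_distribution(weights: np.ndarray,
                               concentration: float,
                               rng: np.random.Generator) -> tuple[np.ndarray,
                                                                  np.ndarray]:
    """Draw the session workload shares of each reader pair.

    Pairs (i, j) get Dirichlet-distributed shares with mean proportional to
    ``weights[i] * weights[j]``.  A small ``concentration`` makes the draw
    sparse, so a few pairs dominate the reading volume — the pattern real
    screening programmes show — while large values approach independent
    per-session sampling.  Returns (pairs, shares) where ``pairs`` is an
    (n_pairs, 2) index array.
    """
    m = len(weights)
    pairs = np.array([(i, j) for i in range(m) for j in range(i + 1, m)])
    base = weights[pairs[:, 0]] * weights[pairs[:, 1]]
    base = base / base.sum()
    alpha = concentration * len(pairs) * base
    shares = rng.dirichlet(alpha)
    return pairs, shares


def assign_reader_pairs(cohort: SyntheticCohort,
                        readers: list[ReaderProfile],
                        seed: int = 0,
                        subjects_per_session: int = 6,
                        pair_concentration: float = 0.15) -> pd.DataFrame:
    """Assign two distinct readers to every image and score it.

    Assignment mimics pragmatic reading practice at two levels.  Women are
    processed in *sessions* of ``subjects_per_session`` consecutive
    subjects (in random order) and one reader pair scores every image of a
    session.  Session pairs are drawn from a sparse Dirichlet workload
    distribution over all pairs (mean share proportional to the product of
    the two readers' ``workload_weight``), so a few heavy pairs co-read
    sizeable image sets while many pairs barely occur — the structure the
    per-pair subset experiments rely on.  Zero-weight readers never appear.
    Returns the long-format label table (image_id, reader_id, score).
    """
    eligible = [r for r in readers if r.workload_weight > 0]
    if len(eligible) < 2:
        raise ConfigurationError(
            "need >= 2 readers with positive workload_weight")
    if subjects_per_session < 1:
        raise ConfigurationError("subjects_per_session must be >= 1")
    if pair_concentration <= 0:
        raise ConfigurationError("pair_concentration must be > 0")
    weights = np.array([r.workload_weight for r in eligible])
    rng = np.random.default_rng(seed)
    pairs, shares = pair_workload_distribution(weights, pair_concentration,
                                               rng)

    by_subject: dict[str, list[SyntheticImage]] = {}
    for image in cohort.images:
        by_subject.setdefault(image.subject_id, []).append(image)
    subject_ids = list(by_subject)
    order = rng.permutation(len(subject_ids))

    rows = []
    for start in range(0, len(subject_ids), subjects_per_session):
        j1, j2 = pairs[rng.choice(len(pairs), p=shares)]
        for si in order[start:start + subjects_per_session]:
            for image in by_subject[subject_ids[si]]:
                for j in (j1, j2):
                    reader = eligible[j]
                    score = simulate_reader_score(reader, image, seed=rng)
                    rows.append((image.image_id, reader.reader_id, score))
    return pd.DataFrame(rows, columns=["image_id", "reader_id", "score"])


# ---------------------------------------------------------------------------
# Case-control subset
# ---------------------------------------------------------------------------

def generate_case_control(
    cohort: SyntheticCohort,
    risk_slope: float,
    n_cases: int,
    controls_per_case: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a nested case-control set with density-dependent case risk.

    Case status follows a logistic link in subject-level density: the odds of
    being sampled as a case are proportional to ``exp(risk_slope * density)``
    (slope 0 gives density-independent risk).  Each case is matched to
    ``controls_per_case`` controls nearest in age, without replacement.
    Returns a DataFrame (subject_id, is_case, match_group, age, density).
    """
    subjects = cohort.subjects
    needed = n_cases * (1 + controls_per_case)
    if len(subjects) < needed:
        raise SamplingError(
            f"cohort has {len(subjects)} subjects; need >= {needed} for "
            f"{n_cases} cases with {controls_per_case} controls each")
    rng = np.random.default_rng(seed)
    dens = subjects["density"].to_numpy()
    # Gumbel-max trick: exact weighted sampling without replacement
    logw = risk_slope * (dens - dens.mean())
    keys = logw + rng.gumbel(size=len(subjects))
    case_idx = np.argsort(-keys)[:n_cases]
    is_case = np.zeros(len(subjects), dtype=bool)
    is_case[case_idx] = True

    ages = subjects["age"].to_numpy()
    available = set(np.nonzero(~is_case)[0])
    rows = []
    for g, ci in enumerate(rng.permutation(case_idx)):
        rows.append((subjects["subject_id"].iat[ci], True, g,
                     ages[ci], dens[ci]))
        pool = np.fromiter(available, dtype=int)
        order = np.argsort(np.abs(ages[pool] - ages[ci]))
        chosen = pool[order[:controls_per_case]]
        if chosen.size < controls_per_case:
            raise SamplingError("insufficient controls for matching")
        for j in chosen:
            rows.append((subjects["subject_id"].iat[j], False, g,
                         ages[j], dens[j]))
            available.discard(int(j))
    return pd.DataFrame(
        rows, columns=["subject_id", "is_case", "match_group", "age", "density"])


# ---------------------------------------------------------------------------
# On-disk representation
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, out_dir: str,
                 labels: pd.DataFrame | None = None,
                 case_control: pd.DataFrame | None = None) -> None:
    """Write PNG images plus metadata/label/case-control CSVs."""
    import imageio.v3 as iio

    img_dir = os.path.join(out_dir, "images")
    os.makedirs(img_dir, exist_ok=True)
    for im in cohort.images:
        iio.imwrite(os.path.join(img_dir, f"{im.image_id}.png"),
                    (im.pixels * 255.0).round().astype(np.uint8))
    cohort.metadata().to_csv(os.path.join(out_dir, "metadata.csv"), index=False)
    cohort.subjects.to_csv(os.path.join(out_dir, "subjects.csv"), index=False)
    if labels is not None:
        labels.to_csv(os.path.join(out_dir, "labels.csv"), index=False)
    if case_control is not None:
        case_control.to_csv(os.path.join(out_dir, "case_control.csv"),
                            index=False)
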