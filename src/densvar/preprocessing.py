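"""Image standardization and subject-level partitioning.

All density models in this package consume identically prepared inputs.  The
chain, applied in this order, is:

    resize -> flip left-sided images to the right -> percentile intensity
    clip -> invert -> histogram equalization -> rescale to [0, 1]

Inversion reflects mammography convention, where dense (radiodense) tissue
appears at one end of the raw intensity scale; equalization spreads breast
tissue over the full dynamic range.  The chain is fully deterministic.

Partitioning is always by subject (woman): all four views of a subject land
in the same split, so no model is ever evaluated on a view of a woman it
trained on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure, transform

from .synthetic_data import SyntheticImage

__all__ = ["PreprocessConfig", "preprocess_image", "split_by_subject"]


@dataclass
class PreprocessConfig:
    """Standardization settings.

    clip_low / clip_high are intensity *percentiles* (defaults 1 and 99 —
    a mild dynamic-range limit); resizing uses bilinear interpolation;
    equalization is global with ``n_equalization_bins`` bins.
    """

    target_size: int = 224
    clip_low: float = 1.0
    clip_high: float = 99.0
    n_equalization_bins: int = 256
    invert: bool = True
    flip_left_to_right: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.clip_low < self.clip_high <= 100.0):
            raise ValueError("require 0 <= clip_low < clip_high <= 100")
        if self.target_size < 16:
            raise ValueError("target_size must be >= 16")
        if self.n_equalization_bins < 2:
            raise ValueError("n_equalization_bins must be >= 2")


def preprocess_image(
    image: SyntheticImage | np.ndarray,
    config: PreprocessConfig | None = None,
    laterality: str | None = None,
) -> np.ndarray:
    """Apply the full standardization chain to one image.

    Accepts either a :class:`SyntheticImage` (laterality taken from its
    metadata) or a raw 2-D array with ``laterality`` given explicitly
    (defaults to "R", i.e. no flip).  Returns a ``target_size x target_size``
    float array in [0, 1].  A constant (degenerate) input yields a constant
    output rather than a numeric failure.
    """
    config = config or PreprocessConfig()
    if isinstance(image, SyntheticImage):
        pixels, lat = image.pixels, image.laterality
    else:
        pixels, lat = np.asarray(image, dtype=float), (laterality or "R")
    if pixels.ndim != 2 or pixels.size == 0:
        raise ValueError("expected a non-empty 2-D pixel grid")

    out = transform.resize(pixels, (config.target_size, config.target_size),
                           order=1, mode="reflect", anti_aliasing=True)
    if config.flip_left_to_right and lat == "L":
        out = np.fliplr(out)

    lo, hi = np.percentile(out, [config.clip_low, config.clip_high])
    if hi <= lo:  # degenerate (constant) image: clip/equalize are no-ops
        return np.full_like(out, float(np.clip(out.flat[0], 0.0, 1.0)))
    out = np.clip(out, lo, hi)
    if config.invert:
        out = hi - (out - lo)
    out = exposure.equalize_hist(out, nbins=config.n_equalization_bins)
    return rescale_unit(out)


def rescale_unit(pixels: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; idempotent; constant input maps to 0."""
    pixels = np.asarray(pixels, dtype=float)
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi <= lo:
        return np.zeros_like(pixels)
    return (pixels - lo) / (hi - lo)


def split_by_subject(
    subject_ids,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    exclude=(),
) -> dict[str, set]:
    """Partition unique subjects into train/val/test by the given fractions.

    ``exclude`` subjects (e.g. the case-control set) are removed before
    splitting so they never enter training or validation.  Deterministic per
    seed.  Returns {"train": set, "val": set, "test": set}.
    """
    if len(fractions) != 3 or not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must be three values summing to 1")
    uniq = sorted(set(subject_ids) - set(exclude))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(uniq))
    n_train = int(round(fractions[0] * len(uniq)))
    n_val = int(round(fractions[1] * len(uniq)))
    train = {uniq[i] for i in perm[:n_train]}
    val = {uniq[i] for i in perm[n_train:n_train + n_val]}
    test = {uniq[i] for i in perm[n_train + n_val:]}
    return {"train": train, "val": val, "test": test}
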