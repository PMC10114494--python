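# Methods

`densvar` studies how inter-reader variability in visual-analogue-scale
(VAS) breast-density labels affects models trained to predict density from
mammograms.  Deep density models decompose into a *representation* (image →
feature vector) and a *mapping* (feature vector → score); label variability
can corrupt either.  The package separates the two questions:

1. **Mapping** — fix the representation, fit the closed-form ridge mapping
   on different label subsets, and see how metrics move.
2. **Representation** — train two networks end-to-end that differ only in
   how they consume labels (averaged vs per-reader with a masked loss),
   strip both to their penultimate features, fit the *same* linear probe,
   and compare.

Because no screening dataset with paired VAS scores is publicly
distributable, all analyses run on a synthetic cohort with a known latent
density, which makes the two questions answerable against ground truth.

## The reader-variability model

A simulated reader scores an image as

    score = clip( warp(t) + b · a + ε , 0, 100 )

where `t` is the image's latent density (percent), and the three terms
implement the three recognized components of inter-reader variability:

- **Systematic assessment differences** — `b · a`: a per-reader linear
  response (weights `b`, SD 4 VAS points per attribute) to latent texture
  attributes `a` of the image (dense-blob count, blob size, clustering).
  Two readers can genuinely disagree about the same image, in a way that is
  correlated with what the image looks like.
- **Distribution differences** — `warp`: a strictly monotone map of the
  density scale, parameterized as a scaled beta CDF
  `warp(t) = 100·F_beta(t/100; α, β)` with `log α, log β ~ N(0, 0.35²)` per
  reader.  It fixes 0 and 100 and preserves order: two noiseless readers
  differing only in warp have Spearman correlation exactly 1, which the
  test suite verifies.
- **Random error** — `ε ~ N(0, σ_r²)` with σ_r ≈ 8 VAS points (spread ×
  `exp(N(0, 0.25²))` across readers).  With only this component active the
  RMSE between the two readers of an image is σ√2, also verified by
  simulation.

The magnitudes are free parameters of the generator; the defaults give an
inter-reader RMSE of ≈18 VAS points and a paired-reader Spearman of ≈0.6 on
shared images — substantial disagreement, consistent with the premise that
reader variation is large enough to matter.

## The image generator

Images are 2-D grayscale grids in [0, 1]: a breast-shaped half-ellipse mask
(anchored to the chest-wall edge given by laterality; taller for MLO than
CC projections) holding a darker fatty background plus bright Gaussian
"dense tissue" blobs.  Blobs are added until the thresholded dense area
covers `t`% of the mask, so the latent density is visually and
statistically present: mean breast intensity rises monotonically with `t`
(rank correlation > 0.9, tested).  Each woman contributes four views (RCC,
LCC, RMLO, LMLO) sharing one subject-level density drawn from
Beta(2, 3.5)·100 (right-skewed, as screening populations are), with
per-view jitter of SD 2 VAS points.

What the generator does *not* emulate: radiographic physics, pectoral
muscle, scanner intensity profiles, lesions, or intra-reader drift over
time.  Passing tests therefore demonstrate the *logic* of the analyses
(what label variability does to mappings and representations when a true
density exists), not performance on real mammograms.

## Reader-pair assignment

Each image is scored by exactly two readers from a pool of m = 13.
Assignment mimics pragmatic reading practice at two levels: women are
processed in sessions of 6 consecutive subjects, one pair per session, and
session pairs are drawn from a sparse Dirichlet workload distribution whose
mean is proportional to the product of the two readers' log-normal workload
weights (concentration 0.15).  This reproduces the structure real
programmes show — a few heavy pairs jointly reading a sizeable share of the
volume, many pairs barely occurring — which the per-pair subset experiments
require.  A resampling oracle in the tests re-simulates the scheme
independently and checks the per-reader count distribution.

## Preprocessing

The standardization chain, in order: bilinear resize to the target size
(224 default; 32 or 64 at desk scale) → flip left-sided images to the right
→ clip intensities to the (1, 99) percentiles → invert → global histogram
equalization (256 bins) → min–max rescale to [0, 1].  Degenerate constant
images pass through as constants.  Whether inversion precedes or follows
clipping is a convention here (clip → invert); the chain is deterministic
either way.  Splits are always by woman.

## Method 1: the ridge mapping and subset experiments

Features X (n × (p+1), bias column appended) map to scores through

    w = (XᵀX + λ₂ I)⁻¹ Xᵀ y ,        ŷ = X w

solved by Cholesky factorization of the normal equations (never an explicit
inverse); λ₂ = 1.0 by default, features unstandardized, bias penalized
exactly as the formula states.  All predictions are held-out via five-fold
CV with folds split by woman.  Being closed-form, the mapping is exactly
reproducible, so metric differences between label regimes are attributable
to the labels.

The default feature extractor (`TextureBackbone`, p = 56) reflects what
survives preprocessing: global equalization flattens each image's intensity
histogram, so density information is carried by *morphology*, not by
intensity levels.  For four intensity thresholds it measures the candidate
dense region's area fraction, connected-component count, boundary length
and mean/largest component size, plus 2×2-pooled intensities and a small
seeded random filter bank.  It is deterministic, training-free, and reaches
a held-out rank correlation of ≈0.84 against the latent density at 1,000
images.  Any callable producing per-image feature rows (e.g. a pretrained
deep backbone) can be substituted.

Experiments:

- **Tr/Ts grid** — train and test on averaged (Av) vs individual (Ind)
  labels.  Ind training uses each (image, reader score) pair as a row; the
  ridge penalty in that cell is scaled by the duplication factor so the
  regularization *per image* matches the Av cell.  (With two scores per
  image this makes Ind and Av training provably identical — duplicated-row
  least squares is weighted averaged-label least squares — which is why
  the training-label choice barely moves metrics while the test-label
  choice moves them a lot.)  Ind testing evaluates each prediction against
  both reader scores.
- **Per-reader subsets** — train and test on one reader's own scores.
- **Per-pair subsets** — train and test on one pair's averaged scores over
  the images that pair jointly read.

Subsets below an inclusion threshold are reported as excluded.  The
threshold is expressed in images and defaults to 400 per `SubsetSpec`; the
desk-scale pipelines use 100 images = 25 women, enough for stable
subject-level five-fold CV (the inclusion rule in the underlying study
design is likewise quoted in women).

Aggregates follow the two standard conventions: **Av1** is the unweighted
mean of per-subset metrics with the across-subset SD as its uncertainty;
**Av2** recomputes the metric on all pooled prediction/label pairs (and is
*not* the weighted mean of per-subset metrics — a property the tests pin
down with a pooled-recompute oracle).

## Method 2: single- vs multi-predictor training

Both models share a small convolutional trunk — [3×3 conv → ReLU → 2×2
average pool] × 2 → 3×3 conv → ReLU → global average pooling → linear to a
64-dimensional penultimate layer → ReLU — implemented directly in numpy
(im2col convolutions, full backprop, Adam), float32, fully seeded.  The
single-predictor has one output trained on the per-image reader average.
The multi-predictor has m = 13 outputs, one per reader, trained with the
masked squared-error loss

    loss = Σᵢ φᵢ (ρᵢ − dᵢ)²

where φᵢ = 1 iff reader i scored the image (exactly two per image).  The
gradient at a masked output is exactly zero — verified by finite
differences — so only the head rows of observed readers update while the
trunk learns from every image; a reader absent from training keeps its head
row bit-identical to initialization (Adam moments stay zero).  The batch
loss divides by the number of unmasked terms so both objectives see
comparable gradient scales.  Unknown labels hold NaN sentinels that are
masked out *before* subtraction and never enter arithmetic.

Conditioning choices that matter: inputs are standardized with fixed
constants (mean 0.5, scale 0.3 — the moments of an equalized [0, 1] image)
and the head output is multiplied by 100 so head parameters stay O(1) while
predictions are in VAS units.  Without these, Adam spends most of a short
schedule escaping the predict-the-mean plateau; with them both objectives
converge within ten epochs at learning rate 3·10⁻³ on the desk-scale
problem (≈2,000 training images at 64×64).  The learning-rate sweep
machinery trains one model per rate and keeps the lowest validation RMSE;
multi-mode validation RMSE is computed per-reader on unmasked outputs
(a convention — the alternative of validating against averages is not
used).  Early stopping: patience 5 on validation RMSE; epochs default 30
(10 in the desk-scale comparisons).  Divergent rates are recorded and
skipped.

Augmentation: horizontal flip with probability 0.5, rotation up to ±10°,
Gaussian pixel noise (SD 0.01).  Draws are keyed by (seed, epoch, image
index) and the image order by the seed alone, so single and multi runs
consume identical schedules and differences are objective-driven; the
desk-scale representation comparison disables rotation (interpolated
rotations dominate runtime without changing the comparison, which keeps a
full five-seed study in the minutes range).

## Linear probes and representation comparison

Each model (single, multi, and an untrained seeded trunk as control) is
reduced to its penultimate 64-dimensional representation on the held-out
test women; the identical ridge mapping (same λ₂, same fold plan) is fitted
on top.  Label regimes: `Av` (train/test on averages), `Ind1` (per-reader
mappings tested against averages, metrics averaged across readers ± SD),
`Ind2` (same mappings, metrics on the pooled predictions).  Pairwise
prediction similarity (Spearman + RMSE) between models quantifies how close
the representations are *as seen through a linear map*; two representations
equal up to an invertible affine map provably give identical probe
predictions as λ₂ → 0, and the tests exercise exactly that property.

## Evaluation

Spearman rank correlation (average ranks on ties; undefined on constant
input, returned as NaN rather than a silent 0) and RMSE, with 95%
percentile-bootstrap intervals over 1,000 resamples of image-level pairs
(resamples with undefined metrics are redrawn, capped).  Percentile rather
than BCa: the simpler interval is adequate at the sample sizes used and its
coverage is verified by simulation (93–97% at n = 200).

Case-control risk: each case woman is matched to three controls nearest in
age; case odds are proportional to `exp(slope · density)` (slope 0 = null).
The subject-level density for risk scoring is the mean of the subject's
per-image predictions.  Quintile boundaries come from the control score
distribution; the odds ratio compares top vs bottom quintile with a
log-normal CI and the Haldane–Anscombe 0.5 correction (flagged) when a cell
is empty.  Marginal quintile counts are used rather than a conditional
model stratified on the matching — the simpler estimator is the one being
exercised, and the null simulations confirm it is centred at OR = 1.

## Problem sizes and numerical conventions

Desk-scale defaults, chosen so a full study runs on one CPU in minutes:
mapping experiments use ~1,000-image cohorts at 32×32 with 20 seeded
realizations; data-size curves use a 2,000-image cohort subsampled to
{2,000, 1,000, 500, 200}; representation training uses ~2,000 training
images at 64×64 for 10 epochs, five seeds.  Ties in Spearman are handled by
average ranks; rank-deficient designs at λ₂ = 0 raise an error naming the
remedy; fold sizes differ by at most one subject; all randomness flows
from explicit integer seeds.

## Known limitations

- Synthetic images are caricatures; absolute metric values have no clinical
  meaning — only the *relative* patterns between label regimes do.
- The untrained-trunk control stands in for an ImageNet-pretrained
  backbone; with a genuinely pretrained plug-in the control would start
  stronger and fine-tuning gains would be smaller.
- The numpy trunk is intentionally small; it demonstrates representation
  effects, not state-of-the-art density accuracy.
- Odds ratios ignore the matching in estimation (marginal quintile
  counts); conditional logistic modelling is out of scope.
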