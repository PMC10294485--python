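# Methods

`histomil` implements a weakly-supervised multiple-instance learning (MIL)
pipeline for classifying whole-slide histology images (tumor vs control) when
the training data come from several centers, together with the evaluation and
diagnostic machinery needed to detect the failure mode such data invite: a
model that learns to recognize the *source* of a slide instead of its biology.
Everything is exercised end to end on synthetic multi-center cohorts whose
class signal, stain variation and class–dataset confounding are known by
construction.

## The classification model

A slide is represented by bags of tiles. From each slide's tile store,
`tiles_per_slide` tiles (default 200) are drawn uniformly without replacement
— topped up by re-drawn permutations when a slide holds fewer tiles — and
partitioned into consecutive bags of `bag_size` (default 100), so every slide
yields two bags. Every tile inherits the slide's global label (weak
supervision: not every tile of a tumor slide contains tumor).

Per-tile features come from a convolutional backbone; the bag feature is the
arithmetic mean of its tile features (average pooling — order-invariant by
construction); a single linear layer maps the pooled feature to two class
logits. Training minimizes cross-entropy on bag labels with AdamW
(lr 1e-3, decoupled weight decay 0.01, one optimizer step per
`max(1, batch_size // bag_size)` bags with `batch_size` = 64 tiles), with
horizontal/vertical flip augmentation (each with probability 1/2), input
scaled to [0, 1] and standardized with the ImageNet channel statistics, the
head Xavier-initialized, up to 100 epochs with early stopping (patience 20)
on patient-level validation accuracy, restoring the best-epoch parameters.
The 80–20 train/validation split is stratified by patient-class entity.

The default backbone, `small_cnn`, is a three-block network sized for CPU
training on desk-scale slides: two frozen 3×3 conv blocks (3→8 with 4×
max-pooling, 8→16 with 8× max-pooling) act as a fixed texture filter bank —
their weights are package constants playing the role a pretrained network's
early layers play at full scale — followed by one trainable 3×3 conv block
(16→64) and global average pooling, giving a 64-dimensional tile feature.
Only the last conv block and the head are trained, mirroring the common
fine-tuning regime in which all but the last convolutional layer of a
pretrained extractor stay frozen. A `resnet50_imagenet` configuration value
(D = 2048, head width 2048) names the full-scale variant, but it cannot be
constructed here because pretrained weights cannot ship inside a source-only
package; requesting it raises a clear error. Frozen-block outputs are
memoized per (tile, flip, normalizer) — a pure caching layer that changes
no numerics but makes repeated folds and seeds tractable on one CPU.

Slide-level probability is the arithmetic mean of the slide's bag
probabilities (a mean of points on the simplex stays on the simplex). How
several bags combine into one slide prediction is not prescribed by the bag
formulation itself; the mean is consistent with the averaging style used
everywhere else in the pipeline. Per-tile probabilities (for inspecting how
predictions distribute across tissue) run the head on each un-pooled tile
feature, i.e. a bag of one.

## Preprocessing

Tiling. A non-overlapping 256×256 grid anchored at the slide origin; partial
edge tiles are dropped. One global Otsu threshold on the 256-bin grayscale
histogram separates (darker) tissue from bright background; the threshold is
the cut maximizing between-class variance, ties broken toward the smallest
cut. A tile is kept iff its background fraction (non-tissue pixels of the
global mask inside the tile) is ≤ 0.60 — strictly more than 60% background
discards it — and its grayscale standard deviation is ≥ 8 on the 0–255
scale. The low-contrast rule is this package's own operationalization (the
underlying idea, discarding featureless tiles, does not fix a number): 8 is
low enough that any textured tissue passes and high enough to reject blank
or blurred tiles. When more than 4000 tiles survive, a uniform random
subsample of 4000 is drawn with a per-slide seed derived from the global
seed and slide id, over tile ids, so the kept set is independent of grid
traversal order. Stores round-trip losslessly through one HDF5 file per
slide (datasets `tiles`, `origins`, `background_fraction`, `contrast_stat`
plus scalar attributes).

Stain normalization. Reinhard color transfer in Ruderman's lαβ space, fast
variant: RGB (scaled to [0, 1]) → LMS via the fixed 3×3 matrix, `log(LMS+1)`
(the +1 guards black pixels; the log base cancels inside the affine
transfer), then the fixed orthogonal opponent transform. Each tile channel
is affinely mapped so its mean and standard deviation equal the stored
target, then mapped back to RGB with gamut clipping. No separate
percentile-based brightness standardization is applied before the transfer
(that is the step the "fast" variant removes); the luminance channel goes
through the same affine map as the opponent channels. Pre-clipping, the
output moments equal the targets exactly; clipping perturbs them slightly
(bounded at 2% in the tests for tissue-like tiles). Blank (zero-variance)
tiles pass through unchanged with a warning. The shipped preset target is
the lαβ statistics of a deterministic synthetic H&E-like reference tile
generated in code — a synthetic stand-in chosen because no published
constants exist for the upstream preset it emulates; results are therefore
relative to this package's reference, which `fit_reinhard` can replace with
any user reference image. Normalization happens at training/inference time
on bag tiles and is never baked into tile stores.

## Patient-level evaluation

The unit of evaluation is the entity (patient, class): a patient with one
tumor and one control slide contributes one entity per class, because the
two represent different tissue states. Folds partition entities —
stratified round-robin dealing per class (per-fold class counts within one
of parity) or one fold per group value (the per-country protocol). A
patient's slides never straddle a split within a class; a dual-class
patient's two entities may legitimately fall on opposite sides, and the
leakage guard asserts entity- and slide-level disjointness accordingly.

A patient's final probability is the componentwise mean of the slide
probabilities followed by a softmax of the mean vector; a single slide's
prediction is used directly, without softmax. The two branches genuinely
disagree (softmax of (0.9, 0.1) is (0.69, 0.31)); the single-slide
passthrough is the documented behavior, and `softmax_single=True` exposes
the uniform alternative. Metrics are patient-level: accuracy and the 2×2
confusion from argmax (ties toward tumor — conservative for screening),
binary F1 with tumor positive, AUC as the rank statistic of the tumor
probability (half-credit ties, undefined with one class).

Protocols: within-cohort stratified k-fold CV (each fold's training part
re-split 80–20); train on one cohort (80–20), test on another; pool several
cohorts for training, test on a held-out cohort. Every run checks
train/test disjointness programmatically. A label-permutation mode shuffles
entity labels before training (slides of an entity move together) as a
negative control.

## Batch-effect diagnosis

Per slide, the mean of bag-pooled pre-head features is the slide's
representation. For a labelling of the slides, the k-NN purity (k = 10,
Euclidean, self excluded, distance ties broken by row order) is the mean
fraction of each slide's k nearest neighbors sharing its label. The
confounding index is dataset purity minus class purity: positive values
mean feature space organizes by origin more than by biology — the
quantitative form of the colored-cluster-plot diagnosis. A deterministic
2-D UMAP embedding is produced for visual reporting only; quantitative
claims always use the original features. Purities are computed on raw
(unstandardized) features because the head consumes them unstandardized.

Note a structural property of the index on a confounded pair: with A = 20
tumor + 2 control entities and B = 20 control (42 slides), the index is
bounded by the number of (same-dataset, different-class) neighbor
incidences, which only the two misaligned slides can generate — an
adversarial ceiling of ≈ 0.14 at k = 10, with dataset-clustered features
realistically giving ≈ 0.04–0.10. The informative quantities on such a pair
are the sign of the index and the dataset purity itself (≈ 1.0 when the
shortcut is encoded), not its magnitude.

## The synthetic scenario

`make_multicenter_scenario("confounded_trio")` builds four cohorts at
1024×1024 (16 grid tiles per slide): A — 20 tumor patients, 2 of which also
contribute a control slide (dual-class entities, as tumor resections with
adjacent normal tissue produce); B — 20 control-only patients; C — 12 + 12
balanced, with country labels cycling over 12 values for the grouped
protocol; T — 5 + 5 held out, disjoint patient namespace. In A+B, ~95% of
slides satisfy (dataset == A) == (class == tumor): origin predicts class.

Each slide is a bright N(242, 4) background (clean bimodal histogram for
Otsu) with a contiguous superellipse tissue region (default 85% of the
slide) in eosin-pink with low-frequency mottle, carrying dark
hematoxylin-purple elliptical spots: control 6 spots per 10⁴ px² of radius
3, tumor double density and 1.5× radius — the simplest texture contrast a
small CNN can learn quickly while staying invisible to a histogram of the
background. Tumor slides keep a contiguous 20% band of control texture
(tumor purity 0.8), emulating intratumoral normal tissue; the figure is a
free parameter with no published value, chosen once as a plausible default.
Dataset stain casts are affine maps (multiplicative then additive) applied
to tissue pixels only and clipped — staining variation rather than scanner
vignetting. A and B carry strong opposing casts (multiplicative components
~±25%, additive ~±20 gray levels); the magnitudes are chosen so the source
remains identifiable even after per-tile Reinhard moment matching, because
real inter-site variation is not an affine color map and survives
normalization — with mild casts, normalization removes the shortcut
entirely and the confounded pair no longer emulates the study conditions.
C and T have mild distinct casts. Setting `identity_casts=True` switches
the color route off entirely while leaving the texture signal untouched.

What the generator does *not* emulate: nuclei morphology and chromatin,
stain deconvolution structure (hematoxylin/eosin channels as such),
compression artifacts, pen marks, tissue folds, magnification pyramids, and
site-specific texture differences. Passing tests therefore show that the
pipeline's logic (preprocessing, weak supervision, aggregation, leakage
protection, confounding diagnosis) behaves correctly under known structure
— not that the classifier would reach any particular accuracy on real
slides.

## Numerical and design choices

- Determinism: every stochastic step (generation, subsampling, bagging,
  flips, init, UMAP) derives from explicit seeds; identical seeds give
  bit-identical cohorts and training histories. Per-object RNGs are derived
  via CRC32 of stable string ids so results do not depend on call order.
- Otsu ties take the smallest maximizing cut; the threshold convention is
  "tissue = gray < cut", one level above the convention that reports the
  last low-class bin (the tests pin both against brute force and an
  independent library implementation).
- Early stopping requires strict improvement; the best epoch's parameters
  are restored. The validation bag draw is fixed per slide across epochs so
  the metric is comparable between epochs.
- Zero-variance tiles in normalization pass through with a warning rather
  than raising: the contrast filter should have removed them, and a single
  blank tile must not abort a training epoch.
- Degenerate inputs: constant images raise a histogram error naming the
  slide; slides smaller than the tile size yield an empty flagged store;
  empty stores are excluded from training with a warning but raise on
  explicit prediction.
- Experiment schedule: the scaled-down experiments (tests, acceptance
  script, examples) run the default model with `max_epochs` 25 and patience
  8 (the texture signal saturates validation accuracy within a few epochs,
  and the permuted-label control must not wander for tens of epochs);
  cohort sizes are the scenario preset at scale 1. The full-scale defaults
  (100 epochs, patience 20) remain the `ModelConfig` defaults.

## Known limitations

- The confounding index saturates at a small positive value on heavily
  confounded pairs (see above); compare its sign and the dataset purity,
  and prefer balanced evaluation sets when quantifying magnitude.
- Reinhard transfer assumes a unimodal color distribution per tile; tiles
  mixing background and tissue get a compromise correction (this residual
  is precisely what lets a strong source cast survive normalization, in the
  synthetic scenario as in practice).
- The numpy training loop is single-threaded BLAS-bound; it is sized for
  tens of slides at 1024², not thousands at full WSI scale.
- Pyramidal slide formats are out of scope; inputs are single-resolution
  raster images already at working magnification (the resample hook is a
  no-op by default).
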