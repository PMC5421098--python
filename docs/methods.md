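# Methods

`histocode` builds a surrogate biomarker from H&E histopathology images: a
classifier that predicts a dichotomised genomic label ("BRAF-positive",
i.e. V600E mutants plus BRAF-mutant-like tumours as defined by a 64-gene
signature score) from tissue texture alone. This note records the model,
its parameters, the numerical choices, what the synthetic data generator
does and does not emulate, and the known limitations.

## Image model and stain separation

Transmitted light through a stained section follows the Beer–Lambert law:
per-pixel optical density `OD = -log10(I / I0)` is approximately a
non-negative linear mixture of the optical-density colour vectors of the
dyes. With the stain matrix `M` (rows: unit OD vectors of haematoxylin,
eosin and a residual completed as their unit cross product), concentrations
are recovered per pixel by solving `od = c · M` and clipping negatives to
zero. The haematoxylin and eosin concentration channels (the H- and
E-images) are the sole input to texture analysis.

Choices:

* Stain vectors: the Ruifrok–Johnston H&E values
  (H = (0.650, 0.704, 0.286), E = (0.072, 0.990, 0.105)), row-normalised;
  configurable. These are the de-facto standard for colour deconvolution
  of H&E.
* `I0 = 255`, base-10 logarithm, input floored at 1 grey level so fully
  absorbed pixels stay finite.
* All analysis runs at an equivalent 5x magnification; 20x input is
  block-averaged by a factor of 4 first (partial edge blocks average the
  pixels they contain). Deconvolution happens after downscaling — the
  order is not identifiable from the reference analysis and downscaling
  first is cheaper; the two orders differ only through the non-linearity
  of the log, which is marginal at 8-bit depth.
* Background: pixels where a supplied tumour mask is zero; without a mask,
  near-white pixels (all channels ≥ 240).

## Texture descriptors

Local texture is described with a fixed bank of real Gabor kernels

    G(x, y; ν, θ, σ) = exp(-(x² + y²) / 2σ²) · cos(2πν (x cosθ + y sinθ))

crossing σ ∈ {1, 2√2} pixels, θ ∈ {0, π/4, π/2, 3π/4} and
ν ∈ {3/4, 3/8, 3/16} cycles/pixel — 24 filters. Kernel support is the
smallest odd integer ≥ 6σ + 1 (three standard deviations each way). The
kernels are used verbatim: no DC correction and no L2 normalisation.

Each non-overlapping 32×32-pixel patch (grid anchored at pixel (0,0),
row-major, 0-based) is described by the mean and the population variance
of every filter response over the patch, H channel first:
`[24 H means | 24 H variances | 24 E means | 24 E variances]` — 96 values.
Responses are computed image-wide by correlation with mirror-reflected
borders. Implementation detail: the kernel factorises as
`cos(ax + by) = cos(ax)cos(by) − sin(ax)sin(by)` under a separable
Gaussian envelope, so each response costs at most four 1-D correlations;
the result is identical to full 2-D correlation to ~1e-10.

A patch is excluded whenever *more than* 50% of its pixels are background
(exactly half is still used). Responses are evaluated in float32 with
float64 accumulation of the patch moments.

## Two-level codebook coding

**L1.** Up to 1000 valid patch descriptors are sampled uniformly without
replacement from each training image, pooled, z-scored per dimension
(mean/variance entries live on very different scales; degenerate
dimensions get unit scale), and clustered by k-means into K1 = 128
codewords (k-means++ initialisation, best of 5 restarts, ≤ 300 iterations,
tolerance 1e-4). Every valid patch of every image is then recoded as the
1-based index of its nearest codeword (squared Euclidean distance, ties to
the lowest index); excluded patches carry the sentinel 0.

**L2.** A 15×15-patch window (480×480 px) is described by the relative
frequencies of the L1 codes among its valid member patches (normalised to
sum 1); a window with more than half invalid members is itself invalid.
Up to 500 window descriptors per training image are sampled at uniformly
random valid positions (stride 1), pooled *within class*, and clustered
into two class-specific codebooks of K2 = 128 codewords each (same
k-means protocol; no standardisation — frequencies are already
commensurate). The final image representation tiles the patch grid with
non-overlapping 15×15 windows anchored at (0,0) and histograms the
nearest-codeword assignments over the concatenated 2·K2 codeword set
(positive-class block first), normalised to relative frequencies so that
image size does not confound content.

## Classifier

On the 2·K2-bin histograms: (1) features are ordered by recursive feature
elimination — repeatedly fit a linear-kernel SVM (C = 1, inverse-frequency
class weights) and drop the 5 features with the smallest absolute weight;
the reversed elimination order is the ranking. (2) For each subset size
f ∈ {30, 50, …, 130} an RBF-kernel SVM is tuned over
C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵} × γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³} by 5-fold stratified
inner cross-validation maximising the mean AUC of decision values (ties:
smallest C, then smallest γ). (3) The f with the best inner AUC (ties:
smallest f) is kept and the final SVM trained on it. Class imbalance
(~20% positives) is met with inverse-frequency class weights in every fit.
The default operating point is decision value 0; a sample is called
positive iff its margin is strictly above the threshold.

For unbiased evaluation the *entire* recoding (L1 codebook, standardiser,
both L2 codebooks) plus steps (1)–(3) is refitted inside each training
fold of a 10-fold stratified outer cross-validation; held-out images are
encoded with their training fold's codebooks only. Randomness derives from
one cohort-level seed: per-image sampling substreams are keyed by the
image identifier and per-fold substreams by the fold index, so the fit of
a fold is a pure function of its training images — removing a held-out
image cannot perturb it (tested).

Two summaries of the out-of-fold margins are computed. The pooled AUC
treats all margins as one score set, mirroring the reference analysis; it
is the right summary when fold models are similar enough for their
decision values to share a scale (large cohorts, rich histograms). The
fold-averaged AUC (`pipeline.fold_average_auc`) computes each fold's AUC
separately and averages; it depends only on within-fold ranking and is the
estimator used for desk-scale synthetic evaluation, where margins of
different folds are decision values of very different SVM fits. Observed
concretely: on desk-scale cohorts every fold separates perfectly
(per-fold AUC 1.0) while the pooled value can drop to ~0.8 purely through
cross-fold scale mismatch.

A related small-cohort artefact affects the default operating point
(margin > 0): when the inner-CV AUC saturates at 1.0 over many grid
points, the deterministic tie-break (smallest C, then smallest γ) selects
an extreme, underfitted corner of the lattice whose decision values sit
almost entirely on one side of zero. Ranking is unaffected; hard labels
at the default threshold are not trustworthy on easily separable small
cohorts. On realistically noisy data the inner AUC does not saturate and
the argmax is interior.

## Evaluation statistics

* Sensitivity, specificity, accuracy from the out-of-fold confusion
  matrix; undefined ratios are reported as NaN, never silently 0.
* Binomial 95% intervals by the Agresti–Coull adjusted-Wald closed form
  (ñ = n + z², p̃ = (x + z²/2)/ñ, half-width z·sqrt(p̃(1−p̃)/ñ)), clipped
  to [0, 1].
* AUC as the Mann–Whitney statistic (ties half); scores are margins,
  never flipped — an AUC below 0.5 is reported as-is.
* AUC interval by stratified percentile bootstrap, 2000 replicates
  resampled within class.
* Association with categorical covariates: Pearson χ² with Yates
  continuity correction on 2×2 tables (the convention of the R
  environment used for the reference analysis).
* Feature polarity: the sign of the slope of a univariable logistic
  regression of the label on one histogram feature. Perfectly separable
  features keep their determinate sign via a ridge-stabilised refit;
  constant features or |slope| < 1e-10 are "undetermined".
* No multiple-testing adjustment anywhere.
* Spatial feature maps mark each valid non-overlapping window whose
  assigned codeword is a selected feature of positive (resp. negative)
  polarity; invalid (background/low-contrast) windows appear in neither
  map.

## Synthetic cohorts

Real slides cannot be redistributed, so the generator emits labelled
pseudo-H&E mosaics with controllable two-scale structure:

* Eight texture motifs (oriented gratings, band-pass noise, Gaussian blob
  fields) with orientations and frequencies on the Gabor bank's grid and
  distinct H/E stain loadings. Each 480-px tile — exactly one L2 window
  footprint — carries one motif, so within-tile texture drives L1 coding
  and between-tile composition drives L2 coding.
* Class mixtures over motifs interpolate with a `divergence` knob:
  `(1−d)·uniform + d·class-specific`, identical at d = 0, disjoint
  supports at d = 1.
* Stain fields go through the exact forward of the deconvolution model
  (Beer–Lambert with the same stain matrix), quantised to 8 bits, plus
  Gaussian pixel noise (default sd 2 grey levels).
* Labels are Bernoulli at the reference prevalence 20.3%; a white frame
  (default 48 px) surrounds the tile mosaic and is masked as background.
* Every image derives from the cohort seed through fixed substreams;
  the manifest (per-image label, motif layout, SHA-256) reconstructs the
  cohort exactly.

Desk-scale defaults: 60 images of 960×720 px (a 2×2 tile mosaic, two
non-overlapping L2 windows per image), K1 = K2 = 16, subset grid
{8, 16, 24, 32}, 3-fold outer CV, and a step-4-exponent hyperparameter
lattice. These sizes were chosen as the largest configuration a single
CPU handles comfortably while preserving both coding scales; the
reference configuration remains the package default (`PipelineConfig()`).

What the generator does **not** emulate: nuclear morphology, mucin,
scanner/compression artefacts, pen markings, stain variability between
labs, or spatial correlation between neighbouring tiles. Passing tests
therefore demonstrate that the pipeline recovers planted two-scale
texture signal and is leak-free and well-calibrated under its own model —
not that the biological association is reproducible on real slides.

Parameter guidance observed on synthetic data: K1 must be at least the
number of distinct texture populations; with K1 below the motif count the
classes alias onto shared codewords and class signal at L2 collapses.

## Degenerate inputs and tie-breaks

* All nearest-centroid assignments break ties toward the lowest index;
  `argmin` order makes encoding deterministic.
* k-means requires at least k distinct points (checked); degenerate
  standardisation dimensions get sd = 1.
* An image with no valid patch is skipped from codebook sampling with a
  warning; an image with no valid L2 window raises an explicit
  "unusable image" error rather than emitting an empty histogram.
* Margin exactly at the threshold is classified negative (strict >).
* Inner CV folds that lack a class are skipped; if all folds lack one,
  tuning fails loudly.

## Limitations

* NDPI decoding, slide scanning and tumour-region annotation are out of
  scope; input is pre-exported TIFF with an optional mask.
* The pooled out-of-fold margin scale caveat above.
* Survival analysis of the reference study is out of scope (requires
  clinical follow-up data).
* With very small cohorts (≲ 20 images, ≲ 4 positives) the inner
  cross-validation cannot estimate hyperparameters meaningfully; the
  coding levels still separate classes but the tuned classifier may
  degenerate. The desk-scale cohort (60 images) is the intended minimum
  for end-to-end runs.
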