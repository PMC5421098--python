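# histocode

Texture-based surrogate genomic biomarkers from H&E histopathology images.

Molecular classifiers such as the 64-gene "BRAF-positive" signature for
colorectal cancer (V600E *BRAF* mutants plus BRAF-mutant-like wild types)
require gene-expression profiling that is often too slow, costly or
tissue-hungry for routine use. `histocode` implements an image-only
surrogate: from a routine H&E slide export it predicts the dichotomised
signature label, so the model can act as a cheap pre-screen before
molecular testing. It is aimed at computational-pathology researchers who
want a transparent, fully reproducible bag-of-visual-words baseline —
every stage is inspectable text (codebooks, rankings, SVM state) rather
than an opaque learned representation.

## Method

1. **Stain separation.** RGB → optical density (`OD = -log10(I/I0)`) →
   colour deconvolution with the Ruifrok–Johnston H&E matrix → per-stain
   intensity channels (H- and E-images), at an equivalent 5x
   magnification, with non-tumour pixels masked.
2. **Gabor descriptors.** A fixed bank of 24 real Gabor kernels
   `G(x,y; ν,θ,σ) = exp(-(x²+y²)/2σ²)·cos(2πν(x cosθ + y sinθ))`
   (σ ∈ {1, 2√2}, θ ∈ {0, π/4, π/2, 3π/4}, ν ∈ {3/4, 3/8, 3/16});
   each 32×32-px patch ⇒ 96 values (mean and variance of every response,
   H‖E). Patches with >50% background are excluded.
3. **Two-level coding.** L1: k-means codebook (K₁ = 128) over z-scored
   patch descriptors (1000 sampled per training image); every patch gets
   its nearest codeword index. L2: each 15×15-patch window (480×480 px)
   becomes the frequency vector of its L1 codes; two *class-specific*
   codebooks (K₂ = 128 each, 500 windows sampled per training image) are
   fitted, and an image is finally a 2K₂-bin histogram of nearest-codeword
   assignments over the non-overlapping window tiling.
4. **Classifier.** SVM-RFE feature ranking (linear kernel), per-subset-size
   RBF-SVM tuning (inner 5-fold stratified CV maximising AUC over a
   C × γ grid), best subset size by inner AUC, final RBF SVM with
   inverse-frequency class weights. Evaluation embeds *all* of the above
   (codebooks included) in a 10-fold stratified outer cross-validation, so
   held-out images are never seen by any fitted component.
5. **Statistics.** Confusion metrics with Agresti–Coull 95% intervals,
   AUC (Mann–Whitney) with stratified bootstrap interval, Yates-corrected
   χ² for 2×2 associations, univariable-logistic feature polarity, and
   spatial maps of where selected positive/negative codewords fire.

Because the clinical trial slides behind the original analysis are not
public, the package ships a synthetic cohort generator
(`histocode.synthetic`) producing pseudo-H&E mosaics of stain-loaded
texture motifs with a tunable class `divergence`, on which the entire
pipeline is exercised end-to-end. See `docs/methods.md` for the full
model description and design rationale.

## Worked example

Generate a 60-image synthetic cohort with disjoint class motifs and run
the desk-scale cross-validation (K₁ = K₂ = 16, 3 outer folds):

```python
from histocode.metrics import binary_metrics, confusion
from histocode.pipeline import fold_average_auc, outer_cv
from histocode.presets import desk_scale_config, desk_scale_spec
from histocode.synthetic import cohort_features, generate_cohort

cohort = generate_cohort(desk_scale_spec(seed=1, divergence=1.0))
feats = cohort_features(cohort)
cfg = desk_scale_config(seed=1)
report = outer_cv(feats, cohort.labels, config=cfg, k=cfg.outer_folds)

print("AUC (fold-averaged)", round(fold_average_auc(report.predictions), 3))
se, sp, acc = binary_metrics(confusion(report.predicted_labels, report.true_labels))
print("Se", round(se, 3), "Sp", round(sp, 3), "Acc", round(acc, 3))
```

```
AUC (fold-averaged) 1.0
Se 1.0 Sp 0.347 Acc 0.467
```

The fold-averaged AUC of 1.0 says every fold's out-of-fold margins rank
all held-out positives above all held-out negatives — the planted texture
signal is fully recovered. The default operating point (margin > 0) is
nevertheless poorly calibrated here: with an easily separable synthetic
cohort the inner-CV AUC saturates at 1.0 across many (C, γ) grid points
and the deterministic tie-break (smallest C, then smallest γ) picks an
extreme, underfitted corner whose decision values are mostly positive.
This is a small-cohort artefact discussed in `docs/methods.md`; margins,
not hard labels, are the quantity to trust at this scale. The same run
through the command line:

```bash
python -c "from histocode.presets import desk_scale_config; desk_scale_config(seed=1).to_yaml('config.yaml')"
histocode synth --n 60 --divergence 1.0 --seed 1 --out run/images
histocode cv --cohort run/images --k 3 --config config.yaml --out run/cv
histocode eval --predictions run/cv/predictions.csv --out run/report.json
```

`run/cv/` then holds the per-image out-of-fold margins
(`predictions.csv`), a `summary.json` with AUC/Se/Sp/Acc and their 95%
intervals, and the full-data model bundle (codebooks, ranking, SVM state
— all JSON/CSV text) for `histocode predict` and `histocode maps`.

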