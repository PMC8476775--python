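# Methods

## Problem

Immunohistochemistry (IHC) of human testis stains a protein's expression
brown (DAB) over a blue (hematoxylin) counterstain.  A trained observer
annotates, per image, which of eight testicular cell types express the
protein — five germ-cell stages arranged as concentric layers of the
seminiferous tubule (spermatogonia, preleptotene spermatocytes, pachytene
spermatocytes, round/early spermatids, elongated/late spermatids) and three
somatic types (Sertoli, Leydig, peritubular) — together with a staining
intensity (0-3) and subcellular locations.  Automating this is a multilabel
image classification problem, and because automated calls feed curated
protein atlases, every prediction needs a usable confidence estimate: the
point of this package is not only the classifier but the machinery that
decides *which* predictions can be auto-accepted and which must go back to
a human.

## Model

The classifier is a hybrid network.  A convolutional trunk ends in global
average pooling and a learned projection to a `cnn_feature_dim`-long vector
(default 256).  In parallel, three classical descriptor families are
extracted from the luminance image — HOG (8 unsigned orientation bins,
8x8-px cells, 8x8-cell blocks, L2 block norm), the 13 Haralick co-occurrence
statistics averaged over four directions, and the 7 Hu moment invariants on
a signed log scale — z-scored per feature and reduced by PCA (default
3732 components at full scale, clamped to min(n-1, d) on small runs).  The
hybrid vector (CNN features first, handcrafted second) feeds fully
connected layers ending in one sigmoid per cell type; training minimizes
mean per-label binary cross-entropy without class weighting.

Bayesian behavior comes from drop-weights: every fully connected weight
matrix is multiplied elementwise by a Bernoulli(1-rate) mask rescaled by
1/(1-rate) (rate 0.3 by default), resampled per training batch *and per
inference pass*.  Keeping the masks active at test time makes T stochastic
forward passes a Monte-Carlo approximation of the posterior predictive
distribution over head weights.  Only the head is stochastic, so the trunk
and the handcrafted block are evaluated once per image and the T passes
re-run the head only.

## Uncertainty and the DHC score

For one label with MC samples p_1..p_T:

- predictive mean `mu = mean(p_t)` — the point prediction;
- plug-in entropy `H(mu)` in bits, so it lives in [0, 1] for a binary
  label;
- jackknife bias-corrected entropy
  `H_J = T*H(mu) - (T-1)*mean_i H(mu_{-i})` over leave-one-out means —
  the plug-in estimator is downward-biased at finite T and the jackknife
  removes the O(1/T) bias term;
- plug-in mutual information `H(mu) - mean_t H(p_t)` and its jackknife
  bias-corrected form `MI_J = H_J - mean_t H(p_t)` (the per-sample entropy
  term is a plain average, hence unbiased, so the jackknife correction
  passes through it and acts on the plug-in term alone);
- CPPD `|2 mu - 1|`: the gap between the probabilities of the label's two
  outcomes (its best and next-best "classes" under the sigmoid head);
- DHC `= CPPD / max(MI_J, 1e-10)`, capped at 1e6 to keep tables finite.

The denominator is deliberately the *mutual information* — the
disagreement between stochastic passes, i.e. the epistemic component —
rather than the predictive entropy `H(mu)`.  The two differ in a way that
matters: `H(mu)` depends only on the predictive mean, so a score divided
by it would be a deterministic function of `mu` and entirely blind to how
much the MC passes disagree; `MI_J` grows with sample dispersion at a
fixed mean, which is exactly the behavior a confidence score built on MC
drop-weights needs (and the behavior the monotonicity tests pin down).

DHC near 0 means the uncertainty dwarfs the class-probability margin
(route to manual review); DHC >> 1 means the margin dwarfs the
uncertainty (auto-accept).  Raw scores are min-max normalized per label
over the scored batch for reporting; an all-equal batch maps to 1.

Numerical conventions: entropies use log2 and the non-negative Shannon
sign convention; H_J and MI_J may legitimately undershoot zero near
degenerate means (jackknife overshoot / estimator noise), hence the
epsilon floor, whose magnitude matches the smallest published
per-cell-type cutoffs (1e-10).  A CPPD variant across the eight labels
(gap between the two largest per-label means) is available via
`cppd_mode="across_labels"`, but the per-label reading is the default:
under independent sigmoid outputs each label is its own two-outcome
problem.

## Thresholds, metrics and triage

Per-label probability thresholds are chosen by grid search (0.01..0.99,
step 0.01) maximizing the Matthews correlation coefficient on the
validation split, which tolerates the strong class imbalance (Leydig ~66%
positive, peritubular ~10%).  Ties take the lowest threshold.  Performance
is reported as Hamming loss, macro/micro F1, Exact Match ratio and mean
Average Precision (all-point AP, ties broken by stable original order),
plus per-label confusion counts, accuracy and MCC.  ROC/AUC aggregation is
deliberately not offered for the multilabel prediction as a whole.

Triage ranks predictions per label by DHC.  Cutoffs are either a named
preset (`hpa_testis_v1`, the published per-cell-type values, applied on
the normalized 0-1 scale) or selected on validation data as the smallest
cutoff whose retained accuracy reaches a target (default 0.95) while
keeping at least a minimum retained fraction (default 0.5); when the
target is unattainable the accuracy-maximizing admissible cutoff is used
with a warning.  Learned cutoffs are selected and applied on the *raw*
DHC scale: within one batch raw and min-max-normalized scores are
affinely equivalent (identical retained sets), but min-max constants are
batch-relative, so only raw cutoffs transfer correctly from the
validation batch to a later test batch.  Selection is performed on the
validation split — setting it on test data would leak information.  The
accuracy/discard curve evaluates retained accuracy at every observed
score so the trade-off is explicit.

## Cross-validation

`multilabel_stratified_split` implements iterative stratification
(assign examples of the currently rarest label first, to the fold that
most needs that label; ties go to the fold with the largest remaining
overall desire), followed by two deterministic refinement passes: a size
rebalance so fold sizes differ by at most one, and a greedy
size-preserving swap pass that minimizes the summed squared deviation of
per-fold label counts from their proportional targets.  The swap pass
matters: pure greedy stratification balances the label it is currently
processing but lets the most frequent label drift by several points,
while after refinement the worst per-fold prevalence gap on a
1000-image/8-label plan is under one point.  Repetitions use fresh
randomization.  When a
group column is given (antibody id), whole groups are assigned to folds so
replicate images of one antibody never straddle a fold boundary; grouping
is the default because replicate crops are near-duplicates and splitting
them inflates scores.

## Synthetic data

The image generator is first-class, tested code: it emulates the geometry
the annotation task depends on, not histological appearance.  Each image
(default 64 px) contains 1-2 non-overlapping circular tubule
cross-sections; from the rim inward: a thin peritubular ring, then five
concentric germ-cell layers, a lumen; Sertoli cells are radial intratubular
wisps, Leydig cells interstitial blobs.  Tubule radii are drawn so every
germ layer is at least ~2.5 px wide at the working resolution — a
compartment thinner than the receptive grain of any detector would make
the task unlearnable by construction, which would defeat the generator's
purpose.  Labels come from a Gaussian copula with three co-expression
clusters (somatic; premeiotic; meiotic/postmeiotic) reproducing the
requested marginal prevalences (defaults span 0.10 for peritubular to 0.66
for Leydig, mirroring the real corpus) with positive within-cluster
correlation (rho = 0.5).  Positive compartments are painted DAB-brown
mixed over hematoxylin-blue with strength 0.35/0.65/1.0 for weak/moderate/
strong intensity — weak staining is deliberately faint, because faint
staining is what makes real annotation hard — plus Gaussian pixel noise
(sd 12).  Intensity grades given positivity are drawn 0.25/0.40/0.35.

A color oracle (mean R-B channel difference inside the ground-truth
compartment mask, threshold -35) recovers the generated labels with >=99%
accuracy, guaranteeing the task is learnable in principle.  What the
generator does **not** emulate: nuclear texture, cell morphology,
staining artifacts, subcellular patterns, inter-laboratory variation.
Passing tests on synthetic data therefore demonstrate that the pipeline's
statistics behave as designed, not that the classifier reaches any
particular accuracy on real tissue.

`generate_mc_samples` fabricates MC prediction sets directly: per item the
Beta mean is pulled toward the true label by (1 - difficulty) and the
concentration interpolates log-linearly between 150 (easy) and 2 (hard),
so difficulty jointly degrades separation and tightness — a controlled
stand-in for network output when testing uncertainty and triage machinery
in isolation.

## Training profiles and numerical choices

Two profiles ship.  `paper_scale` is the published recipe: VGG19-like
trunk, 1024-px bicubic-resized input, he-uniform init, Adam with the
maximum-of-past-variance (AMSGrad) correction, base learning rate 1e-6,
minibatch 32, 250 epochs, weight decay 0.2, drop rate 0.3, T = 1000 MC
samples.  It requires the real image corpus and days of compute.  `desk`
is the out-of-box profile this package is tested under: 64-px images, a
3-block trunk (16/32/64 channels), 256-d CNN feature, two 256-wide head
layers, learning rate 1e-3, 50 epochs, weight decay 1e-3, handcrafted
features on the DAB color-deconvolution channel reduced to 128 PCA
components, random dihedral augmentation of training batches (tissue
orientation carries no information), T = 100.  The desk values are sized
to the small network and image count; the weight-decay reading ("L2
penalty" vs "learning-rate decay") is ambiguous in common usage, so both
are implemented (`weight_decay_mode`), L2 by default.

The DAB channel matters at desk scale: at 64 px the brown stain and blue
counterstain differ by only ~8 luminance units against pixel noise of
sd 12, so luminance-based texture descriptors carry almost no staining
signal, whereas descriptors on the deconvolved DAB channel localize the
staining directly (ring vs blob vs wisp geometry is exactly what Haralick
and HOG statistics see).  At full scale, where texture is resolved, the
module default remains luminance and the channel is a configuration
switch (`handcrafted_channel`).

Other numerical choices: images are normalized to [-0.5, 0.5] before the
trunk; validation accuracy for checkpointing is mean per-label accuracy at
threshold 0.5 under the expectation (mask-free) forward pass; the best
checkpoint over epochs is returned.  Training aborts with a diagnostic on
a non-finite loss.  One master seed drives initialization, shuffling, mask
sampling and augmentation; runs are bit-reproducible on a fixed BLAS
configuration.  Degenerate inputs have defined conventions: Haralick
correlation is 0 at zero gray-level variance, Hu moments of an all-zero
image are the zero vector, per-label F1 with an empty union is 0, MCC with
a zero denominator factor is 0, Kendall correlation against a constant
intensity column is 0 with a warning.

## Scaled-down study conditions

The acceptance study runs the full pipeline on 600 synthetic 64-px images
(400 train / 100 validation / 100 test) with the desk profile and T = 100
— sizes chosen so the entire study, including training the trunk from
scratch, completes in minutes on one CPU while still exercising class
imbalance, correlated labels and the accuracy/discard mechanism.  At this
scale the headline numbers of a full-scale run (e.g. exact-match ratios
near 67% on thousands of real images) are not expected; what the study
reproduces is the mechanism: the trained classifier beats the prevalence
baseline by a wide margin, and DHC-thresholded retained accuracy exceeds
the unthresholded accuracy at a bounded discard fraction.

## Known limitations

- The numpy trunk is CPU-bound; the `vgg19_like` backbone is provided for
  completeness and constructs correctly, but training it at 1024 px is not
  practical without an accelerator.
- Handcrafted features are computed on the luminance image; a DAB
  color-deconvolution channel hook exists in configuration but is off by
  default.
- No calibration post-processing (temperature scaling) and no
  aleatoric/heteroscedastic decomposition; the uncertainty reported is the
  epistemic component accessible to MC drop-weights.
- Min-max DHC normalization is batch-relative: scores are comparable
  within a scored set, not across sets; the raw score is always
  co-reported.
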