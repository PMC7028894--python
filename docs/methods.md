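# Methods

This note documents the models, algorithms and design choices behind
`thermostage`: what each stage computes, which parameters matter, what the
synthetic data does and does not emulate, and the package's known limits.

## Problem setting

Input is a false-colour infrared thermogram of the posterior thighs
(nominally 320×240, 8-bit RGB) decorated by the camera software with a
vertical temperature-scale bar and text overlays, plus a severity label on
the four-level Nürnberger–Müller scale. The approach is purely
morphological: pixels are treated as intensities, never mapped back to
temperatures, so no radiometric calibration is needed and ordinary PNG
exports suffice. The thermographic signature of advancing cellulite is
increasing spatial inhomogeneity ("orange peel") of the warm thigh
regions; the pipeline turns that into a texture-classification problem.

## ROI extraction

The chain, in order: grayscale conversion → annotation removal → contrast
stretch → Sobel edges → threshold → noise removal → crop → resize.

* **Grayscale** uses Rec. 601 luminance weights (0.299, 0.587, 0.114).
  Rainbow palettes are not luminance-monotone in pseudo-temperature, but
  the downstream analysis only needs contrast, not monotonicity, and
  luminance is the standard, palette-agnostic reduction.
* **Annotation removal.** The scale bar is a tall thin strip of dense
  edges abutting the left or right border; text overlays form dense strips
  along the top and bottom. Mean Sobel edge density is profiled per border
  row/column and compared against 3× the profile median (falling back to
  the mean when the median vanishes). A strip must announce itself within
  the outermost 12 px — otherwise interior structure (a thigh outline
  entering the margin) could trigger a cut — and at most
  `annotation_margin_fraction` (default 0.2) of each dimension may be
  excised per border; the cut runs 3 px past the deepest above-threshold
  line to clear edge blur. If nothing qualifies the image passes through
  unchanged, which is the correct behaviour for pre-cropped inputs.
* **Contrast** is a linear percentile stretch, defaults (2, 98), with a
  constant-image guard. The low clip suppresses background noise; the high
  clip keeps isolated hot pixels from compressing the thigh range.
* **Edges** are the 3×3 Sobel gradient magnitude √(Gx²+Gy²) with reflected
  borders. The binarisation threshold is Otsu's method on the magnitude
  image by default (the edge histogram is strongly bimodal:
  outline vs. noise); a fixed relative threshold is available in
  `PreprocessConfig` for pathological inputs.
* **Noise removal** drops 8-connected components below
  `min_component_area` (default 64 px — well below a thigh outline,
  well above speckle) and then closes with a 3×3 square, fusing
  single-pixel gaps so each thigh outline becomes one component.
* **Crop** takes the union bounding box of the surviving components with
  area ≥ 20% of the largest, which retains both thighs whether they
  survive as two components or one merged one, while ignoring residue. A
  box under 16 px a side is treated as a failed extraction. The crop is
  resized to 210×240 with bilinear interpolation (anti-aliased when
  downscaling) and min-max rescaled to [0, 1].

## Feature extraction

* **HOG** (reference): 48×48-px cells, 9 unsigned orientation bins over
  [0°, 180°), 2×2-cell blocks at 1-cell stride, L2 block normalisation
  with an ε-guard (a constant image maps to the zero vector). On 210×240
  that yields 4×5 cells → 3×4 blocks → 432 features; the dimensionality
  formula D = (⌊H/c⌋−b+1)(⌊W/c⌋−b+1)·b²·bins is exposed on `HOGConfig` and
  property-tested against brute-force block counting. The 48-px cell is
  large relative to the mottling scale, so the descriptor reads the
  coarse gradient texture of the thigh surface rather than individual
  blobs. Computation is delegated to scikit-image.
* **Stat**: mean, variance, skewness, excess kurtosis (both 0 for
  zero-variance images), median, 10th/90th percentiles, entropy of the
  64-bin histogram — a fixed, documented resolution of "first-order
  statistics", so vectors are comparable across runs.
* **Cont**: Otsu-binarise, largest component; perimeter, area,
  area/perimeter², eccentricity, solidity. The perimeter is the length of
  the marching-squares boundary polygon simplified by Douglas–Peucker at
  1-px tolerance; unlike pixel-chain counts this removes the staircase
  bias, landing within ~1% of the true perimeter for both discs and
  axis-aligned rectangles (verified in tests).
* **LBP**: uniform rotation-invariant local binary patterns, P=8, R=1,
  normalised 10-bin histogram. Images are quantised to 256 grey levels
  first and the 1-px border excluded (border codes would mix in
  out-of-image neighbours).
* **PCA**: images flattened to 50,400-vectors, mean-centred; features are
  the top-k projection coefficients, default k = 40 (capped at n−1): with
  ~150 training images the spectrum beyond a few dozen components is
  noise.
* **EucDist**: Euclidean distances to per-stage mean-image templates; a
  stage absent from training receives a large finite sentinel so it can
  never be the nearest template.

PCA and EucDist require fitting and accept only the training partition;
the split helper in `thermostage.pipeline` enforces that, so no test image
can leak into any fitted extractor state.

## Classification

One binary scorer per stage on z-scaled features (scaling parameters from
the training set only; constant dimensions keep unit scale). Prediction is
the argmax of the four probability scores with ties to the lowest stage —
a deliberate, documented bias toward under-staging on complete ties. A
stage with zero positive training examples is flagged untrainable and
masked out of the argmax.

The reference scorer is a three-layer perceptron written out in numpy:
input → sigmoid hidden layer (default 20 units) → single sigmoid output;
weights initialised uniform in [−0.5, 0.5] from the seed; full-batch
gradient descent on binary cross-entropy, 500 epochs at fixed rate 0.05;
the per-epoch loss history is kept on the fitted object and training
aborts with a diagnostic if the loss goes non-finite. With 432 HOG inputs
the network has ≈8.7k parameters — deliberately small next to ~150
training images; the descent property (non-increasing loss at small
rates) and perfect separation of well-separated blobs are tested.

The eight classical families are backed by scikit-learn with fixed,
documented defaults (KNN k=5; SVM RBF, C=1, γ=1/d, Platt-calibrated
probabilities fitted on the training data via internal cross-validation;
RF 100 trees; DT Gini; LDA/LogReg/GaussianNB native posteriors), except
MinDist, which is a two-centroid scorer with a softmin over distances so
that equidistant points score exactly 0.5. No hyper-parameter search is
performed anywhere: defaults are fixed and recorded in the run record.

Class imbalance: the binary fits are unweighted by default. Inverse-
prevalence weighting (`class_weight="balanced"`) is available, but as a
default it interacts badly with argmax fusion — under uninformative
features every weighted scorer converges to ≈0.5 and the fused prediction
degenerates to a uniform draw, whereas unweighted scorers fall back on the
class prior, the behaviour the evaluation's null checks assume. The
stratified split plus one-vs-rest decomposition is itself the primary
response to imbalance.

## Evaluation

The 70/30 split is stratified per stage: n_train = round-half-up(0.7·n),
assignment by a seeded within-stage permutation (reproducible; the seed is
part of the run record), and a stage that would be swallowed whole by
training donates one image back to test. For class counts 27/93/61/31
this gives 19/65/43/22 train and 8/28/18/9 test (149/63). The balanced
option first subsamples every stage to the minimum per-stage count,
mirroring a balanced-database control experiment.

Per-stage metrics come from the one-vs-rest confusion table of the fused
predictions; "class accuracy" is the binary accuracy (tp+tn)/N of that
table, and the report's Average row is the unweighted mean over stages.
ROC curves sweep thresholds at every distinct score with
predict-positive-at-or-above semantics; AUC is the trapezoidal area,
which equals the Mann–Whitney probability of correct ranking with ties
counted one half — the identity is property-tested against brute-force
pair counting. Under score negation the ROC point set maps to
(1−FPR, 1−TPR) and AUC to 1−AUC; this (rather than a coordinate swap) is
the correct symmetry for the ≥-threshold convention, verified by
exhaustive threshold enumeration. Reports print at 3 decimals
(round-half-even); recomputations against published tables use an
absolute tolerance of 1e-3 since printed tables mix rounding and
truncation.

## Synthetic thermograms

The generator emulates the *layout* and the *severity signal* the
pipeline relies on, nothing more. A scalar pseudo-temperature field in
[0, 1] is built as: cool background (0.25) + two smooth warm elliptical
domes (peak contrast 0.4; semi-axes ≈48×75 px with 4% seeded jitter,
centred at 32%/68% of the content width) + Poisson(λ(stage)) Gaussian
blobs of amplitude ±a(stage) confined to the thigh masks (radius
U(6, 14) px — a mottle scale small against the ~100-px thigh width but
large against pixel noise) + i.i.d. Gaussian noise (σ = 0.02). Severity
defaults λ = (0, 6, 14, 26) and a = (0, 0.08, 0.14, 0.22) are monotone
with stage and exactly zero at stage 0, so healthy thighs are smooth and
patchwise within-mask variance grows with stage (tested over 50 seeds).
The field is mapped through a piecewise-linear rainbow palette whose
luminance is deliberately non-monotone in pseudo-temperature — the same
property that makes real false-colour exports awkward — then a framed,
densely ticked colour bar (24 px, right edge by default) and dark
pseudo-text strips (16 px, top and bottom) are composited. Ground-truth
thigh masks are returned (and written as sidecar PNGs) so ROI recall is
measurable.

What it does **not** emulate: heat diffusion physics, anatomical thigh
shapes, pose/distance variation, camera fixed-pattern noise, vignetting,
or any clinically validated stage-to-texture relationship. Passing tests
on synthetic data therefore demonstrate that the pipeline's machinery is
correct and that it recovers a known monotone texture signal; they do not
certify clinical accuracy on real thermograms.

## Problem sizes and determinism

The test suite and the acceptance script run the full chain on
212-image synthetic datasets (the reference class distribution
27/93/61/31), the size at which per-stage test counts are 8/28/18/9; the
signal check uses three generator seeds and the null check (all stage
effects zeroed) one. Every stochastic step — generation, splitting, ANN
initialisation, RF bootstraps, SVM calibration folds — draws from an
explicit seed; per-stage scorers use seed+s and per-image generator seeds
are spawned from one root seed, so identical seeds give bit-identical
images, fits and reports.

## Known limitations

* The fixed 210×240 ROI stretches crops of arbitrary aspect ratio, so
  gross thigh shape is distorted; only texture survives faithfully. This
  matches the fixed-input-size design of the downstream descriptors.
* Annotation removal assumes annotations abut the borders; watermarks or
  centre overlays would survive and contaminate the edge mask.
* The one-vs-rest probability scores of different families (and even of
  the four scorers of one model) are not calibrated against each other;
  argmax fusion is the documented, simple rule, not an optimal combiner.
* Keypoint-based descriptors (SURF/BRISK and hybrids) are not provided:
  their aggregation into fixed-length vectors is a separate design space,
  and the benchmark grid here is 6 extractors × 9 families = 54 of the
  9 × 9 = 81 systems a full sweep would enumerate.
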