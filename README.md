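# thermostage

Automatic recognition of cellulite severity stages from infrared
thermograms of the posterior thighs.

Cellulite (gynoid lipodystrophy) is clinically graded on the
Nürnberger–Müller scale: 0 (healthy), 1 (mild — alterations visible only
after pinching), 2 (moderate — "orange peel" appearance when standing),
3 (severe — visible standing and lying). Grading by inspection and
palpation is subjective; infrared thermography images the skin-surface
temperature distribution without contact, and advancing cellulite shows up
as increasingly inhomogeneous hot/cold mottling of the thermogram. This
package implements a fully automatic, purely morphological recognition
pipeline for such images — no temperature calibration is used, only the
spatial structure of the false-colour frame.

## The pipeline

1. **ROI extraction** (`thermostage.preprocess`). A 320×240 false-colour
   thermogram is converted to grayscale; the temperature-scale bar and
   text overlays are located by border edge-density profiling and excised;
   contrast is stretched between the 2nd and 98th intensity percentiles;
   thigh outlines are found with a 3×3 Sobel gradient-magnitude detector
   thresholded by Otsu's method; small components are removed and a 3×3
   morphological closing applied; the union bounding box of the thigh
   component(s) is cropped and resized (bilinear) to a 210×240 grayscale
   region of interest in [0, 1].
2. **Texture features** (`thermostage.features`). The reference descriptor
   is the histogram of oriented gradients (HOG): 48×48-px cells, 9 unsigned
   orientation bins, 2×2-cell blocks at 1-cell stride, L2 block
   normalisation. On a 210×240 ROI this is ⌊210/48⌋×⌊240/48⌋ = 4×5 cells →
   3×4 blocks × 4 cells × 9 bins = **432 features** (the raw ROI has
   210·240 = 50,400 intensities). Five further extractors — intensity
   statistics, contour geometry, uniform rotation-invariant LBP, PCA
   projections and per-stage Euclidean template distances — share the same
   interface.
3. **Classification** (`thermostage.classify`). One-vs-rest: for each stage
   s a binary scorer is fitted on labels 1{stage = s}; the predicted stage
   is argmax over the four probability scores (ties to the lowest stage).
   The reference scorer is a three-layer perceptron (one sigmoid hidden
   layer, default 20 units; sigmoid output; full-batch gradient descent on
   binary cross-entropy, 500 epochs at rate 0.05), implemented from scratch
   in numpy. Eight classical families (MinDist, KNN, NB, LogReg, SVM, LDA,
   DT, RF) plug into the same harness, giving the benchmark grid.
4. **Evaluation** (`thermostage.evaluate`). Stratified 70/30 split (per
   stage, round-half-up, seeded). Each stage is scored one-vs-rest on the
   fused predictions: TPR/FNR, TNR/FPR, PPV, F-score, trapezoidal ROC AUC,
   and binary class accuracy (tp+tn)/N, with unweighted stage averages.
5. **Synthetic data** (`thermostage.synthetic`). Labelled synthetic
   thermograms with the layout the pipeline assumes — cool background, two
   warm elliptical thighs, a right-edge colour bar, pseudo-text strips, and
   stage-dependent hot/cold Gaussian mottling (blob count and amplitude
   grow with stage; stage 0 is smooth) — so every stage of the chain is
   testable without clinical data.

## Worked example

```python
import numpy as np
from thermostage import SplitSpec, SynthConfig, generate_images, train_ovr
from thermostage.pipeline import preprocess_images, split_features

# a 212-image synthetic dataset with the reference class distribution
raws, _ = generate_images({0: 27, 1: 93, 2: 61, 3: 31}, SynthConfig(), seed=1)
rois = preprocess_images(raws)                  # 210x240 grayscale ROIs
stages = np.array([r.stage for r in raws])

X_tr, y_tr, X_te, y_te = split_features(rois, stages, "hog",
                                        split=SplitSpec(seed=17))
results = train_ovr(X_tr, y_tr, family="ann", seed=1, feature_method="hog")
print(results.evaluate(X_te, y_te).summary())
```

prints

```
One-vs-rest test metrics per cellulite stage
==============================================================================
                    n_test   TPR   FNR   TNR   PPV   FPR  F_score   AUC  class_accuracy
Stage 0 (healthy)        8 0.125 0.875 0.982 0.500 0.018    0.200 0.705           0.873
Stage 1 (mild)          28 0.821 0.179 0.629 0.639 0.371    0.719 0.796           0.714
Stage 2 (moderate)      18 0.444 0.556 0.822 0.500 0.178    0.471 0.643           0.714
Stage 3 (severe)         9 0.556 0.444 0.926 0.556 0.074    0.556 0.947           0.873
Average                 63 0.487 0.513 0.840 0.549 0.160    0.486 0.773           0.794
==============================================================================
```

Reading it: the split holds out 8/28/18/9 images per stage (63 of 212).
Each row is that stage's one-vs-rest binary problem on the fused
predictions — e.g. stage 1 sensitivity 0.821 means 23 of the 28 mild-stage
test images were predicted mild; its class accuracy 0.714 is (tp+tn)/63.
The Average row is the unweighted mean over the four stages. AUC is the
area under the ROC traced by each stage's probability-score column.

The same flow is available from the shell:

```bash
thermostage simulate  --counts 27,93,61,31 --seed 1 --out-dir sim/
thermostage preprocess --manifest sim/manifest.csv --out-dir roi/
thermostage extract   --method hog --manifest roi/manifest.csv --out features.csv
thermostage train     --features features.csv --family ann --out model.bin
thermostage evaluate  --model model.bin --features features.csv --out report.json
thermostage benchmark --manifest roi/manifest.csv --out grid.csv   # 6x9 grid
```

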