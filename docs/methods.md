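# Methods

## The problem and the pipeline

The package targets binary slice-level classification of chest CT for
malignant pleural mesothelioma (MPM) against benign pleural disease,
under the constraints typical of that setting: a small, balanced,
single-center cohort; several slices per patient; and a pleural (rim)
disease signal. The design is a hybrid: a trainable image classifier is
used only to compress each slice into its class-probability vector z;
z is then re-expressed as a small image by three generative renderers; a
per-sample representative is chosen by a centroid-distance score; and a
kernel SVM on residual-CNN features performs the final classification.
Every split — holdout and cross-validation — is grouped by patient and
stratified by the patient's label, so no patient contributes slices to
both sides of any split.

All trainable networks (the reference CNN backbone, the three renderers,
the residual feature extractor) are implemented in a compact numpy
neural-network core (`pleuradx.nnet`: dense and 3×3 conv layers,
residual blocks, pixel-shuffle upsampling, Adam, manual backprop, exact
gradients verified against finite differences in the test suite).
Standard steps go through established libraries: scikit-image for Otsu
thresholding, connected components and resizing; scikit-learn for the
SVM, logistic regression and ROC/PR machinery; Pillow for PNG I/O;
pandas for tables.

## Synthetic phantom cohort

Real MPM CT datasets are not public, so the cohort generator emulates
the *structure* of such a dataset rather than CT physics. Each slice is
an elliptical thorax: background 5, body 170, lung fields 30, pleural
rim 230 (8-bit intensities), with additive Gaussian noise (default
σ = 8). The class signal is pleural: the diseased class has rim
thickness `rim_base + class_effect` pixels (defaults 3 + 4) with
per-patient jitter (σ = 0.8 px) and 1–3 nodular bumps protruding into
the lung; the healthy class keeps the baseline rim. Slice counts per
patient are Poisson(`slices_mean`, default 5.8) clipped to [1, 12];
`total_per_class` repairs the draw to an exact per-class total when a
fixed cohort size is wanted (e.g. 86 patients and 504 slices per class,
i.e. 1008 slices from 172 patients). Demographics (sex, age, stage,
histology, asbestos exposure, smoking, chest pain, weight loss) are
sampled from fixed 172-patient reference marginals; the same marginals
drive the `summarize_cohort` count/percentage arithmetic.

What the phantom does *not* model: DICOM/3-D geometry, scanner physics
and artifacts, anatomical variability beyond rim jitter, and any effect
of stage or histology on the image. Passing tests therefore demonstrate
that the pipeline's machinery propagates a pleural-rim class signal
end-to-end without leakage — not clinical performance on real CT.

## Segmentation and overlay

The testable mask provider is deliberate plumbing: Otsu threshold →
8-connected components → area filter (default min 50 px), masks ordered
by decreasing area. The overlay is a convex blend, `alpha·color +
(1−alpha)·base`, rounded half away from zero, with alpha capped at 0.5
so the underlying tissue always remains at least 50% visible; the
palette cycles across masks and later (smaller) masks overwrite earlier
ones where they overlap. Provider failures on individual images yield
empty mask sets with a logged warning; only a provider failing on every
image aborts the batch. The classifier consumes the RGB overlay.

## Backbone and class-based features

The reference backbone is a from-scratch CNN: three stride-2 3×3 conv
blocks (16/32/64 channels), global average pooling, and a linear K-way
logits head trained jointly with cross-entropy and Adam. The head's
softmax probabilities are the class-based features F₁…F_K (F₁ =
probability of the first class in sorted label order); raw logits are
retained alongside for the direct-logits ablation, and the 64-wide
pooled representation is exposed as the dense "FC" feature block.
Default input size for the reference CNN is 64×64 (bilinear resize,
never cropping): at phantom scale this loses no rim signal and keeps
training to seconds; `BackboneSpec.input_size` accepts larger sizes.
`BackboneSpec` defaults (lr 1e-4, 15 epochs, batch 32, seed 42) suit a
fine-tuning regime; the pipeline's default config uses lr 1e-3 and 8
epochs because the reference CNN trains from scratch. Pretrained
transformer backbones can be adapted behind the same
train/logits/fc-features contract but require external checkpoint
downloads and are intentionally outside the test surface.

## Target encoding and the three renderers

The renderers need a reconstruction target; the package defines
T(z)[r,c] = clip(2·Σₖ zₖ·Gₖ(r,c) − 1, −1, 1), where Gₖ is an
unnormalized Gaussian bump (σ = H/6) at the class-k anchor — opposite
quadrant centers for K = 2, a circle around the image center otherwise.
Pixel coordinates are taken at pixel centers, which makes T exactly
symmetric under 180° rotation for symmetric z. T is smooth and injective
on the simplex, so rendering preserves class information by
construction, and it gives all three renderers a common, testable
objective:

* **Decoder-MLP**: K → 64 → 256 → H·W dense layers, ReLU hidden, Tanh
  output, MSE to T(z).
* **GAN**: generator G(z, noise₈) with the decoder's architecture;
  discriminator D(image, z) (H·W+K → 128 → 64 → 1); non-saturating
  adversarial loss plus λ·MSE-to-target with λ = 100. Inference zeroes
  the noise, making rendering deterministic.
* **NeRV-style**: input concat(positional-encoding(t, 6 bands), z) where
  t is the sample's normalized index; MLP to an (H/4, W/4, 16) feature
  stack followed by two ×2 pixel-shuffle upsamplings and Tanh. Pixel
  shuffle is NeRV's own upscaling primitive and is a pure permutation,
  which keeps the numpy backward pass exact; the reconstruction target
  is t-free, so t-conditioning adds an index pathway without changing
  the objective.

Rendered images are 32×32 in [−1, 1] (persisted 8-bit: −1 → 0, 1 → 255).
Training: Adam, lr 1e-3, ≤ 300 epochs (pipeline defaults 150/100/150),
minibatch 64, fixed seeds. Non-finite losses abort with a diagnostic.
A constant feature table logs a degeneracy warning but still trains.
The per-sample reading (one render per K-vector z) was chosen over a
per-scalar reading (one render per feature column) because selection
and the manifest operate per sample.

## Discriminative selection

DS(m) = d(m, C_neg)/d(m, C_pos), Euclidean, on flattened pixel vectors;
centroids are the arithmetic means of all candidate images (all three
renderers pooled) per class, fitted on training-split samples only to
avoid test leakage. A representative should be near its own class
center and far from the rival's, so selection takes the argmax of the
ratio; the opposite orientation is exposed behind a flag
(`orientation="min"`) for comparison. Ties break in the fixed order
decoder → gan → nerv. If m coincides with C_pos (distance < 1e-12) the
score is the capped sentinel d(m, C_neg)/1e-12. The selection outcome is
persisted as a CSV manifest with header
`Index,Selected_Method,Label,Image_Path`; label and path are kept
consistent by construction. The variance-threshold alternative picks the
candidate with the highest pixel variance and ignores labels entirely.

## Residual SVM and ablation classifiers

The residual feature extractor is a small residual CNN (stride-2 stem,
two identity residual blocks, stride-2 transitions, global average
pooling to a declared width of 32) trained briefly (default 6 epochs) as
a classifier on the training-split selected images; its penultimate
pooled features feed the final classifier and the head is discarded.
The SVM is sklearn's SVC with polynomial degree 3, coef0 = 1, C = 1 and
`gamma="scale"` = 1/(d·Var[x]) — the "cubic, auto kernel scale, box
constraint 1, one-vs-one" convention — with libsvm's built-in Platt
scaling for probabilities (calibration and decision-curve analyses need
them). Ablations share the interface: logistic regression (L2, sklearn)
on the same features, and a direct-logits SVM on the K-dimensional
class-based features with rendering bypassed (using the retained raw
logits when present).

## Evaluation

Sensitivity, specificity, precision, F-score and accuracy are computed
from per-class confusion matrices (each class in turn as positive) and
macro-averaged as the unweighted class mean; zero denominators yield 0
with a logged warning rather than an exception mid-report. ROC AUC is
trapezoidal; precision-recall uses sklearn's sweep. Calibration uses 10
equal-width bins with empty bins flagged. Decision-curve net benefit is
NB(pt) = TP/N − (FP/N)·pt/(1−pt) against treat-all
(prev − (1−prev)·pt/(1−pt)) and treat-none (0), thresholds in (0, 1)
only. Bootstrap CIs are seeded percentile intervals over resampled
evaluation cases (default B = 200 in the pipeline; B ≥ 100 enforced);
resampling is at the image level — patient-level resampling would be a
defensible alternative but was not adopted. Under cross-validation every
stage (backbone, renderers, extractor, classifier) is retrained inside
each fold; per-fold confusion matrices are reported and sum to the
pooled matrix by construction.

## Orchestration and reproducibility

A single global seed fans out to per-stage seeds via
`stage_seed(seed, name) = (seed·1000003 + crc32(name)) mod 2³¹`, so any
stage can be re-run independently and two runs with the same config are
bit-comparable in every deterministic artifact (the test suite asserts
this). The run manifest records stage seeds, cohort hash, sizes and
accuracies. The ablation grid shares the backbone/rendering stages
within each split across its four scenarios (full, no-rendering,
variance selector, logistic regression), which is what makes the
4 × 2 grid affordable on one CPU.

Problem sizes used by the shipped diagnostics: the end-to-end runs use
the 86 + 86-patient phantom cohort (504 slices per class) with
`class_effect = 6` under the holdout scheme, and a 40 + 40-patient
cohort for k = 5 cross-validation; renderer-fidelity checks train on 200
uniformly drawn probability vectors and score a step-0.1 z-grid. These
sizes were chosen so a full reproduction stays within minutes on a
single CPU while keeping every class separable at the stated effect
size.

## Known limitations

* The phantom's class signal is geometric and strong at the default
  effect size; absolute accuracies on it (typically ≥ 0.99) say nothing
  about clinical performance.
* Renderers are trained against a fixed, hand-chosen target encoding;
  other encodings (e.g. learned autoencoders) may behave differently.
* Binary classes only; the K > 2 generalizations (anchor circle,
  nearest-rival centroid) are implemented but not exercised by the
  pipeline.
* The numpy networks are single-threaded and CPU-bound; they are sized
  for the phantom scale, not for 224×224 clinical imagery.
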