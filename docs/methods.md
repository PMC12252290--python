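# Methods

## Problem and pipeline

`nucat` implements a two-stage analysis of slit-lamp pupil images for nuclear
cataract (NC):

1. **Gate (one-class)** — decide CATARACT vs NON-CATARACT. No public
   slit-lamp dataset of healthy eyes exists, so the decision is posed as
   *reversed* anomaly detection: a convolutional autoencoder (CAE) is trained
   only on cataract images, which play the role of the "normal" class.
   Pseudophakic (IOL) eyes — clear artificial lens, specular glints — serve as
   the non-cataract class at evaluation time.
2. **Grading (six-class)** — for gated images, assign an NC grade 1–6 on the
   LOCS III scale with a convolutional classifier.

A third, deployment-facing stage exports trained classifiers to a portable
graph format and quantifies how much the metrics move after conversion.

## Preprocessing

Inputs are either RGBA images whose alpha channel marks the manually
extracted pupil, or an RGB eye image plus a user-drawn circle (rasterized to
an alpha mask; a pixel is inside when its center lies within the radius,
inclusive). The visible region is tightly cropped to the alpha>0 bounding
box; transparent pixels inside the box are composited onto **black** (the
background color is an open choice; black matches the rotation fill used in
augmentation, so both sources of synthetic background agree). The crop is
resized to 224×224 with box-filter **area interpolation** (PIL `Image.BOX`),
then scaled to [0,1] and standardized with the ImageNet channel statistics,
mean (0.485, 0.456, 0.406) and std (0.229, 0.224, 0.225).

Augmentation (training only, applied offline to expand the training list by
an integer multiplier) draws, in a fixed order: horizontal flip with
probability 0.5, rotation uniform in ±15° (bilinear, black fill), then
brightness and contrast scalings each uniform in [0.8, 1.2]. Each augmented
copy's generator is derived from (seed, copy index, image index), so
expansion is reproducible and order-independent.

## Gate model

The CAE encoder is four 3×3 convolutions with stride 2, each followed by
ReLU (224 → 112 → 56 → 28 → 14 spatially); the decoder mirrors it with four
4×4 stride-2 transposed convolutions, each followed by ReLU. Default channel
widths are 8/16/32/64; training uses Adam (lr 1e-3), batch 16, 8 epochs,
minimizing mean squared reconstruction error. The widths and epoch count
were sized for single-CPU training; on phantom data the reconstruction-error
separation between cataract and IOL classes saturates well before larger
configurations would pay off, and all values are configurable.

Reconstruction error is computed on the **[0,1] intensity representation**,
not on the ImageNet-normalized tensors, so the MSE scale is comparable
across images and thresholds are interpretable.

The decision threshold τ is a percentile of the training-error distribution
(linear interpolation between order statistics), and the decision direction
is an explicit model field. The reversed-logic configuration "τ at the 1st
percentile with error ≤ τ → CATARACT" accepts only the ~1% most accurately
reconstructed images and therefore rejects almost all cataract inputs; the
shipped default keeps the same direction but places τ at the **99th**
percentile, so ~99% of cataract-class training images fall inside the
accepted region while poorly reconstructed (non-cataract) inputs fall
outside. P = 1 remains available for the strictest gate. Ties (error = τ)
resolve to CATARACT. The threshold is calibrated on training-set errors
only.

## Grading model

Six architecture ids are exposed: `vgg11`, `vgg16`, `resnet18`, `resnet50`,
`mobilenet_v3`, `efficientnet_b0`. Each is a compact, family-faithful
variant built on this package's numpy CNN engine: plain 3×3-conv/maxpool
ladders with a fully connected head (VGG), basic and bottleneck residual
blocks (ResNet-18/-50 style), inverted residual blocks with depthwise
separable convolutions (MobileNetV3 style; the id follows the Methods-level
naming of the source app, whose summary also mentions V2), and expansion-6
MBConv-style blocks (EfficientNet-B0 style). Widths are scaled to ~0.1–1.1M
parameters so the networks train from scratch on one CPU. There is no
bundled ImageNet weight zoo, so `pretrained_init` must remain False; the
flag exists to keep the configuration surface explicit.

The default training recipe is cross-entropy, Adam with lr 1e-4, 100
epochs, batch 32, `ReduceLROnPlateau` on validation loss with patience 2
(factor 0.1), and the checkpoint with the best validation accuracy is
returned. That recipe presumes long schedules; the scaled-down phantom
checks in the test suite use 10 epochs with lr 1e-3, which is the
appropriate operating point for small from-scratch networks on a few
hundred images.

Splitting is stratified 80/10/10 by default. Per class, subset sizes follow
the **largest-remainder rule** (floors of the exact quotas, leftovers to the
largest fractional remainders, ties toward the earlier subset — so a
singleton class lands in training). Cross-validation reuses the same
allocator with k equal fractions; the overfit statistic is the gap between
mean training and mean validation accuracy, with the sample standard
deviation (ddof = 1) of the per-fold differences.

Metrics are accuracy plus macro-averaged precision/recall/F1 over the class
set (macro is the conservative convention for imbalanced grades); the
confusion matrix is stored rows = true, cols = predicted. Classes absent
from both truth and predictions contribute 0 to the macro averages and
raise a warning. Grade prediction is the argmax of the softmax, ties
breaking toward the lowest grade.

## Export and parity

Trained networks serialize to a portable compute graph: a JSON manifest of
ops plus an NPZ of weights. A separate interpreter re-executes the graph by
a *different numerical route* — sliding-window views with `einsum` in
float64, and transposed convolution as zero-stuffed correlation with the
flipped kernel — so native-vs-exported agreement is a genuine cross-check
rather than running the same code twice. The contract is max-absolute logit
deviation ≤ 1e-4 on pinned phantom probes for every architecture. The
optional `float16` leg stores weights at half precision, a lossy analogue of
mobile-format conversion; the parity report *measures* its deviation and
accuracy delta rather than bounding them, mirroring how post-conversion
degradation is a finding, not a contract.

## Phantom generator

Real slit-lamp images cannot ship with the package, so tests and experiments
run on rendered phantoms that carry exactly the features the pipeline keys
on: a roughly circular dark pupil (radius 0.8 of the half-image, small
seed-dependent jitter) on a brown, radially fibered iris texture; for grade
g ∈ 1..6 a centered nuclear opacity whose yellow-brown chroma and brightness
ramp linearly with opacity strength (g − 0.5)/6; for IOL a darker,
low-chroma pupil with a faint bluish rim reflex and 1–3 small specular
glints; Gaussian pixel noise (sd 8 intensity levels); optionally a saturated
white elliptical overexposure patch. Per-image seeds derive from
(master seed, label, index) through `numpy.random.SeedSequence`.

The defaults make grade classes separable by mean pupil chroma alone
(a nearest-class-mean rule on that statistic reaches ≥ 95% accuracy), which
guarantees the downstream learning tasks are solvable at test scale. What
phantom results do **not** show: robustness to the anatomy, illumination
geometry, focus and acquisition variability of clinical slit-lamp
photographs, or to the genuinely hard grade-3/grade-4 boundary; absolute
accuracies on phantoms are not comparable to accuracies on clinical data.
The generator's appearance model is invented, and tests deliberately assert
only its contracted properties (determinism, monotone grade signal, IOL
separability), not cosmetic pixel details.

## Problem sizes and numerical choices

End-to-end checks run at desk scale as the package's own experiment design:
the gate trains on 300 phantoms (50/class) and is evaluated on 300 held-out
grade phantoms + 100 IOL phantoms; the grader trains on 240 phantoms
(6×40, stratified 80/10/10, 10 epochs); cross-validation uses 120 phantoms
with k = 5 at 5 epochs; parity uses 10 pinned probes per architecture and a
60-phantom probe set. All arithmetic is float32 in the training engine
(float64 in the interpreter and error statistics). Degenerate inputs fail
loudly: empty ROIs, empty training sets, empty error lists, unknown labels
and architectures, k > n folds all raise with specific messages.

## Known limitations

- The gate's absolute threshold is dataset-dependent; a clinical deployment
  would recalibrate the percentile on clinical training errors.
- The architecture zoo's variants are family-faithful but not weight- or
  depth-identical to the published reference networks; conclusions about
  *relative* family behavior transfer, absolute capacity does not.
- No TFLite/ONNX runtimes are involved; the portable-graph parity surface
  measures conversion fidelity of this package's own export chain.
- The optional real-data loader expects a `path,label` manifest; it does not
  download or redistribute the clinical database.
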