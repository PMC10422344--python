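# Methods

## Overview

The pipeline is an end-to-end study harness: synthetic labeled brain-MRI-like
images are preprocessed, partitioned, augmented by each of five GAN variants,
classified by a fixed small CNN, and the augmenters are ranked by soft voting
over confusion-matrix metrics. Every stage is a pure function of its inputs
and a seed; a single global seed derives per-stage seeds by mixing a CRC32 of
the stage name, so one integer reproduces an entire run bit-for-bit (wall-clock
latency excluded).

## Phantom model

Each phantom is a 2-D 8-bit image composed of a bright elliptical skull ring,
a darker brain interior filling 88 % of the inner skull radius (the remaining
band is a dark CSF-like gap that detaches the brain from the skull — this gap
is what makes largest-component skull stripping well-posed), and an optional
tumor blob. The blob is a Gaussian-smoothed disk (sigma 0.8, support clipped
back to the disk so its pixel count stays close to pi r^2) adding +60 gray
levels over the brain mean. Tumor position follows the class prior:

- glioma: off-center in either cerebral hemisphere;
- pituitary: inferior-central (the sella region);
- meningioma: peripheral and superior, as close to the inner skull surface as
  the blob radius allows.

Placements are expressed in normalized elliptical coordinates and clamped so
the blob always fits inside the brain at any image size; the prior *regions*
used for auditing are computed with the same clamped centers and are pairwise
disjoint, which makes a per-region mean-intensity statistic a perfect class
separator at moderate noise (verified over 100 samples in the tests). Noise
is additive white Gaussian plus a smoothed low-frequency texture inside the
brain, both scaled by `noise_sigma` (default 6 gray levels); at
`noise_sigma=0` the rendering is exactly piecewise constant, which the
morphology tests exploit.

What the phantom does *not* model: MR physics (bias fields, partial volume,
Rician noise), 3-D anatomy, tumor texture heterogeneity, or inter-patient
variability. Passing tests therefore demonstrate the pipeline's mechanics and
internal consistency, not clinical performance on real MRI.

## Preprocessing

All morphological primitives are implemented from first principles (the test
suite uses scipy.ndimage only as an independent oracle).

Skull stripping: Otsu binarization (exhaustive within-class-variance
minimization over all 256 thresholds, ties to the smallest), largest
foreground component (8-connected by default, ties broken by raster order),
one dilation by a 3x3 square, then morphological reconstruction by dilation
constrained to the Otsu foreground, and finally superimposition (pixels
outside the mask become 0). The reconstruction uses the Otsu binary image as
its constraint; the reconstruction structuring element defaults to a 3x3
square, the standard 8-connected geodesic convention.

Contrast improvement: complement, grayscale closing of the complement by a
flat disk (radius 5 by default), complement back — algebraically the
grayscale opening — then the white top-hat (image minus opening, nonnegative)
is added back with saturation at 255. Grayscale erosion/dilation are flat
min/max filters with the footprint clipped at image borders; clipping is
self-dual, so the complement identity holds exactly, and the opening is
anti-extensive, so the output never darkens any pixel. Both algorithms
operate on the stripped image throughout.

## Dataset handling

Manifests are CSV files (`path,label,plane,split` plus an `origin` column
tagging synthetic rows). Splitting is stratified per class with the rounding
rule train = floor, validation = round-half-up, test = remainder; at 60:20:20
this reproduces the published per-class partition of the 3064-image reference
collection exactly (1426 -> 855/285/286, 708 -> 424/142/142, 930 ->
558/186/186). Splitting is by image, not by patient, mirroring the reference
protocol; this is a known leakage caveat, kept deliberately.

Balancing oversamples every minority train class up to the majority count,
either by duplicating rows or by SMOTE: each synthetic image is
x + u (x_nn - x) with u ~ U(0,1) and x_nn one of the k = 5 nearest same-class
neighbours in flattened-pixel Euclidean space, quantized without leaving the
parents' pixel-wise interval. Validation and test splits are never touched.

Model inputs are scaled by the fixed factor 1/255 rather than per-image
min-max: per-image normalization would erase absolute intensity differences,
which can carry class information. The standalone `normalize` utility offers
min-max and z-score schemes for other uses.

## GAN variants

All five variants run the same alternating adversarial loop on a compact
numpy layer library (`nn.py`: im2col convolutions, transposed convolutions,
batch norm, Adam, manual backprop). Channel widths cap at 32: the point is
mechanism fidelity, not sample quality, and no published layer tables exist
for these augmenters. Adversarial loss is non-saturating cross-entropy,
except CycleGAN which uses least squares per its original convention. Default
training budget is 150 steps at 16x16, batch 16, Adam at 2e-3 with beta1 0.5.

- DCGAN: strided-conv discriminator with batch norm and leaky ReLU (0.2),
  transposed-conv generator with a sigmoid output in [0,1]. Unconditional,
  so augmentation trains one model per class.
- Conditional GAN: one-hot label appended to the latent vector and broadcast
  as constant planes onto the discriminator input.
- InfoGAN: the latent carries a categorical code of dimension = number of
  classes; a recognition head on the shared discriminator trunk is trained
  (with the generator) on the cross-entropy variational lower bound of the
  mutual information between code and image. Codes double as class labels
  for augmentation; note the code-to-class assignment is emergent, not
  supervised.
- CycleGAN: two generator/discriminator pairs translating between two tumor
  classes with an L1 cycle-consistency penalty (weight 10). Generators are
  residual — output = input + f(input) with f's last convolution
  zero-initialized — so they are exact identities at initialization and the
  cycle loss starts at 0. As an augmenter, the model for class X is trained
  on the pair (previous class, X) in alphabetical ring order and synthesizes
  X by translating held real images of the paired class.
- PGGAN: training walks the schedule [4, 8, ..., target]; each stage owns a
  toRGB/fromRGB 1x1 head, and when a stage opens, its block is blended with
  the upsampled previous head via a fade-in coefficient rising linearly from
  0 to 1 over the first half of the stage (the first stage needs no fade).
  The step budget is split equally across stages; optimizer state restarts
  at each stage boundary since the parameter set grows. Equalized learning
  rates and minibatch-stddev refinements are deliberately out of scope.

Per-class models at generation time attach their class tag to every sample;
conditional models take the label as an argument. Generated values are
clipped to [0,1] and written as 8-bit PNGs tagged with their variant in the
manifest's origin column.

## Classifier

The modulated CNN is fixed at 7 convolutions, 4 max pools, 4 ReLUs, 1 fully
connected layer, with dropout after every convolutional block: four
conv(3x3)-relu-pool-dropout blocks (widths 8, 16, 32, 32), then three further
3x3 convolutions with dropout on the 16x-reduced feature map, then the dense
head. Input resolution must be divisible by 16. The head is a sigmoid for
binary (malignant/benign) output or softmax for the three tumor classes —
the dataset is 3-class, so multiclass is the default and binary is a config
switch. Training minimizes cross-entropy with Adam (defaults: rate 1e-3,
20 epochs, batch 16 — small batches matter at desk scale because the number
of gradient steps, not the epoch count, drives convergence on tens of
images).

Vote-counting prediction (binary head): score `n_views` stochastic views of
the image (identity, random horizontal flips, shifts up to 2 px); each score
strictly above the threshold increments the malignant counter, otherwise the
benign counter; the image is Malignant only when the malignant counter
strictly exceeds the benign one, so ties are Benign. With one view this
reduces to plain thresholding. The counter bookkeeping in the source
procedure is ambiguous (both counters incremented in the same branch); the
implementation uses the only self-consistent reading: one counter per view,
strict-inequality decision.

## Evaluation and soft voting

Undefined ratios (zero denominators) are reported as undefined-with-reason
rather than silently 0, except the F-score, which is 0 when TP = 0 but
errors exist. Accuracy is a weighted mean of precision and NPV, a relation
the tests check numerically. The published metric table never needed a
tie-break (one augmenter dominates all five metrics), so the aggregation
rule was genuinely open; both mean-of-metrics and metric-wise-wins are
implemented, rankings under both are always reported, and ties break by
accuracy then lexicographic variant name.

## Problem sizes and numerical choices

Default study conditions: 300 phantoms (100 per class) at 32x32 with tumor
radius 3.5 and noise 6; GANs at 16x16 for 150 steps; 20 synthetic images per
class per augmenter; classifier at 32x32 for 20 epochs. A full end-to-end
run takes well under a minute on one CPU and reaches perfect held-out
accuracy on the separable phantom classes — the informative outputs are the
mechanism audits (training logs, fade-in traces, augmentation bookkeeping),
not the ceiling-level metric values.

Other numerical choices: saturating uint8 arithmetic everywhere images are
written; Otsu is undefined on constant images (error, not a default); the
largest-component tie-break is raster order; reconstruction terminates
because its iterate is monotone and bounded; batch norm uses batch statistics
during training and running averages (momentum 0.9) at generation; dropout
is inverted and disabled at prediction.

## Limitations

Sample quality of the desk-scale GANs is far below production scale and is
not scored (no FID/IS); CycleGAN's class pairing is a configuration choice;
InfoGAN's codes may not align with the intended classes; the phantom's
separability ceiling means augmenter rankings on phantoms routinely tie; and
all results concern synthetic data — nothing here validates clinical use.
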