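# Methods

This note records the modeling, numerical and design choices behind the
package, in particular every place where the architecture description left a
decision open and what this implementation chose.

## Network

**Layout.** A 7×7×7 stride-2 convolution maps the input volume to 32
channels. Four encoder levels (widths 32, 64, 128, 256) each stack one or
more MDDMS feature blocks with one channel-attention (MDCA) block at the end
of the level; 2×2×2 stride-2 convolutions descend between levels. The
decoder ascends with 2×2×2 stride-2 transposed convolutions; each skip
connection passes through a residual block and is fused with the upsampled
features by an RSA spatial-attention block. A final transposed convolution
restores the input resolution; the decoded features are concatenated with
the raw input volume, fused by a residual block, and a pointwise head with
softmax emits per-class probabilities. Spatial extents must be divisible by
16 (stem plus three descents).

**Calibration of open hyperparameters.** The architecture description fixes
the stem width (32), the number of levels (4), the multi-scale kernels
(5/7/9 with cross-kernel 3) and the attention ratios (r = 4), but not the
number of feature blocks per level, the internal width of the
full-resolution fusion stage, or the PSC expansion ratio. The published
footprint (26.97M parameters, 84.837G FLOPs at 96³) is the only global
constraint, so these were fixed by grid search against it with the analytic
profiler: PSC ratio 4, blocks per level (1, 1, 1, 2), final fusion width 18.
The resulting defaults profile at 26.73M parameters (−0.9%) and 85.68G MACs
(+1.0%), both inside the 2% calibration band. Channel attention applied once
at the end of a multi-block level (rather than after every block) follows
the stated placement "at the end of the module" and is part of the same
calibration.

**Choices where the description is silent.**

* PSC is two pointwise convolutions (expand ×ratio, compress back) with a
  leaky rectification between — the minimal realization of "expansion and
  compression" that stays pointwise.
* The depthwise gate is a depthwise 3×3×3 convolution → sigmoid →
  elementwise multiply.
* The third axis equation is read as the width branch (the printed text
  repeats the depth symbol with width-oriented kernels; treating it as a
  typo keeps the three branches distinct).
* LeakyReLU uses negative slope 0.01 everywhere.
* The MDCA axial convolutions keep the channel width (C→C); its fully
  connected layer maps 3C→C so the sigmoid yields one weight per channel.
* Instance normalization follows convolutions inside residual and RSA
  blocks, and additionally after each axial depthwise convolution and the
  two fusion convolutions inside MDDMS. The latter is a numerical necessity
  of this implementation: the three-scale product fusion cubes the
  activation scale, and without normalization a four-level stack overflows
  in float32 at initialization. Biases are dropped on convolutions
  immediately followed by a norm.
* The elementwise product over the three gated scales is taken in kernel
  order with no rescaling (at zero gate initialization it attenuates by
  0.5³; no normalizer is introduced).
* Sequential MDCA (feature block, then attention with its own residual) is
  the default; `mdca_parallel=True` computes the channel weights from the
  level input and applies them to the feature output, the alternative
  "applied in parallel" reading.
* Residual blocks are conv–norm–act, conv–norm, plus an identity (or
  pointwise-projected) skip added without a post-sum activation, so
  zero-initialized convolutions give an exact identity.
* Weights use He-style normal initialization (fan-in, leaky-ReLU gain);
  biases start at zero. Initialization is bit-reproducible per seed.

**Profiler.** `profile` enumerates every trainable weight exactly and
accumulates multiply-accumulate counts analytically during a shape-only
traversal of the same forward code path. One MAC counts once; only
convolutional, transposed-convolutional and fully connected layers
contribute (normalization, activations and pooling are excluded), the
convention under which such footprints are usually printed.

## Differentiation and optimization

No GPU framework is assumed. Layers are numpy arrays in nested dicts;
gradients come from `autograd` with custom primitives for dense, depthwise
and transposed 3D convolution (shift-and-add over kernel taps, each tap one
BLAS contraction, with hand-written vector-Jacobian products), plus fused
leaky-ReLU / sigmoid / instance-norm primitives. All primitives are verified
against nested-loop convolution oracles and central finite differences in
the test suite. AdamW is implemented directly (decoupled weight decay 1e-2,
β = (0.9, 0.999), ε = 1e-8).

## Training protocol

Dice + cross-entropy loss with equal weights; the soft Dice term averages
over all classes including background with smoothing 1e-5 in numerator and
denominator. Patches are drawn one at a time, batch size 1; a patch is
centered on a foreground voxel with probability ratio/(1+ratio) (ratio 1 by
default). The stated protocol mixes an iteration cap (40,000) with
epoch-based patience (15), so an "epoch" here is one pass over
`patches_per_epoch` sampled patches (default 250); patience counts these
epochs and the iteration cap is honored exactly. Validation Dice is the mean
foreground DSC over the validation cases under sliding-window inference; the
best-validation parameters are returned. The learning rate is constant
(1e-4 preset; no schedule is specified). A non-finite loss aborts with a
diagnostic rather than continuing.

Cross-validation: a seeded shuffle is split into 5 folds; each fold's test
part is held out and 1/8 of the remaining cases (at least one) form the
validation set.

Sliding-window inference tiles the volume with configurable overlap
(default 0.25), averages class probabilities uniformly in overlaps and takes
the voxelwise argmax; volumes smaller than the window are zero-padded
symmetrically and cropped back.

## Preprocessing and augmentation

Resampling uses trilinear interpolation for images and nearest-neighbor for
labels; new extents are round(old · old_spacing / target_spacing). Cohort
presets carry target spacings (1.2, 1.2, 2.0) mm and (0.93, 0.93, 1.0) mm
and the CT intensity window [−145, 275], mapped linearly to [0, 1] and
clamped. Foreground cropping takes the bounding box of strictly positive
remapped intensities (margin 0); the cropping criterion is not stated in the
architecture description, so intensity-based cropping was chosen over
label-based to keep the test path label-free. Patch centers are clamped so
patches stay inside the volume; smaller volumes are zero-padded
symmetrically first.

Every training patch receives a rotation about the depth axis (angle uniform
in [0, π/30]) and a uniform scaling (one factor in [0.9, 1.1] applied to all
axes — "uniform" is read as isotropic); with probability 0.5 a single scalar
offset uniform in [−0.1, 0.1] is added to the image intensities. Resampling
out-of-bounds values replicate the edge. Validation and test cases are never
augmented.

## Synthetic phantoms

A phantom is a rotated ellipsoid organ (default semi-axes scaled from
13×30×15 voxels at 96³ — small and elongated in-plane) with 1–3 spherical
tumors of radius 3–6 voxels placed strictly inside the organ via a distance
transform, over a homogeneous background. Default intensities 0.25 /
0.55 / 0.65 give organ-vs-background contrast 0.3 and tumor-vs-organ
contrast 0.1 on the [0, 1] scale. Boundaries are blurred with a Gaussian
(σ = 1 voxel) before additive Gaussian noise (σ = 0.05) and clamping.
Overlapping tumors merge into one lesion label, preserving the label
hierarchy the metrics assume. Dataset generation jitters geometry per case
from a master seed and writes NIfTI pairs plus a JSON manifest.

What phantoms do not emulate: CT texture and artifacts, neighboring organs,
intensity inhomogeneity, anisotropic acquisition. Passing end-to-end runs on
phantoms therefore demonstrates pipeline correctness and desk-scale
learnability, not clinical segmentation accuracy — reproducing cohort-level
DSC/HD95 figures would require the external datasets and GPU-scale training
and is out of scope here.

## Metrics

Per-class one-vs-rest evaluation. Empty-mask conventions: both masks empty →
DSC = Jaccard = 1, HD95 undefined (NaN); exactly one empty → DSC = Jaccard
= 0, HD95 undefined; undefined HD95 values are excluded from means while DSC
values always count. Sensitivity/specificity are NaN when their denominator
is zero. Surfaces are foreground voxels with a 6-connected background or
out-of-volume neighbor; HD95 is the 95th percentile (linear interpolation
between order statistics) of the pooled directed nearest-surface distances
in both directions, scaled to millimetres by the voxel spacing. The printed
formula nests a percentile around a maximum of suprema (a single number);
the standard pooled-percentile reading is used, matching the accompanying
prose. The paired t-test is two-sided on fold-wise scores; identical samples
give (t = 0, p = 1) and a constant nonzero offset is flagged degenerate
instead of reporting an infinite statistic.

## Problem sizes in the test suite

Unit tests run blocks at 8 channels on ≤8³ volumes and the full-width
network only through the analytic profiler. The trainability check memorizes
one 32³ phantom with the default-width network (learning rate 1e-3, chosen
by a pilot run of the same protocol; convergence to foreground DSC ≥ 0.95
typically takes ~20 iterations). The end-to-end smoke run uses four 48³
phantoms, 50 training iterations and 32³ windows. These sizes are the
package's desk-scale defaults; the 96³ patch preset remains available for
real cohorts.

## Known limitations

* CPU-only: a 96³ forward pass of the default network is minutes, not
  milliseconds; realistic cohort training is out of reach by design.
* The conv primitives support only the cases the network needs (uniform
  stride, kernel = stride for transposed convolutions).
* No elastic deformation, mirroring or gamma augmentation; no DICOM input.
* Checkpoints store raw weights plus configs in a compressed npz archive;
  no cross-framework export.
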