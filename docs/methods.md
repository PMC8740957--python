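# Methods

## Problem and model

`siamreg` performs deformable registration of 3-D volume pairs whose
voxel grids may differ in extent per axis — the situation that arises
when two MR sequences of the same anatomy (e.g. a contrast-enhanced
sequence and a time-of-flight angiogram of a carotid artery) are acquired
or cropped to different matrix sizes.  The fixed image `I_F` defines the
output space; the moving image `I_M` is resampled into it through a dense
displacement vector field (DVF) `u`, with the backward-mapping transform

    T(x) = x + u(x),        warp(I_M, u)(x) = I_M(x + u(x)),

`u` in voxel units on the fixed grid.

The DVF is predicted by a Siamese U-Net: two encoders with **shared
weights** digest the fixed and moving inputs (each input is the image
stacked with its binary anatomical label map as a second channel;
a label-free mode exists for inference without labels).  Weight sharing
means both branches measure features on one common scale, and a fully
convolutional encoder accepts any extents divisible by `2^levels`.  The
encoder applies a 7x7x7 first convolution, then per level two 3x3x3
convolutions followed by 2x2x2 max-pooling, channel counts doubling from
`base_channels`.  Because the grids differ, the moving branch's feature
maps are smaller at every level; a padding module zero-pads them out to
the fixed branch's feature extents — symmetrically per axis, an odd
difference placing the extra cell on the trailing edge, or on a single
edge when configured.  Padding happens strictly at feature scale, between
encoder and decoder: padding the raw input would contaminate the
low-level features of the original image.  A single decoder then
up-samples (nearest-neighbour + convolution), concatenating skip features
from *both* branches at each level, and a final zero-initialized
convolution maps to the 3 displacement components, so an untrained
network emits exactly the identity transform.

## Training objective

The two modalities have unrelated intensity distributions, so training is
weakly supervised: the loss only sees anatomical labels.  With `p` the
warped (soft, trilinearly interpolated) moving label and `g` the fixed
label:

* soft Dice:  `L_DSC = 1 − 2·Σ(p·g) / (Σp + Σg + ε)`, `ε = 1e-6`;
* multi-scale Gaussian-smoothed Dice (GDSC): each label is convolved with
  a separable discrete Gaussian `k(x) ∝ exp(−x²/2σ²)` sampled at integer
  offsets `−3σ..3σ` and normalized to unit sum, for every σ in the scale
  set (default `{0, 1, 2, 4, 8}`; σ = 0 is the identity); the loss is one
  minus the mean per-scale Dice overlap.  Smoothing spreads sparse
  foreground spatially, which bounds the per-voxel Dice gradient — the
  closed form `|∂L_DSC/∂p| = 2g²/(p+g)²` blows up as `p+g → 0`, and the
  test suite demonstrates that the smoothed loss's maximum per-voxel
  gradient is strictly smaller on sparse disjoint labels.

  Note a consequence of this formulation: smoothed labels are soft, so
  the per-scale overlap of *identical* labels sits below one and the
  multi-scale loss has a nonzero floor.  Perfect alignment is still the
  minimizer; only the σ = 0 scale reaches exactly zero.
* smoothness: `L = L_GDSC + α·L_smooth`, `α = 0.5`.  Three regularizer
  variants are implemented.  `diffusion` (default) is the mean squared
  Frobenius norm of the forward-difference Jacobian of `u`.  `gradient`
  is the un-squared norm, and `bending` the mean squared second-order
  differences over the valid interior.  The un-squared norm is *not* used
  for training: it is an L1-type penalty whose gradient keeps unit
  magnitude however small the field becomes, and with label-overlap
  gradients of order 1e-4 it measurably drives the network to the exact
  zero field.  The squared form's gradient vanishes with the field and
  trains properly; it is the standard diffusion regularizer of the
  learning-based registration literature.

Optimization uses Adam.  Cross-scale pairs cannot share a dense
minibatch, so a "batch" accumulates gradients over `batch_size`
single-pair passes before one optimizer step.  On-the-fly augmentation
applies a small random rotation/scale/translation identically to both
members; offline left-right flipping doubles a dataset.  Reference
settings for full-scale training: learning rate 1e-4, 10,000 iterations,
batch 2, checkpoints every 15 iterations; all configurable.  Grouped
k-fold splitting (4 folds) partitions by subject, so the left and right
halves of one subject never straddle train and test.

## Implementation

No deep-learning framework is used: the package carries a compact
reverse-mode autodiff engine on NumPy arrays (`siamreg.autodiff`) with
exactly the operators the model needs — convolution (im2col + GEMM for
3x3x3 kernels, FFT for the 7x7x7 first layer), pooling, up-sampling,
zero-padding, separable Gaussian smoothing, finite-difference stencils,
and a trilinear grid sampler differentiable in the displacement field.
Every operator's gradient is validated against central finite differences
in the test suite, and the whole pipeline is finite-difference-checked
end-to-end through the network weights.  Network state is float32;
loss-formula tests run in float64.

Numerical choices: convolutions are same-padded; activations default to
LeakyReLU(0.2) (plain ReLU is available, but a net this small with no
normalization layers can die wholesale under aggressive optimizer steps);
the final layer is zero-initialized; Dice denominators carry `ε = 1e-6`;
the `sqrt` in the gradient-norm regularizer guards its derivative at
zero; label warps are trilinear (soft) in the loss path and
nearest/thresholded for evaluation masks.

## Synthetic data

The generator replaces clinical data with bifurcating-vessel phantoms: a
curved tube of 3.0–4.5 voxel radius (≈ 2–3 mm lumen at the default 0.6 mm
isotropic spacing) that splits into two thinner branches, rendered in two
"modalities" with inverted foreground/background contrast plus
independent Gaussian noise — making intensity similarity useless, as in
the multi-modal clinical condition.  Each phantom carries a binary lumen
label, a bifurcation landmark and two wall points standing in for
plaques.

Mis-alignments are synthesized by warping the moving rendering with a
random elastic field: i.i.d. normal vectors on a coarse control grid
(default spacing 4 voxels), trilinear up-sampling, Gaussian smoothing
(default σ = 2), scaled so the *peak* displacement equals the configured
amplitude (default 3 voxels).  These defaults keep the field's
correlation length above its amplitude, so the deformation is fold-free
and accurately invertible.  The stored ground truth is the field that
aligns moving back onto fixed — the inverse of the applied field,
computed by fixed-point iteration (`u ← −ψ(x+u)`, 15 iterations; residual
< 0.1 voxel at default settings).  The stored moving label is warped with
nearest-neighbour interpolation so it stays crisp binary, like a clinical
annotation.  Moving landmarks are the fixed landmarks transported through
the ground truth, and a centered crop of the moving side reproduces the
cross-scale acquisition regime.

What the phantoms do **not** emulate: MR physics (bias fields, flow
artifacts, partial-volume profiles), anatomical variability beyond a
Y-shaped lumen, imperfect or inter-rater-variable annotations, and
through-plane anisotropy.  Passing the synthetic benchmarks therefore
shows the machinery is correct and trainable, not that clinical-grade
accuracy is reached.

## Scaled-down benchmark sizes

The packaged end-to-end benchmark (tests and `scripts/acceptance.py`)
runs entirely on CPU at deliberately small sizes, chosen as the package's
reference desk-scale experiment: 12 phantom pairs at 48x48x48, 3-voxel
peak deformations, a levels-2 / 8-channel network, 300 Adam iterations at
learning rate 1e-3 with single-pair gradient steps, loss scales
σ = {0,1,2,4} and α = 0.5, 8 training / 4 held-out pairs.  The raised
learning rate and reduced batch are the appropriate re-scaling of the
reference schedule (1e-4 for 10,000 iterations, batch 2) to a 300-step
run; with 1e-4 the network barely leaves its identity initialization in
300 steps.  Under these conditions held-out lumen Dice typically improves
from ≈ 0.85 to ≈ 0.90+ and the label-masked target registration error
drops below the identity-transform baseline.

## Known limitations

* The approximate inverse in the generator leaves a small residual, so
  ground-truth alignment Dice is ≈ 0.95–0.97, not 1.0.
* The smoothness regularizer named in the reference settings is
  ambiguous between first-order gradient and bending energy; all variants
  are provided and none is asserted as "the" intended one.
* Whether anatomical labels are network inputs at inference (as drawn in
  the reference architecture) or loss-only is genuinely open; both modes
  are implemented (`use_label_channels`), labels-as-inputs being the
  default.
* Training at the full clinical scale (10k iterations, 112x64x64 grids)
  is supported by the code but takes hours on CPU; the NumPy engine is
  single-device by design.
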