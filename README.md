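# siamreg

Cross-scale Siamese U-Net deformable registration for multi-sequence
vascular MRI — with a synthetic vessel-phantom benchmark.

## The problem

Multi-sequence MR of the carotid artery (e.g. a contrast-enhanced T1
sequence and a time-of-flight angiogram) shows complementary views of the
same vessel, but the sequences are acquired with different parameters and
often different matrix sizes, and soft tissue moves between scans.
Quantifying plaque change across sequences needs deformable registration,
and two properties make the standard toolkit awkward here:

1. **Cross-scale grids.**  Fixed and moving volumes may have different
   extents per axis (e.g. 112×64×64 vs 96×56×64).  Most learned
   registration models require pre-cropping to one size.
2. **Multi-modal intensities.**  The sequences' intensity distributions
   are unrelated, so intensity similarity (NCC, MI at small scale) is
   unreliable; what *is* reliable are segmentations of the lumen.

`siamreg` implements a registration network for exactly this setting,
aimed at researchers in medical image analysis who want a transparent,
fully tested CPU implementation: two **weight-shared** convolutional
encoders (a Siamese pair) digest the fixed and moving inputs at their
native sizes; the moving branch's feature maps are zero-padded to the
fixed branch's extents at every resolution level; one decoder with skip
connections from both branches emits a dense displacement vector field
(DVF) `u` on the fixed grid, and the moving image is resampled through
`T(x) = x + u(x)`.

Training is **weakly supervised**: the loss never sees intensities, only
anatomical label overlap,

    L = L_GDSC(warp(p, u), g) + α · L_smooth(u),        α = 0.5,

where `L_GDSC` is a multi-scale Dice computed on Gaussian-smoothed copies
of both labels (scale set σ = {0, 1, 2, 4, 8}).  Smoothing bounds the
Dice gradient `2g²/(p+g)²`, which otherwise explodes for the sparse,
initially disjoint labels typical of vessels, and `L_smooth` keeps the
field regular (diffusion / gradient-norm / bending-energy variants).

Everything — including the 3-D convolutional network, reverse-mode
autodiff and Adam — runs on NumPy/SciPy; there is no GPU or
deep-learning-framework dependency.

## Worked example

```python
import numpy as np
import siamreg as sr

# a bifurcating-vessel phantom in two contrast renderings, deformed by a
# random elastic field whose aligning inverse is stored as ground truth
phantom = sr.make_phantom(sr.PhantomConfig(seed=3))
pair = sr.make_deformed_pair(phantom, sr.DeformConfig(amplitude=3.0, seed=4))

ident = sr.identity_dvf(pair.fixed.extents, pair.fixed.spacing)
pre = sr.dsc(sr.warp(pair.moving_label, ident, interp="nearest"), pair.fixed_label)
oracle = sr.dsc(sr.warp(pair.moving_label, pair.gt_dvf, interp="nearest"), pair.fixed_label)
print(f"lumen DSC before registration: {pre:.3f}")
print(f"lumen DSC with ground-truth field: {oracle:.3f}")
print(f"identity TRE over the lumen: {sr.tre(ident, pair.gt_dvf, mask=pair.fixed_label):.3f} mm")
```

prints

```
lumen DSC before registration: 0.844
lumen DSC with ground-truth field: 0.944
identity TRE over the lumen: 0.641 mm
```

The pre-registration Dice of 0.844 is the misalignment the 3-voxel
elastic deformation causes; 0.944 is the ceiling a perfect prediction of
the stored field would reach (the gap to 1.0 is interpolation and
binarization of the thin vessel); 0.641 mm is the mean displacement error
a do-nothing registration leaves over the lumen.  Training the network
closes most of that gap — the scaled-down experiment below reaches a
held-out post-registration Dice of ≈ 0.93 from a 0.84 baseline, with the
masked TRE dropping below the identity baseline.

The same pipeline is scriptable from the shell:

```bash
siamreg simulate --out data/ --pairs 12 --extent 48 --amplitude 3 --seed 1
siamreg train    --config experiment.yaml --manifest data/manifest.yaml --out run/
siamreg register --checkpoint run/ckpt_000300.npz \
                 --fixed data/phantom1000_fixed.nii.gz --moving data/phantom1000_moving.nii.gz \
                 --fixed-label data/phantom1000_fixed_label.nii.gz \
                 --moving-label data/phantom1000_moving_label.nii.gz --out reg/
siamreg evaluate --checkpoint run/ckpt_000300.npz --manifest data/manifest.yaml --out metrics.csv
```

`simulate` can emit cross-scale pairs (`--crop-moving 32,40,48`): the
moving volumes are centered crops with smaller extents, and the network
still returns fields on the full fixed grid — the cross-scale contract
the architecture exists for.

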