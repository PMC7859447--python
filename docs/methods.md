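# Methods

## Problem and model

Deformable volumetric registration seeks, for a fixed volume `I_f` and a
moving volume `I_m`, a dense transform `φ` minimizing

```
L = L_sim(I_f, I_m ∘ φ) + λ L_smooth(φ)
```

`epreg` implements an edge-aware pyramidal network that predicts this
transform in one forward pass and is trained without ground-truth
correspondences:

1. **Dual inputs.** Each volume is paired with its 3D Sobel edge magnitude
   (three 3×3×3 kernels, one per axis; the edge map is the Euclidean norm of
   the three responses). Edges are rescaled to [0,1] and stacked with the
   intensity channel so both enter on comparable scales. A single config
   flag (`use_edges=False`) drops the edge channel, giving the
   intensity-only ablation variant used for comparison.
2. **Shared encoder.** Four stride-2 convolutional blocks (channels
   16/32/32/64 by default) encode both dual inputs with literally shared
   weights, producing feature pyramids `F_1..F_4` and `M_1..M_4` at strides
   2..16. Blocks two and three carry two residual blocks each; the coarsest
   block ends in a 3D atrous spatial pyramid pooling module (parallel
   dilated convolutions at rates 1/2/4, fused by a 1×1×1 convolution).
3. **Affine head.** `F_4‖M_4` pass through a residual block, a 1×1×1
   convolution to 12 channels, and global average pooling, yielding a 3×4
   matrix acting on normalized coordinates (12 degrees of freedom). The
   final convolution is zero-initialized and the identity matrix is added,
   so an untrained network performs an exact identity alignment.
4. **Coarse-to-fine deformable heads.** For levels i = 3, 2, 1 the head
   receives `F_i`, `M_i` warped by the upsampled coarser grid, the
   upsampled coarser feature pair, and the upsampled coarser residual
   field, concatenated channelwise; two residual blocks and a
   zero-initialized 1×1×1 convolution emit the residual displacement
   `φ_i`. Grids compose additively: `G_i = up₂(G_{i+1}) + φ_i`. The final
   warp uses `up₂(G_1)` (the finest predicted level sits at stride 2).

### Coordinate convention

Grids and fields live in normalized `[-1, 1]` coordinates with
align-corners semantics, component `c` addressing array axis `c`. Under
this convention 2× trilinear upsampling of a field requires no magnitude
rescaling, which is what makes the additive grid combination well defined
across levels. Converters to voxel-unit displacements are provided
(`field_to_voxels` / `voxels_to_field`). Sampling outside the domain clamps
to border values; label maps are warped with nearest-neighbor sampling.

## Training objective

* **Similarity** is patch-based local normalized cross-correlation over a
  `v³` window (default v = 9): the negative sum over voxels of
  `cross² / (var_f · var_w + ε)`, computed with separable sliding box sums
  under edge-replicate padding. Note the denominator uses *squared*
  centered sums; the correlation ratio then lies in [0,1] per voxel and the
  loss is invariant to positive affine intensity rescaling of either image.
  `ε = 1e-5` (on [0,1]-normalized intensities) stabilizes locally constant
  windows.
* **Regularizer** is the diffusion penalty `Σ‖∇φ‖²` with forward finite
  differences over interior sites, applied to the *aggregated*
  full-resolution field `φ = Σᵢ up_{2^i}(φ_i)` (the level-4 term is the
  dense affine residual). Default weight λ = 1000. Because the field is
  stored in normalized coordinates, the penalty at 48³ desk scale is mild;
  its units follow the field convention, and a λ sweep test verifies that
  λ → ∞ drives the field's roughness toward zero.
* **Total loss** sums the similarity at all four pyramid levels, comparing
  `down_{2^i}(I_f)` with `down_{2^i}(I_m)` warped by `G_i` (trilinear
  downsampling), plus the weighted regularizer. The full-resolution pair is
  never compared directly — the finest similarity term lives at stride 2 —
  which bounds the attainable alignment fidelity and is visible in the
  recovery experiments below.
* **Optimizer**: Adam, initial learning rate 2e-4 halved every 10 epochs
  (step decay), 300 epochs by default for population training over all
  ordered pairs of distinct volumes. Instance mode fits a single pair from
  zero-initialization with a constant learning rate (3e-3 in the recovery
  experiments; single-pair fitting tolerates and needs far larger steps
  than population training) — it optimizes the identical objective and
  serves as the desk-scale surrogate for population training.

## Differentiation engine

No automatic-differentiation framework is part of the dependency set, so
the package carries a small reverse-mode engine (`epreg.autodiff`)
implementing exactly the primitives the model needs: elementwise
arithmetic, matmul, strided/dilated 3D convolution (im2col with a
transposed-convolution adjoint), trilinear grid sampling (differentiable in
image and grid, border-clamped, with zero grid-gradient at clamped
samples), separable trilinear resizing, and sliding box sums with
edge-replicate padding. Every primitive's gradient is verified against
central finite differences in the test suite, and the full objective's
gradient is checked end-to-end to ≤1e-3 relative error. Network compute
defaults to float32 (the engine avoids silent float64 promotion); oracle
tests run in float64.

Normalization layers normalize per channel over space. With one pair per
step this makes batch and instance normalization coincide; the layer keeps
running statistics for evaluation mode, and `norm` can be set to
`instance`, `batch`, or `none`.

## Synthetic data

The generator stands in for skull-stripped, intensity-normalized brain MRI:
smooth random background texture (Gaussian-filtered noise, σ = 3 voxels)
plus blob-shaped ROIs (thresholded smooth random fields inside random
ellipsoids) with distinct intensities and matching integer labels. Ground
truth transforms combine a random 12-DOF affine (defaults: ≤3° rotation,
≤3% scale deviation, ≤2% translation) with Gaussian-smoothed white-noise
displacement (σ = 8 voxels) rescaled to an exact peak amplitude (default 4
voxels). The moving image is the fixed phantom warped by the known grid, so
recovery error has an exact reference. Everything is a pure function of its
seed.

What the phantoms do **not** emulate: MRI bias fields, Rician noise,
anatomical shape statistics, partial-volume effects, or inter-subject
topology differences. Passing recovery tests therefore demonstrate that the
pipeline optimizes its objective and recovers known smooth deformations at
desk scale — not clinical-grade brain registration accuracy.

## Recovery experiment and problem sizes

The recovery experiment uses 48³ phantoms with 4 ROIs, the deformation
defaults above, a narrow network (encoder channels 4/8/8/16, head width 8),
and 200 instance-optimization iterations, repeated over 3 seeds, with and
without the edge channel. These sizes are the package's desk-scale study
conditions; the default architecture widths (16/32/32/64) remain available
and are exercised by the architecture-contract tests at 64³.

Scores: mean per-ROI Dice before vs after registration, and the residual
misalignment of the recovered transform. Because the moving image is
generated as `I_m = I_f ∘ G_gt`, a perfect registration inverts the ground
truth, so field error is measured as the mean voxel norm of the composed
residual `G_gt(G_pred(p)) − p`; with no registration this equals the mean
ground-truth displacement, which is the natural pre-registration baseline.

At this scale the multi-scale objective — whose finest similarity term is
evaluated at stride 2 with a 9³ window — recovers roughly a third to a half
of the attainable similarity gap before plateauing; a free-form
(network-less) optimization of the same objective plateaus at nearly the
same point, indicating the objective rather than network capacity is the
binding constraint. Dice improves and residual error drops well below the
initial displacement in every seed; edge-aware and intensity-only variants
perform comparably on these phantoms, whose intensity texture is already
informative — the ablation hook reproduces the comparison design, not any
particular effect size.

On trained instances the coarse-to-fine refinement is visible as a
monotone improvement of common-resolution alignment quality from `G_4` to
`G_1` (averaged over seeds). The finest residual fields are, however,
small at this scale: the affine and coarse deformable levels carry most of
the recovered displacement, and the level-1 field does *not* show more
high-spatial-frequency energy than the coarser levels on 32³ instances —
fine-detail refinement of the kind seen at full scale needs more
similarity resolution than the stride-2, 9³-window objective provides
here.

## Numerical and design choices

* Sobel filtering is applied as cross-correlation; the edge magnitude is
  invariant to kernel flipping, so the choice is free and documented.
* Border handling: replicate padding for edge maps and window sums; border
  clamping for sampling. Preprocessing resamples trilinearly to a
  16-divisible target shape (four stride-2 halvings) and min–max normalizes
  to [0,1]; constant volumes map to all zeros.
* Grid "combination" across levels is additive, `up₂(G) + φ`, rather than
  resampling composition `φ ∘ G`.
* Empty-vs-empty Dice is defined as 1 (strict mode raises); Hausdorff is
  the 100th-percentile boundary distance (not HD95) over 6-connectivity
  boundary voxels with exact Euclidean distance transforms, in voxel units.
* Checkpoints store weights, normalization statistics, and the full
  architecture config, so a checkpoint is self-describing.

## Known limitations

* No diffeomorphic integration or inverse-consistency: large predicted
  fields can fold.
* The engine is CPU-only and sized for desk-scale volumes; paper-scale
  training (192³, hundreds of epochs) is out of its intended range.
* Physical voxel spacing is carried through I/O but ignored by the
  registration math; surface distances are reported in voxels.
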