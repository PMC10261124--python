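# Methods

## Problem and approach

Fluorescence microscopy of cleared tissue yields 3D stacks of densely packed,
often touching nuclei.  Semantic segmentation (foreground vs background)
merges touching nuclei into one blob; instance segmentation must assign each
nucleus its own label.  This package splits instances via a per-voxel
**centroid-offset vector field**: every foreground voxel stores the 3D offset
`v(x) = c_k − x` to the centroid `c_k` of its own nucleus `k`, and background
voxels store the zero vector.  Within one convex nucleus each component of
the field decreases along its own axis (slope −1 for the exact field), while
across the interface between two nuclei the component jumps from negative to
positive — so directional derivatives are strongly positive exactly on
inter-nucleus boundaries and negative in interiors.  This sign structure is
what the splitter exploits, and it is why the gradient map takes the *signed*
maximum of the three responses rather than a magnitude (an `abs_gradient`
option exists for comparison).

## Instance splitting

Given a binary mask `M` and a field `V` (ground truth in oracle mode, or the
network's estimate):

1. **Gradient map** `G`: each component `V_a` is filtered with the
   unnormalized 3D Sobel operator whose derivative stencil `[-1, 0, 1]` lies
   along axis `a` and whose smoothing stencil `[1, 2, 1]` lies along the two
   others (reflected boundaries); `G` is the voxelwise signed maximum of the
   three responses.  With unnormalized kernels the interior response of an
   exact field is `−2·16 = −32` and boundary responses are large positive.
2. **Blob map**: `relu(M − [G ≥ T_m])` — foreground with boundary voxels
   carved out.  Any `T_m` between 0 and the smallest boundary response works
   on exact fields; the default `T_m = 16` (half the interior magnitude) also
   tolerates the noise of predicted fields.
3. **Conditional erosion**: each 26-connected blob component is eroded
   repeatedly — first with a coarse structuring element while it holds at
   least `t_c` voxels, then with a fine one while at least `t_f` voxels.
   Components are re-split after every pass and fragments are processed
   independently (an erosion that disconnects a dumbbell yields two seeds); a
   component that would vanish keeps its last nonempty state.  Defaults:
   coarse = 5×5×3 discrete ellipsoid (lateral-heavy, matching the coarser Z
   sampling of confocal stacks), fine = 6-connected 3×3×3 cross, `t_c = 150`,
   `t_f = 40` — roughly 40% and 10% of the typical nucleus volume of the
   synthetic volumes used here (semi-axes 4–8 voxels).  Dataset-tuned presets
   `seg-v1..seg-v5` carry the published per-dataset thresholds.
4. **Marker-controlled watershed** floods from the seeds, restricted to the
   mask.  The elevation surface is the negative Euclidean distance transform
   of the mask (standard marker-controlled practice); an inverted-intensity
   surface or a blend is available, since which surface the original system
   used is not specified.  A foreground component containing no seed is kept
   as one instance (a seed is placed at its interior-most voxel) rather than
   silently discarded.
5. **Small-object removal**: instances under 20 voxels are dropped and labels
   compacted.

## Network and training

The segmentation network is a modified 3D U-Net: per level a conv block
(3×3×3 convolution, batch norm, leaky ReLU 0.1) plus a residual block;
downsampling by stride-2 conv blocks (learnable, instead of pooling);
decoding by 3×3×3 transpose-conv blocks with additively attention-gated skip
concatenations; two heads on the finest features — a 1-channel logistic mask
head (binarized at 0.5) and a 3-channel linear vector head (offsets are
unbounded, so no squashing).  Depth and width are configurable
(`levels=4, base_width=16` default; `levels=3, base_width=8` desk preset).
The exact internals of the attention gate are not numerically specified in
the source system; the additive form (1×1×1 projections of gate and skip,
leaky ReLU, logistic coefficient rescaling the skip) is the standard one.

The loss is `λ_tv·L_TL + λ_f·L_FL + λ_mse·L_MSE` with defaults
`(1, 10, 10)`:

* Tversky loss `1 − TP/(TP + α_fn·FN + α_fp·FP)` with soft counts and
  `α_fn = 0.3, α_fp = 0.7` (penalizing false positives harder), smoothing
  `ε = 1e−6`.  The underlying index is maximal at perfect overlap, so the
  *loss* is one minus the index.
* Focal loss with nucleus-class weight `β = 0.8` and focusing exponent
  `γ = 2`, probabilities clipped at `1e−7`.  Subscript 1 means "nucleus" for
  both target and prediction.
* MSE over all `3P` scalar entries of the vector field.

Training uses Adam at a constant learning rate; the mask target is
`label > 0`, intensities are min-max normalized per volume, and batch-norm
statistics are frozen at evaluation.  The full-scale recipe is 100 epochs at
`lr = 1e−3`; the desk-scale smoke runs (tiny model, 32³ patches, ≤ 50
epochs, `lr = 0.01`) use a higher rate because so few optimizer steps are
taken.  Output heads are initialized for fast early progress: the mask-head
bias starts at −2 (the logit of a ~12% foreground prior), the vector head at
exactly zero (which is also the correct background target), and mask-head
weights are scaled by 0.1.

The network stack is implemented on NumPy with a small reverse-mode autodiff
engine (`nn/autodiff.py`): broadcast arithmetic, logistic/leaky-ReLU/log,
axis reductions, concatenation, and strided 3D convolution plus its adjoint
(im2col + BLAS).  All convolution gradients are verified against central
differences in the test suite.

## Synthetic volumes

Nuclei are modeled as 3D ellipsoids with semi-axes uniform on
`[a_min, a_max]` per axis, Euler angles uniform on `[0, 2π)` (X-then-Y-then-Z
composition), and centers uniform over the volume.  A voxel belongs to the
ellipsoid when its body-frame coordinates satisfy
`(x'/a_x)² + (y'/a_y)² + (z'/a_z)² < 1` (strict).  Rotation is about the
ellipsoid's own center; the printed transform of the source system composes
rotation after translation (about the global origin), but uniform placement
statistics are the property the generator must deliver, so
rotate-about-center was chosen.  Placement is sequential: a candidate is
accepted iff at most `t_ov` of its voxels are already occupied; contested
voxels stay with the earlier label; after 100 rejections a nucleus is
skipped with a warning (prevents nontermination at high density).  Named
presets `v1..v4` carry the published per-dataset parameters
(`a ∈ [4,8]..[10,14]`, `t_ov ∈ 5..200`, `N ∈ 70..560`, 128³).

Elastic deformation: a coarse `d×d×d×3` grid of i.i.d. `N(0, σ²)`
displacements is interpolated to the full grid by an interpolating cubic
spline (anchors equally spaced across each axis; constants are reproduced
exactly, and `σ = 0` gives the identity).  Warping is implemented backward
(output voxel reads the label at `x − smooth(x)`, nearest-neighbor,
out-of-bounds → background): the forward-shift description in the source
leaves holes in label images, and at the deformation magnitudes used the two
are equivalent.  A label split into several components by warping keeps its
single identity.

**Rendering** turns labels into plausible intensities: per-instance
intensity jitter (uniform ±15% around a 0.7 full-scale mean), anisotropic
Gaussian blur (σ_xy = 1, σ_z = 2 voxels — axial elongation), constant
background 0.08, Gaussian (default, σ = 0.03) or Poisson-Gaussian noise,
clipping and quantization to 8 or 16 bits.  This renderer is a classical
stand-in producing the statistical structure (blurred blobs, axial
anisotropy, sensor noise) needed to exercise training and splitting at desk
scale; it does not reproduce the texture realism of a learned image-to-image
translation, so passing tests demonstrate the machinery works on
blob-structured data, not that the network trained here transfers to real
microscopy.

## Tiled inference

Volumes larger than the network input are processed with K-windows at stride
K/2, each padded by K/4 per border (unclamped padded edge `1.5K`,
out-of-volume voxels by symmetric reflection), keeping only each window's
centered K/2 interior.  The centered-interior rule leaves the outer K/4
shell and trailing remainders uncovered; boundary interiors are extended to
the volume edge and interior boundaries placed at midpoints between window
centers — the unique coverage-preserving completion that reduces to the
centered rule on regular tilings.  Any predictor whose output at a voxel
depends only on inputs within Chebyshev radius K/4 is tiled exactly
(verified bit-for-bit in the tests).  Instance splitting always runs once,
globally, on the stitched mask and field, so no nucleus can be split by a
tile seam.

## Evaluation

Instances are matched one-to-one by IoU, greedily in descending IoU (an
optimal-assignment mode exists; the two agree on all small fixtures, which
the suite checks exhaustively).  Per threshold `t` in `{0.25..0.45}` (or
`{0.5..0.75}` for sparse data): precision, recall, F1 and
`AP_t = TP/(TP+FP+FN)`; their means over the set give mP/mR/mF1/mAP on the
0–100 scale.  Label-free instance maps carry no confidence ranking, so a
precision-recall *curve* is not defined; `AP_t` above is the convention of
the 3D nuclei-segmentation literature, and a curve-based AP is available
when per-instance scores are supplied.  The Aggregated Jaccard Index
accumulates, per ground-truth instance, the intersection and union with its
best not-yet-used prediction, and adds unmatched predicted voxels to the
denominator — the standard form, which is bounded in [0, 1] (the printed
formula in the source transposes numerator and denominator, which would
exceed 1).  Empty-vs-empty scores 100 (perfect vacuous agreement); empty
prediction against nonempty truth scores 0.

## Numerical choices and conventions

* Axis order `(X, Y, Z)`, 0-based voxel coordinates; TIFF page = Z, row = Y,
  column = X.  Centroids are kept sub-voxel (rounding would inject
  quantization ridges into the gradient map).
* Vector fields are stored float32; offsets are bounded by the volume
  diagonal, so the identity `voxel + vector = centroid` holds to ~1e−4
  voxels at 64³.
* Boundary handling everywhere (Sobel, tiling pads, renderer blur) is
  symmetric reflection with edge repeat.
* Watershed tie-breaks follow the flooding order of the underlying
  implementation; markers outside the mask are clipped with a warning.
* Determinism: every stochastic step consumes a caller-supplied seeded
  generator; identical config + seed reproduces bit-identical integer
  artifacts.  Training is additionally deterministic per seed on a single
  BLAS thread.

## Problem sizes used by the test and acceptance runs

Oracle recovery uses 96³ volumes with 40 nuclei (semi-axes 4–8, overlap
budget 10, deformation d=5, σ=2); vector-field checks use 64³ volumes with
up to 40 nuclei; tiling equivalence uses 256×256×64 with K=128; training
smoke uses the tiny 3-level / width-8 model on 32³ volumes with 6 nuclei
each (one-patch overfit for 50 epochs; 8-volume generalization for 30
epochs).  These sizes exercise every code path end to end on one CPU.

## Known limitations

* The renderer is classical; no learned texture synthesis, no depth-dependent
  attenuation, no spectral bleed-through.
* Nuclei are deformed ellipsoids; multi-lobed or branching shapes and
  spatially clustered placement priors are out of scope.
* Distance metrics are isotropic in voxel units; anisotropic voxel sizes are
  carried as metadata but not used by the watershed elevation.
* The NumPy network trains desk-scale models in minutes but is not suited to
  full-resolution GPU-scale training.
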