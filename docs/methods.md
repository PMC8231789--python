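# Methods

## Problem

After breast-conserving surgery, radiotherapy must target the tumor bed —
the tissue that formerly surrounded the resected tumor. Deformable
registration of the pre-surgery CT onto the post-surgery CT can transfer
the segmented tumor into the post-surgery frame, but the tumor exists only
in the pre-surgery image: this *missing-data* situation breaks the
point-to-point correspondence assumption of standard registration. A
similarity term alone cannot decide what should happen inside the tumor,
and enforcing diffeomorphic (fold-free, invertible) deformations actively
prevents the correct answer, which is that the tumor region collapses to
(near) zero volume.

`tumorbedreg` implements a registration family that encodes the prior
"the tumor is fully resected" as a differentiable loss term, in two
regimes: per-case instance optimization of a dense displacement field,
and an amortized multilevel U-Net that predicts the field in a single
forward pass and needs the tumor segmentation only during training.

## Model

All stages minimize variants of

```
J(M, F, u) = -NCC_w(M ∘ u, F) + α R(u)
```

where `M` is the moving (pre-surgery) image, `F` the fixed (post-surgery)
image, and `u` a dense displacement field on the fixed grid that maps into
the moving domain (backward warping: the warped image is
`(M ∘ u)(x) = M(x + u(x))`, trilinear interpolation, border-clamped
sampling).

- **Similarity.** `NCC_w` is the local normalized cross-correlation:
  windowed Pearson correlation over all fully-contained `w`-cubed
  voxel-centered windows, averaged. Windows where the product of the two
  standard deviations falls below 1e-5 contribute zero (this suppresses
  divisions by near-zero variance over homogeneous background). Window
  size is 7 voxels for the affine stage and 5 for the nonrigid stages.
- **Regularization.** `R(u)` is the diffusive regularizer: the mean of
  squared forward-difference spatial gradients over all components and
  axes. The weight is α = 700 under the *normalized field units*
  convention: before evaluating `R`, each displacement component is
  rescaled by `2 / N_c` (voxels → fraction of the half-extent), the unit
  system in which learning-based registration frameworks conventionally
  express fields. On voxel-unit gradients the same α would overwhelm the
  similarity term by roughly two orders of magnitude at any realistic
  deformation amplitude, so the normalized convention is the only one
  under which this weight produces the documented behavior. The
  `diffusive_regularizer` function itself is unit-agnostic; the
  conversion happens inside the composite objectives and can be disabled
  via `ObjectiveConfig.normalized_field_units`.
- **Volume penalty.** `V(Ms ∘ u) / V(Ms)` — the tumor volume ratio (TVR):
  the warped tumor mask's (fractional) volume over its original volume.
  Warping the mask trilinearly keeps the term differentiable. Added with
  unit weight at every resolution level in the semi-supervised variants.
  Driving it to zero encodes complete resection; at evaluation time the
  same computation is the TVR metric.
- **Inverse consistency.** For the symmetric variant both pair orderings
  are forwarded and `IC(u_fm ∘ u_mf)` — the mean squared magnitude of the
  composed forward/backward fields, in the same normalized units — is
  added with unit weight. This discourages folding without hard
  diffeomorphism constraints.

## Pipeline

1. **Preprocessing** — per-volume min-max intensity normalization to
   [0, 1], trilinear resampling to 2 mm isotropic spacing (Gaussian
   anti-aliasing, σ = 0.5 × the downsampling ratio in voxels, applied
   only on axes that are actually downsampled), zero-padding at the
   high-index side to a common shape (origins unchanged, so world
   coordinates and landmarks are unaffected).
2. **Affine stage** — instance optimization of a 3×3 matrix plus
   translation acting about the volume center in world coordinates, on an
   8/4 mm two-level pyramid, Adam with constant learning rate 0.001. The
   translation parameter is internally expressed in half-extent units so
   that one Adam step moves rotation-like and translation-like parameters
   by comparable fractions of the volume; with millimeter
   parameterization the published learning rate would advance the
   translation by only ~0.001 mm per step. Stopping: at most 500
   iterations per level, early stop after 50 iterations without an NCC
   improvement of 1e-5. The candidate transforms (identity and each
   level's best) are re-scored at the finest level and the best is
   returned, so the result is never worse than no alignment.
3. **Nonrigid stage**, one of:
   - *Instance optimization* (`ARRNI`/`ARNIP`): the field is optimized
     directly per voxel (no spline parameterization; smoothness comes
     only from the diffusive term) over an 8/4/2 mm pyramid, coarse to
     fine, each level warm-started by trilinearly upsampling the previous
     level's best field (voxel-unit magnitudes rescaled by the grid
     ratio). Adam, default learning rate 0.02 in voxel units — chosen so
     a normalized Adam step traverses about one voxel per 50 iterations,
     matching the per-level iteration budget; the value is exposed in
     config. Same stopping rule as the affine stage, with best-loss
     fields retained per level.
   - *Learned* (`ARDN*`): a channel-first 3-D U-Net takes the
     concatenated source/target pair at every pyramid level (injected at
     the matching encoder depth) and emits one displacement field per
     level from the decoder, finest last. Blocks are two 3×3×3
     convolutions with group normalization (8 groups, or the channel
     count if smaller — group rather than batch normalization because the
     batch size is 1) and leaky ReLU (slope 0.01); downsampling is 2×
     average pooling, decoder upsampling is fixed trilinear interpolation
     (no transposed convolutions, avoiding checkerboard artifacts);
     output heads are zero-initialized 3-channel convolutions so the
     untrained network predicts the identity. The default encoder plan is
     16/32/64 channels; the phantom studies use 4/8/16 (see below). A
     `single_level` variant consumes only the finest pair and emits one
     field (the plain U-Net baseline). Training: Adam, initial learning
     rate 0.002 with exponential decay 0.97 per epoch, loss summed over
     pyramid levels, optional augmentation by small joint affine
     transforms (±5°, ±5 mm, ±5% scale) and per-volume intensity
     jitter. The tumor mask enters only the training loss — inference
     takes no mask in any mode.
4. **Composition and evaluation** — the affine transform is converted to
   a displacement field and composed with the nonrigid field for
   end-to-end landmark mapping; TRE is the Euclidean distance in mm
   between fixed-space landmarks mapped through the composite field and
   their moving-space partners. (The backward-warping convention makes
   this mathematically equivalent to comparing warped moving landmarks
   against fixed ones, without numerically inverting the field.)

No deep-learning framework is used: a compact reverse-mode automatic
differentiation engine over numpy arrays (`tumorbedreg.autodiff`) supplies
the differentiable warping, windowed statistics, convolutions and the
Adam optimizer for both the instance-optimization loops and network
training. Its gradients are verified against central differences in the
test suite.

## Synthetic phantoms

The clinical dataset (30 pre/post-surgery CT pairs) is not publicly
available, so a phantom generator emulates its statistical structure at
desk scale:

- a smooth soft-tissue body (ellipsoid torso + spherical breast-like
  protrusion) with a smooth random intensity texture (Gaussian-filtered
  noise, amplitude 0.15, correlation length 6 mm) on background 0;
- a spherical tumor (radius 6–10 mm) inside the breast region, recorded
  as a binary mask, with intensity contrast +0.15 over tissue — mild on
  purpose: in CT, soft tissues are hardly distinguishable, and with a
  salient tumor plain unsupervised registration could "segment away" the
  tumor from intensity alone, which the clinical results show it cannot;
- a smooth ground-truth deformation: the sum of 3–8 Gaussian displacement
  bumps (amplitude 2–6 mm, kernel width ~18 mm), redrawn until the
  analytic Jacobian exceeds 0.1 everywhere (fold-free by construction);
- the post-surgery volume is the *tumor-free* tissue warped through the
  ground truth (the cavity closes over — resection is modeled as
  intensity fill, not a hole) plus Gaussian noise (σ = 0.02) and an
  optional hypointense scar streak;
- landmarks sit at texture extrema away from the tumor and the border,
  paired exactly through the analytic deformation (fixed-point
  inversion), mirroring manually annotated anatomical landmarks.

What the phantoms do not model: CT physics (HU calibration, beam
hardening, partial volume), biomechanically realistic breast deformation,
and inter-rater landmark noise. Passing the phantom studies therefore
demonstrates the correctness and the qualitative behavior of the method
(penalty collapses the tumor, similarity alone does not; inverse
consistency preserves invertibility), not clinical-grade accuracy.

## Phantom study conditions

The experiments the tests and `scripts/acceptance.py` run, sized for a
single CPU core:

- loss-term oracles and gradient checks on ≤7³ fixtures;
- affine recovery of a known 5° + (4, −4, 2) mm transform on a 48³
  phantom;
- instance-optimization contrast on five 32³ resection phantoms
  (150 iterations per level, patience 30);
- learned-registration contrast: eight 32³ phantom pairs, 80/20
  train/validation split, 50 epochs, encoder channels 4/8/16 — a
  deliberately compact plan; the task (predict a smooth field and expel
  a single bright blob) saturates at this capacity, and metrics are
  reported on the held-out validation pairs;
- the same training repeated in plain unsupervised and in symmetric
  (inverse-consistency) mode for the invertibility comparison.

Typical behavior at these conditions: instance optimization reduces mean
landmark error from ~5–8 mm to ~1–1.5 mm; with the penalty the TVR drops
below 0.05 while without it it stays above 0.5; the volume-penalty
network reaches validation TVR < 0.2 (plain unsupervised stays near 1)
at a landmark-error cost below 1 mm; symmetric training keeps the
Jacobian positive everywhere while penalty-only training folds inside
the tumor region — the phantom analog of the clinical finding.

## Numerical choices and edge cases

- Out-of-bounds sampling clamps to the border value; zeros would create
  spurious NCC gradients at the body outline.
- Fields are stored in voxel units of their own grid and converted only
  at level changes and for mm reporting.
- Constant (degenerate) inputs: intensity normalization maps constant
  volumes to zeros; affine registration returns identity with a warning.
- NCC windows with vanishing variance contribute zero (ε = 1e-5 on the
  standard-deviation product).
- The TRE uses the Euclidean distance (with square root); reported
  magnitudes in mm imply it even where the windowed-sum notation omits
  the root.
- Landmarks mapped outside the field extent are excluded with a warning.
- The Jacobian determinant uses central differences in the interior and
  one-sided differences at borders, in voxel units.
- Network grids must be divisible by 2 per pooling level; the 2 mm
  preprocessing of 32³/48³ phantoms satisfies this by construction.
- Training is bit-for-bit reproducible given the seed; all randomness
  flows through explicitly seeded generators.

## Known limitations

- The instance-optimization learning rate and the stopping rules are not
  derivable from published material; they are package defaults exposed in
  config.
- Trilinear mask warping can alter tumor topology for highly irregular
  shapes; the phantom tumors are regular spheres, where this is benign.
- The exact convolution counts/kernel plan of the original network are
  not recoverable; the architecture here satisfies the stated constraints
  (per-level inputs/outputs, group norm, leaky activations, trilinear
  upsampling) and is otherwise this package's design.
- Scar modeling is a generator flag only; no scar-aware loss is
  implemented.
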