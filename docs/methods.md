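# Methods note

## Model

### Pose and transforms
A rigid pose is parameterized as three extrinsic Euler rotations applied in
x→y→z order (`R = Rz(γ) · Ry(β) · Rx(α)`) plus a translation, acting about
a configurable center `c`: `T(p) = R (p − c) + c + t`. Internally angles
are radians; every file and CLI boundary uses degrees and millimetres.
Matrix→pose recovery uses `β = asin(−R[2,0])`; at the gimbal-lock
singularity (|cos β| ≈ 0) only `α ∓ γ` is determined and the `γ = 0`
branch is returned, which re-synthesizes the same matrix. Rotation blocks
are validated to be orthonormal with determinant +1 (tolerance 1e-6).

### Volumes and sampling
Volumes store voxels in (x, y, z) axis order with
`world = origin + index · spacing` and voxel-center addressing; only
axis-aligned (diagonal-direction) orientations are supported by the I/O
layer (NIfTI via nibabel, MetaImage via SimpleITK, DICOM series via
pydicom, slices sorted by z position). Trilinear interpolation is
`scipy.ndimage.map_coordinates(order=1)` with constant fill outside the
grid; rigid resampling pulls back the moving volume through the inverse
transform onto the fixed grid and can return the in-bounds overlap mask.

### Projector
The DRR renderer uses a pinhole model: the source sits at
`iso − sid · ex`, the detector plane at `iso + (sdd − sid) · ex`
(defaults: source–isocenter 1000 mm, source–detector 1500 mm). Each
source-to-pixel ray is clipped to the volume's bounding box (slab test)
and integrated by midpoint quadrature with `n = ceil(L / step)` uniform
steps (default step = half the smallest voxel spacing). The image is the
raw line integral — linear in volume intensity; no Beer–Lambert
exponentiation — which makes analytic oracles (cube chord length,
linearity, magnification) exact. A second view is produced by rotating
the camera with an inter-view transform (90° for orthogonal AP/LAT;
any separation in (0°, 180°) is supported). Contrast variants min-max
normalize to [0, 1] and apply gamma 0.5 / 1.0 / 2.0 (low / mid / high).
Because normalization pins the endpoints, the two extreme gammas differ
only in midtone rendition; order of intensities is always preserved.

### Registration
The metric is the mean squared voxel difference over the pull-back
overlap region: the fixed grid is mapped through `T⁻¹`, the moving volume
sampled trilinearly there, and out-of-bounds points excluded from the
mean (N is the overlap count). The analytic gradient applies the chain
rule through the pull-back, with the image gradient of the moving volume
taken by central differences (`np.gradient`) on its own grid and sampled
at the pull-back points:

- `∂MSE/∂t = −(2/N) R Σ r ∇J`,
- `∂MSE/∂θⱼ = (2/N) Σ r · (∇J · (dRⱼᵀ (p − c − t)))`.

This is *not* the exact derivative of the trilinearly interpolated
objective: on band-limited textures the componentwise mismatch against
finite differences can exceed a few percent for rotation terms
(lever-arm amplification), although the direction agrees closely. On
affine intensity fields — where both the interpolation and the central
differences are exact — the gradient matches finite differences to
~1e-9 relative error, which is the oracle instance used by the
acceptance suite; a separate unit test pins the directional agreement on
textures.

The optimizer is normalized steepest descent in a scaled parameter space
(rotations weighted by a 50 mm equivalence radius) with backtracking line
search; a step is accepted only on strict MSE decrease, so accepted
iterates descend monotonically within each pyramid level (coarse-to-fine
factors 4/2/1 by default). When the line search fails, a compass probe
tries ± each scaled coordinate at fixed steps (2.0 / 0.5 / 0.125 mm);
acceptance of the best strict improvement preserves monotonicity, and
failure of all probes doubles as a convergence certificate. A final
full-resolution evaluation falls back to the initial pose if the pyramid
excursion ended worse than it began.

## Synthetic benchmark generator

The phantom is a triaxial ellipsoidal shell (semi-axes
0.62/0.80/0.86 of the half-extent, ±3 % seeded jitter; 6 mm thick) of
1200 HU around 40 HU tissue in −1000 HU air, with two 3 mm low-density
canals (30 HU) through the shell base as clinically-inspired targets, ten
seeded shell landmarks, and additive Gaussian HU noise (σ = 15).
Ground-truth poses are drawn uniformly from ±10° / ±20 mm. The simulated
reconstructor resamples the bone volume at the hidden pose and degrades
it (Gaussian blur in voxels, optional intensity scale, additive noise as
a fraction of the dynamic range); degradation scales like
`1 / sin(separation angle)`, encoding the loss of depth information as
the two views close on each other. With blur 0 and noise 0 the target is
a bit-exact clean transformed copy.

### Realism limits
- The phantom is a smooth two-material shell, far simpler than a skull:
  no trabecular texture, sinuses, teeth, or soft-tissue gradients; the
  registration problem it poses is easier than clinical data.
- The shell *must* be triaxial: a near-spherical phantom makes rotations
  unidentifiable regardless of optimizer quality (this is asserted as a
  structural test, not tuned post hoc).
- The pseudo-reconstruction noise model (blur + white noise) does not
  reproduce the structured artifacts of learned reconstruction networks;
  the `1/sin` angle scaling encodes the direction of the degradation
  trend, not a measured magnitude.
- DRRs integrate raw HU (which can be negative in air) rather than
  calibrated attenuation; contrast variants are display transforms only.

## Evaluation conventions
- mTRE = mean Euclidean landmark displacement between estimated and
  ground-truth transforms (12 landmarks here).
- GFR counts cases with mTRE **strictly** greater than 3 mm; a case at
  exactly 3.0 mm is a success.
- Aggregates are mean ± *population* (divisor N) standard deviation: the
  convention under which the bundled ten-case reference per-method values
  reproduce their printed aggregates. Those published lists are shipped
  as data (`REFERENCE_MTRE_MM`) and re-aggregated through the package's
  own code at test time; for one refined comparison method the printed
  failure rate is inconsistent with its own per-case values (the
  arithmetic gives 70 %, the printed table 30 % — likely a success rate),
  so that single value is not asserted in either direction.

## Numerical choices
- Integration step defaults to half the smallest voxel spacing
  (midpoint rule; halving the step changes the 64 mm cube line integral
  by less than 1 mm·intensity in the bundled test).
- Interpolation is trilinear everywhere (order-1), matching the metric's
  differentiability assumptions and an independent nested-loop oracle to
  1e-9.
- Downsampling for the pyramid is decimation after box smoothing;
  per-level Gaussian pre-smoothing exists as an option but defaults off
  (it biases the optimum on discrete grids, observed as a ~0.3° rotation
  offset, and slows fine-level convergence).
- All randomness flows from integer seeds through `numpy.random.
  default_rng`; every generator function is deterministic per seed, and
  derived seeds stay below 2^31.

## Limitations
- Only diagonal direction matrices are supported in volume I/O; oblique
  acquisitions must be resampled upstream.
- The optimizer is a local method: with the default identity
  initialization its capture range is bounded by the overlap and the
  metric's basin; poses far beyond the ±10° / ±20 mm augmentation range,
  or small fields of view (e.g. 32-voxel volumes with ±20 mm shifts), can
  diverge.
- The registration assumes mono-modal intensities (MSE); an intensity
  scale between moving and fixed degrades accuracy unless the optional
  z-score normalization is enabled.
- Runtime targets desk-scale CPU execution (seconds per 64-voxel case),
  not the millisecond regimes of GPU ray casters.
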