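# orthoreg

Rigid 2-D/3-D registration utilities for orthogonal-view C-arm guidance,
built around a two-stage idea: first turn a biplanar radiograph pair into a
rough 3-D volume (a *pluggable* reconstruction step — here simulated by a
noise model), then recover the patient pose by classic 3-D/3-D rigid
registration of the pre-operative CT against that volume. The package
provides every piece of that loop in plain NumPy/SciPy:

- **Geometry** — 6-DoF poses (extrinsic x→y→z Euler angles + translation),
  homogeneous rigid transforms, rotation about an arbitrary center,
  pose↔matrix round trips with a deterministic gimbal-lock branch.
- **Volumes** — axis-ordered (x, y, z) voxel model with world coordinates,
  NIfTI / MetaImage / DICOM-series I/O, trilinear sampling, rigid
  resampling with overlap masks.
- **Preprocessing** — scanner-bed removal by per-slice max-ellipse
  detection and elliptical-cylinder cropping (120 % expansion), followed by
  bone thresholding at 100 HU.
- **Projector** — perspective (pinhole) DRR ray caster with midpoint
  quadrature, biplanar AP/LAT rendering at a configurable separation
  angle, contrast (gamma) variants, and the reconstruction / projection /
  combined supervision losses used to train reconstruction networks.
- **Registration** — overlap-masked mean-squared-error metric, analytic
  pose gradient, multi-resolution normalized gradient descent with
  backtracking line search and a compass-probe stall recovery.
- **Benchmark & evaluation** — a seeded triaxial skull phantom with 12
  landmarks (two low-density canal targets + 10 shell points), pose
  augmentation sampling (±10°, ±20 mm), a degradation model for the
  simulated reconstructor, mean target registration error (mTRE), gross
  failure rate (GFR, failure = mTRE > 3 mm), and per-DoF error reports.

## Worked example

Register a bone-thresholded phantom against a blurred, noisy simulated
reconstruction of itself at a hidden pose:

```python
import numpy as np
from orthoreg import (make_phantom, threshold_bone, sample_pose,
                      pseudo_reconstruct, register, pose_to_matrix, mtre)

# 1. synthetic head phantom (64^3, 2 mm voxels) with 12 landmarks
volume, landmarks = make_phantom(seed=7)
bone = threshold_bone(volume)           # keep HU >= 100

# 2. hidden ground-truth pose and a simulated degraded reconstruction
pose_gt = sample_pose(seed=42)          # +/-10 deg, +/-20 mm
target = pseudo_reconstruct(bone, pose_gt, blur_sigma=1.0,
                            noise_frac=0.05, seed=7)

# 3. register bone -> target (multi-resolution MSE gradient descent)
result = register(bone, target)

err = np.abs(result.pose.as_array() - pose_gt.as_array())
tre = mtre(pose_to_matrix(result.pose, bone.center),
           pose_to_matrix(pose_gt, bone.center), landmarks)
print("converged:", result.converged, "| iterations:", result.iterations)
print("rotation error (deg):", np.round(np.degrees(err[:3]), 3))
print("translation error (mm):", np.round(err[3:], 3))
print(f"mTRE over 12 landmarks: {tre:.3f} mm")
```

Output (bit-reproducible on one CPU):

```text
converged: True | iterations: 127
rotation error (deg): [0.805 0.448 0.318]
translation error (mm): [0.007 0.02  0.04 ]
mTRE over 12 landmarks: 0.568 mm
```

## Command line

The `orthoreg` entry point wraps the same building blocks:

```bash
orthoreg phantom --seed 3 --out phantom.nii.gz
orthoreg preprocess --in ct.nii.gz --out bone.nii.gz --report report.json
orthoreg render --ct bone.nii.gz --out drr/          # AP + LAT PNGs
orthoreg register --moving bone.nii.gz --fixed target.nii.gz --out pose.json
orthoreg evaluate --results results.json --out report.json
orthoreg e2e --n 10 --seed 0 --out run/              # full synthetic loop
```

## Reproduction

```bash
python -m pytest -q tests/                 # full suite incl. acceptance
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The test suite and the acceptance script compute everything at runtime:
published ten-case per-method mTRE lists are re-aggregated through the
package's own metric code (mean/std/GFR), pose recovery is measured on 20
seeded phantom registrations against clean and degraded targets, the
analytic gradient is checked against central finite differences, the ray
caster against analytic chord lengths, and the view-separation sweep
(90°/60°/30°) against the expected degradation trend. See
`docs/methods.md` for the model, the numerical choices, and the known
limits of the synthetic generator.
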