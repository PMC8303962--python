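"""Synthetic CT-DRR benchmark construction.

Real head-CT archives are optional inputs to this toolkit; the benchmark
is self-sufficient through a synthetic head phantom.  The phantom is an
ellipsoidal high-HU shell (skull, ~1200 HU) filled with soft tissue
(~40 HU) in air, with two small low-HU canals through the shell base whose
centres stand in for the foramen ovale targets, plus ten further landmarks
sampled on the shell — giving the twelve evaluation landmarks.  Mild
seeded shape jitter and Gaussian HU noise keep cases distinct while every
quantity stays reproducible from its integer seed.

A benchmark case consists of AP and LAT DRRs rendered at a hidden
ground-truth pose drawn from the augmentation range (+/-10 degrees,
+/-20 mm per axis), the landmark set, and provenance metadata.  The
``pseudo_reconstruct`` simulator emulates the output of a learned
biplanar-to-CT reconstructor: the ground-truth anatomy at the unknown
pose, degraded by Gaussian blur, a multiplicative intensity perturbation
and additive noise, so the 3-D/3-D registration stage is testable
end-to-end without training any network.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import LandmarkSet, Pose6DoF, lat_view_transform, pose_to_matrix
from .projector import DRRImage, ProjectionGeometry, contrast_adjust, render_biplanar
from .volume import Volume, resample_rigid

__all__ = ["BenchmarkCase", "make_phantom", "sample_pose", "extreme_pose",
           "generate_case", "pseudo_reconstruct", "reconstruction_degradation",
           "build_dataset"]

SHELL_HU = 1200.0
TISSUE_HU = 40.0
AIR_HU = -1000.0
CANAL_HU = 30.0
CANAL_RADIUS_MM = 3.0
SHELL_THICKNESS_MM = 6.0
HU_NOISE_SD = 15.0


@dataclass
class BenchmarkCase:
    """One registration test case: biplanar DRRs + hidden ground truth."""

    case_id: str
    ap: DRRImage
    lat: DRRImage
    pose_gt: Pose6DoF
    angle_deg: float
    contrast: str
    landmarks: LandmarkSet
    seed: int
    meta: dict = field(default_factory=dict)


def make_phantom(seed: int = 0, shape=(64, 64, 64), spacing=(2.0, 2.0, 2.0)):
    """Build the synthetic head phantom and its twelve landmarks.

    Returns ``(volume, landmarks)``; the volume is centred on the world
    origin.  Landmarks 'fo_left'/'fo_right' are the centres of the two
    low-HU canals through the shell base; ten more lie on the shell.
    Deterministic per seed.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 32 for s in shape):
        raise ValueError(f"phantom shape must be at least 32 per axis, got {shape}")
    spacing = np.asarray(spacing, dtype=float)
    rng = np.random.default_rng(seed)

    origin = -(np.array(shape) - 1) / 2.0 * spacing
    x = origin[0] + np.arange(shape[0]) * spacing[0]
    y = origin[1] + np.arange(shape[1]) * spacing[1]
    z = origin[2] + np.arange(shape[2]) * spacing[2]
    xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")

    half_extent = (np.array(shape) - 1) / 2.0 * spacing
    # triaxial like a skull (narrow left-right, long front-back, tall),
    # with margin for pose shifts
    base_axes = np.array([0.62, 0.80, 0.86]) * half_extent
    axes = base_axes * (1.0 + rng.uniform(-0.03, 0.03, size=3))
    inner = axes - SHELL_THICKNESS_MM

    r_out = (xx / axes[0]) ** 2 + (yy / axes[1]) ** 2 + (zz / axes[2]) ** 2
    r_in = (xx / inner[0]) ** 2 + (yy / inner[1]) ** 2 + (zz / inner[2]) ** 2
    shell = (r_out <= 1.0) & (r_in >= 1.0)
    interior = r_in < 1.0

    vox = np.full(shape, AIR_HU)
    vox[interior] = TISSUE_HU
    vox[shell] = SHELL_HU

    # two low-HU canals through the shell base (z < 0): foramen ovale stand-ins
    names, coords = [], []
    for tag, sx in (("fo_left", -1.0), ("fo_right", 1.0)):
        cx, cy = sx * 0.40 * axes[0], 0.10 * axes[1]
        cyl = ((xx - cx) ** 2 + (yy - cy) ** 2 <= CANAL_RADIUS_MM ** 2)
        region = cyl & shell & (zz < 0)
        if not np.any(region):
            raise RuntimeError("phantom canal did not intersect the shell")
        vox[region] = CANAL_HU
        coords.append([xx[region].mean(), yy[region].mean(), zz[region].mean()])
        names.append(tag)

    # ten extra landmarks on the remaining shell
    shell_after = vox == SHELL_HU
    pts = np.argwhere(shell_after)
    pick = rng.choice(len(pts), size=10, replace=False)
    for i, p in enumerate(pts[pick]):
        coords.append(list(origin + p * spacing))
        names.append(f"shell_{i}")

    vox = vox + rng.normal(0.0, HU_NOISE_SD, size=shape)
    return (Volume(vox, spacing, origin),
            LandmarkSet(tuple(names), np.array(coords)))


def sample_pose(seed: int, rot_range_deg: float = 10.0,
                trans_range_mm: float = 20.0) -> Pose6DoF:
    """Draw a pose uniformly from the augmentation range: each angle in
    (-rot_range, +rot_range) degrees, each translation in
    (-trans_range, +trans_range) mm.  Reproducible per seed."""
    if rot_range_deg <= 0 or trans_range_mm <= 0:
        raise ValueError("sampling ranges must be positive")
    rng = np.random.default_rng(seed)
    ang = np.radians(rng.uniform(-rot_range_deg, rot_range_deg, size=3))
    tr = rng.uniform(-trans_range_mm, trans_range_mm, size=3)
    return Pose6DoF(*ang, *tr)


def extreme_pose(signs=(1, 1, 1, 1, 1, 1), rot_deg: float = 10.0,
                 trans_mm: float = 20.0) -> Pose6DoF:
    """The extreme corner of the augmentation range: |angles| = 10 degrees
    and |translations| = 20 mm with the given sign pattern (how held-out
    test radiographs are posed)."""
    s = np.sign(np.asarray(signs, dtype=float).reshape(6))
    if np.any(s == 0):
        raise ValueError("signs must be +/-1, got a zero")
    return Pose6DoF(*(np.radians(rot_deg) * s[:3]), *(trans_mm * s[3:]))


def default_benchmark_geometry(detector=(128, 128), pixel_mm=2.0,
                               angle_deg: float = 90.0):
    """AP/LAT geometry pair used by the synthetic benchmark (desk scale)."""
    geom_ap = ProjectionGeometry(detector_shape=tuple(detector),
                                 pixel_spacing=(pixel_mm, pixel_mm),
                                 view_tag="AP")
    geom_lat = replace(geom_ap, view=lat_view_transform(angle_deg),
                       view_tag="LAT")
    return geom_ap, geom_lat


def generate_case(ct: Volume, landmarks: LandmarkSet, pose: Pose6DoF,
                  angle_deg: float = 90.0, contrast: str = "mid",
                  geometry: ProjectionGeometry | None = None,
                  seed: int = 0, case_id: str | None = None) -> BenchmarkCase:
    """Render one benchmark case: biplanar DRRs of the (preprocessed) CT at
    ``pose`` with the views separated by ``angle_deg``, contrast-adjusted,
    packaged with the ground truth.  Fully deterministic."""
    geom_ap = geometry if geometry is not None else default_benchmark_geometry()[0]
    geom_ap = replace(geom_ap, view=pose_to_matrix(Pose6DoF()), view_tag="AP")
    geom_lat = replace(geom_ap, view=lat_view_transform(angle_deg), view_tag="LAT")
    ap, lat = render_biplanar(ct, pose, geom_ap, geom_lat)
    ap = contrast_adjust(ap, contrast)
    lat = contrast_adjust(lat, contrast)
    return BenchmarkCase(
        case_id=case_id or f"case_{seed}",
        ap=ap, lat=lat, pose_gt=pose, angle_deg=angle_deg,
        contrast=contrast, landmarks=landmarks, seed=seed,
        meta={"geometry": geom_ap.to_json_dict(),
              "pose_center_mm": list(ct.center)})


def reconstruction_degradation(angle_deg: float, base_blur: float = 1.0,
                               base_noise: float = 0.05):
    """Degradation level of the simulated reconstructor vs view separation.

    Two views constrain the out-of-plane axis in proportion to how far
    apart they are; as the separation angle closes, depth information
    degrades roughly like 1/sin(angle).  Returns (blur_sigma_voxels,
    noise_fraction) with the base values at 90 degrees.
    """
    if not (0.0 < angle_deg < 180.0):
        raise ValueError("view separation must lie in (0, 180) degrees")
    f = 1.0 / math.sin(math.radians(angle_deg))
    return base_blur * f, base_noise * f


def pseudo_reconstruct(ct: Volume, pose: Pose6DoF, blur_sigma: float = 1.0,
                       noise_frac: float = 0.05, intensity_scale: float = 1.0,
                       seed: int = 0) -> Volume:
    """Simulate the output of a biplanar-to-CT reconstructor.

    The ground-truth anatomy is resampled at the (unknown to the
    registration) ``pose`` on its own grid, then degraded: Gaussian blur of
    ``blur_sigma`` voxels, multiplication by ``intensity_scale``, and
    additive Gaussian noise with standard deviation ``noise_frac`` times
    the clean dynamic range.  With (0, 0, 1) the result is exactly the
    clean transformed copy.  Deterministic per seed.
    """
    if blur_sigma < 0 or noise_frac < 0:
        raise ValueError("blur_sigma and noise_frac must be non-negative")
    T = pose_to_matrix(pose, ct.center)
    out = resample_rigid(ct, T, ct)
    vox = out.voxels
    if blur_sigma > 0:
        vox = gaussian_filter(vox, sigma=blur_sigma)
    if intensity_scale != 1.0:
        vox = vox * intensity_scale
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        rng_scale = float(vox.max() - vox.min())
        vox = vox + rng.normal(0.0, noise_frac * rng_scale, size=vox.shape)
    return Volume(vox, out.spacing, out.origin)


def build_dataset(n_cases: int, seed: int = 0, split: float = 0.75,
                  angle_deg: float = 90.0, contrast: str = "mid",
                  rot_range_deg: float = 10.0, trans_range_mm: float = 20.0,
                  out_path=None) -> list:
    """Emit a manifest of ``n_cases`` benchmark cases with a seeded
    train/test split (default 75 % train).

    Each entry records the per-case seed, ground-truth pose (degrees/mm at
    this boundary), angle, contrast and split; counts are exact
    (round(split * n) train cases).  Optionally written as JSON lines.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if not (0.0 <= split <= 1.0):
        raise ValueError("split fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_train = int(round(split * n_cases))
    order = rng.permutation(n_cases)
    train_ids = set(order[:n_train].tolist())
    manifest = []
    for i in range(n_cases):
        case_seed = int(rng.integers(0, 2 ** 31 - 1))
        pose = sample_pose(case_seed, rot_range_deg, trans_range_mm)
        manifest.append({
            "case_id": f"case_{i:04d}",
            "seed": case_seed,
            "pose": pose.to_json_dict(),
            "angle_deg": angle_deg,
            "contrast": contrast,
            "split": "train" if i in train_ids else "test",
        })
    if out_path is not None:
        with open(out_path, "w") as fh:
            for entry in manifest:
                fh.write(json.dumps(entry) + "\n")
    return manifest
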