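"""CT preprocessing for rigid head registration.

Head CTs routinely contain the scanner bed and other non-anatomical
content.  The preprocessing pipeline removes it in two steps and then
isolates the rigid bone structure:

1. **Max-ellipse detection** — on every axial slice, threshold the scene
   at a foreground level (default -200 HU), keep the largest connected
   component, and least-squares fit an ellipse to its boundary.  The
   ellipse of maximal area across slices outlines the head.
2. **Elliptical-cylinder crop** — the detected ellipse, expanded to 120 %
   of its size (factor 1.2 on both semi-axes), is extruded through all
   slices; everything outside is set to air (-1000 HU), removing the bed.
3. **Bone thresholding** — soft, sparse tissue with HU < 100 is set to a
   background value (0 by default, matching the registration fill value);
   HU >= 100 is kept unchanged, leaving the skull.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.measure import EllipseModel, find_contours, label

from .volume import Volume

__all__ = ["Ellipse2D", "detect_max_ellipse", "crop_elliptical_cylinder",
           "threshold_bone", "preprocess_ct"]

MIN_COMPONENT_VOXELS = 100


@dataclass(frozen=True)
class Ellipse2D:
    """In-slice ellipse: centre (mm), semi-axes a >= b (mm), angle (rad)."""

    center: tuple          # (x_mm, y_mm) in world coordinates
    a: float               # semi-major axis, mm
    b: float               # semi-minor axis, mm
    angle: float           # in-plane rotation of the major axis, radians
    slice_index: int = 0   # axial slice where the ellipse was detected

    def __post_init__(self):
        if not (self.a >= self.b > 0):
            raise ValueError(f"ellipse semi-axes must satisfy a >= b > 0, got a={self.a}, b={self.b}")

    @property
    def area(self) -> float:
        return math.pi * self.a * self.b

    def to_json_dict(self) -> dict:
        return {"center_mm": list(self.center), "a_mm": self.a, "b_mm": self.b,
                "angle_deg": math.degrees(self.angle), "slice_index": self.slice_index}


def _fit_slice_ellipse(slice_xy: np.ndarray, foreground: float):
    """Largest-component boundary ellipse fit for one axial slice.

    Returns (xc, yc, a, b, angle) in index units, or None if no component
    of at least MIN_COMPONENT_VOXELS pixels exists or the fit fails.
    """
    fg = slice_xy > foreground
    if fg.sum() < MIN_COMPONENT_VOXELS:
        return None
    lab, n = label(fg, return_num=True)
    if n == 0:
        return None
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    biggest = int(np.argmax(sizes))
    if sizes[biggest] < MIN_COMPONENT_VOXELS:
        return None
    comp = lab == biggest
    contours = find_contours(comp.astype(float), 0.5)
    if not contours:
        return None
    boundary = max(contours, key=len)  # (row=x, col=y) index coordinates
    if hasattr(EllipseModel, "from_estimate"):
        model = EllipseModel.from_estimate(boundary)
        if not model:
            return None
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    else:
        model = EllipseModel()
        if not model.estimate(boundary):
            return None
        xc, yc, a, b, theta = model.params
    if a < b:
        a, b = b, a
        theta += math.pi / 2
    theta = math.atan2(math.sin(theta), math.cos(theta))
    if theta <= -math.pi / 2:
        theta += math.pi
    elif theta > math.pi / 2:
        theta -= math.pi
    return xc, yc, a, b, theta


def detect_max_ellipse(volume: Volume, foreground_hu: float = -200.0) -> Ellipse2D:
    """Detect the largest-area fitted head ellipse across all axial slices.

    Per slice: threshold at ``foreground_hu``, take the largest connected
    component, fit an ellipse to its boundary; return the fit of maximal
    area over slices, in world millimetres.

    Raises ``ValueError`` when no slice contains a foreground component of
    at least 100 voxels (empty scene).
    """
    sx, sy = volume.spacing[0], volume.spacing[1]
    best = None
    for k in range(volume.shape[2]):
        fit = _fit_slice_ellipse(volume.voxels[:, :, k].astype(float), foreground_hu)
        if fit is None:
            continue
        xc, yc, a, b, theta = fit
        # convert to mm (assumes near-isotropic in-plane spacing for a/b)
        a_mm = a * math.hypot(sx * math.cos(theta), sy * math.sin(theta))
        b_mm = b * math.hypot(sx * math.sin(theta), sy * math.cos(theta))
        if a_mm < b_mm:
            a_mm, b_mm = b_mm, a_mm
            theta += math.pi / 2
        cand = Ellipse2D(
            center=(volume.origin[0] + xc * sx, volume.origin[1] + yc * sy),
            a=a_mm, b=b_mm, angle=theta, slice_index=k)
        if best is None or cand.area > best.area:
            best = cand
    if best is None:
        raise ValueError("empty scene: no axial slice has a foreground "
                         f"component of >= {MIN_COMPONENT_VOXELS} voxels "
                         f"above {foreground_hu} HU")
    return best


def crop_elliptical_cylinder(volume: Volume, ellipse: Ellipse2D,
                             expand: float = 1.2,
                             fill_hu: float = -1000.0) -> Volume:
    """Keep only voxels inside the expanded ellipse extruded through z.

    Both semi-axes are scaled by ``expand`` (default 1.2, i.e. a mask 20 %
    larger than the detected head outline); voxels outside the resulting
    elliptical cylinder are set to ``fill_hu``.  Grid shape is unchanged.
    """
    if expand <= 0:
        raise ValueError(f"expand factor must be positive, got {expand}")
    nx, ny, _ = volume.shape
    x = volume.origin[0] + np.arange(nx) * volume.spacing[0]
    y = volume.origin[1] + np.arange(ny) * volume.spacing[1]
    xx, yy = np.meshgrid(x - ellipse.center[0], y - ellipse.center[1], indexing="ij")
    ct, st = math.cos(ellipse.angle), math.sin(ellipse.angle)
    u = xx * ct + yy * st
    v = -xx * st + yy * ct
    inside = (u / (expand * ellipse.a)) ** 2 + (v / (expand * ellipse.b)) ** 2 <= 1.0
    out = volume.voxels.astype(float).copy()
    out[~inside, :] = fill_hu
    return Volume(out, volume.spacing.copy(), volume.origin.copy())


def threshold_bone(volume: Volume, hu_min: float = 100.0,
                   background: float = 0.0) -> Volume:
    """Remove sparse soft tissue, keeping the rigid bone structure.

    Voxels with HU < ``hu_min`` become ``background``; voxels at or above
    the threshold keep their original HU (the boundary is inclusive:
    HU = 100 is retained).
    """
    v = volume.voxels.astype(float)
    out = np.where(v >= hu_min, v, background)
    return Volume(out, volume.spacing.copy(), volume.origin.copy())


def preprocess_ct(volume: Volume, foreground_hu: float = -200.0,
                  expand: float = 1.2, hu_min: float = 100.0):
    """Full pipeline: detect ellipse, crop the elliptical cylinder,
    threshold to bone.  Returns (bone volume, report dict)."""
    ellipse = detect_max_ellipse(volume, foreground_hu)
    cropped = crop_elliptical_cylinder(volume, ellipse, expand=expand)
    bone = threshold_bone(cropped, hu_min=hu_min)
    report = {
        "ellipse": ellipse.to_json_dict(),
        "expand": expand,
        "hu_min": hu_min,
        "voxels_foreground_before": int(np.count_nonzero(volume.voxels >= hu_min)),
        "voxels_foreground_after": int(np.count_nonzero(bone.voxels != 0)),
    }
    return bone, report
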