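"""Perspective DRR rendering and reconstruction-supervision losses.

The X-ray imaging system is modelled as a calibrated pinhole camera: a
point source, an isocenter, and a flat detector behind it.  A digitally
reconstructed radiograph (DRR) is produced by ray casting — marching
uniform steps along each source-to-pixel segment and accumulating
trilinearly interpolated volume samples, approximating the line integral

    I(x; T) = integral over p in L(x, r) of J(T^-1 p) dp

where L(x, r) is the ray from the source to detector pixel x and T the
6-DoF pose of the volume.  The second (lateral) view shares the pose and
composes a fixed inter-view transform T_lat before the pull-back:
J(T^-1 T_lat^-1 p).

The photometric model is the raw line integral of intensity, in units of
intensity * mm — no Beer-Lambert exponentiation or logarithm; display
transforms are cosmetic only.

The module also provides the supervision utilities used to train a
biplanar-to-CT reconstructor: a voxelwise MSE reconstruction loss, a
perspective projection loss that re-renders the generated volume through
the same ray caster, and their weighted total.  No network is trained
here; the reconstruction stage is pluggable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import Pose6DoF, RigidTransform, apply_points, compose, invert, pose_to_matrix
from .volume import DRRImage, Volume, sample_trilinear

__all__ = ["ProjectionGeometry", "render_drr", "render_biplanar",
           "reconstruction_loss", "perspective_projection_loss",
           "total_generator_loss", "contrast_adjust", "CONTRAST_GAMMA"]

#: gamma exponents emulating X-ray energy levels (applied after min-max
#: normalization; contrast ratio varies qualitatively with energy)
CONTRAST_GAMMA = {"low": 0.5, "mid": 1.0, "high": 2.0}


@dataclass
class ProjectionGeometry:
    """Pinhole C-arm geometry.

    The view frame has its viewing direction along +x: the source sits at
    ``isocenter - sid * ex`` and the detector plane at
    ``isocenter + (sdd - sid) * ex``, spanned by the y (detector u) and z
    (detector v) axes.  ``view`` maps the patient frame to this view frame
    (identity for AP; ``lat_view_transform`` for the lateral view).
    """

    sid: float = 1000.0          # source-to-isocenter distance, mm
    sdd: float = 1500.0          # source-to-detector distance, mm
    detector_shape: tuple = (256, 256)
    pixel_spacing: tuple = (1.0, 1.0)   # mm
    view: RigidTransform = field(default_factory=RigidTransform.identity)
    view_tag: str = "AP"
    step: float | None = None    # ray-march step mm; None -> 0.5 * min(spacing)
    isocenter: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.sid <= 0 or self.sdd <= 0:
            raise ValueError("source distances must be positive")
        if self.sdd <= self.sid:
            raise ValueError("detector must lie behind the isocenter "
                             f"(sdd={self.sdd} <= sid={self.sid})")
        if self.step is not None and self.step <= 0:
            raise ValueError("ray-march step must be positive")
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValueError("pixel spacing must be positive")
        if any(n < 1 for n in self.detector_shape):
            raise ValueError("detector must have at least one pixel per axis")

    def to_json_dict(self) -> dict:
        return {
            "sid_mm": self.sid, "sdd_mm": self.sdd,
            "detector_shape": list(self.detector_shape),
            "pixel_spacing_mm": list(self.pixel_spacing),
            "view_tag": self.view_tag,
            "view_matrix": self.view.matrix.tolist(),
            "step_mm": self.step,
            "isocenter_mm": list(self.isocenter),
        }


def _integrate_rays(volume: Volume, src: np.ndarray, pixels: np.ndarray,
                    step: float, chunk: int = 8192) -> np.ndarray:
    """Midpoint-rule line integrals from a common source to each pixel.

    Rays are clipped to the volume's axis-aligned bounding box (slab
    method); each ray uses n = ceil(L / step) equal sub-steps of length
    dt = L / n <= step, so partial first/last steps are weighted by their
    actual length.  Pure per-ray map: chunking does not change results.
    """
    lo = volume.origin.copy()
    hi = volume.origin + volume.extent
    out = np.zeros(len(pixels))
    eps = 1e-12
    src_inside = (src >= lo) & (src <= hi)
    for i in range(0, len(pixels), chunk):
        P = pixels[i:i + chunk]
        d = P - src
        dn = d / np.linalg.norm(d, axis=1, keepdims=True)
        safe = np.where(np.abs(dn) > eps, dn, eps)
        ta = (lo - src) / safe
        tb = (hi - src) / safe
        tmin = np.minimum(ta, tb)
        tmax = np.maximum(ta, tb)
        par = np.abs(dn) <= eps
        tmin = np.where(par, np.where(src_inside, -np.inf, np.inf), tmin)
        tmax = np.where(par, np.where(src_inside, np.inf, -np.inf), tmax)
        t0 = np.maximum(tmin.max(axis=1), 0.0)
        t1 = tmax.min(axis=1)
        hit = t1 > t0
        if not np.any(hit):
            continue
        L = np.where(hit, t1 - t0, 0.0)
        n = np.maximum(np.ceil(L / step), 1).astype(int)
        n_max = int(n.max())
        dt = L / n
        k = np.arange(n_max)
        t = t0[:, None] + (k[None, :] + 0.5) * dt[:, None]
        active = (k[None, :] < n[:, None]) & hit[:, None]
        pts = src[None, None, :] + dn[:, None, :] * t[:, :, None]
        vals = sample_trilinear(volume, pts.reshape(-1, 3)).reshape(t.shape)
        out[i:i + chunk] = (vals * active).sum(axis=1) * dt
    return out


def render_drr(volume: Volume, pose: Pose6DoF | None = None,
               geometry: ProjectionGeometry | None = None,
               pose_center=None) -> DRRImage:
    """Render a perspective DRR of ``volume`` posed at ``pose``.

    For each detector pixel the segment from the source to the pixel is
    marched in steps of at most ``geometry.step`` mm, accumulating
    ``sample_trilinear`` values times the step length.  The pose pull-back
    J(T^-1 V^-1 p) composes the view transform with the pose, so the same
    pose drives all views.  Deterministic for fixed inputs; a geometry that
    misses the volume entirely yields an all-zero image.

    ``pose_center`` is the rotation centre of the pose (default: the
    volume's world centre).
    """
    geom = geometry if geometry is not None else ProjectionGeometry()
    pose = pose if pose is not None else Pose6DoF()
    step = geom.step if geom.step is not None else 0.5 * float(np.min(volume.spacing))
    iso = np.asarray(geom.isocenter, dtype=float)
    nu, nv = geom.detector_shape
    su, sv = geom.pixel_spacing
    u = (np.arange(nu) - (nu - 1) / 2.0) * su
    v = (np.arange(nv) - (nv - 1) / 2.0) * sv
    uu, vv = np.meshgrid(u, v, indexing="ij")
    pix = np.stack([np.full(uu.shape, geom.sdd - geom.sid), uu, vv],
                   axis=-1).reshape(-1, 3) + iso
    src = iso + np.array([-geom.sid, 0.0, 0.0])

    center = volume.center if pose_center is None else np.asarray(pose_center, float)
    T = pose_to_matrix(pose, center)
    M = compose(invert(T), invert(geom.view))
    S = apply_points(M, src)
    P = apply_points(M, pix)
    vals = _integrate_rays(volume, S, P, step)
    return DRRImage(vals.reshape(nu, nv), (su, sv), view=geom.view_tag)


def render_biplanar(volume: Volume, pose: Pose6DoF,
                    geom_ap: ProjectionGeometry,
                    geom_lat: ProjectionGeometry,
                    pose_center=None):
    """Render the AP/LAT pair sharing one pose.

    ``geom_ap`` should carry the identity view transform and ``geom_lat``
    the inter-view transform (e.g. ``lat_view_transform(90)``).
    """
    ap = render_drr(volume, pose, geom_ap, pose_center=pose_center)
    lat = render_drr(volume, pose, geom_lat, pose_center=pose_center)
    return ap, lat


# ---------------------------------------------------------------------------
# Supervision losses for a pluggable biplanar-to-CT reconstructor

def reconstruction_loss(generated: Volume, truth: Volume) -> float:
    """Voxelwise mean squared error between a generated and a truth volume."""
    if generated.shape != truth.shape:
        raise ValueError(f"volume grids differ: {generated.shape} vs {truth.shape}")
    diff = generated.voxels.astype(float) - truth.voxels.astype(float)
    return float(np.mean(diff * diff))


def _image_mse(a: np.ndarray, b: np.ndarray) -> float:
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    d = a.astype(float) - b.astype(float)
    return float(np.mean(d * d))


def perspective_projection_loss(generated: Volume, ap_image: DRRImage,
                                lat_image: DRRImage,
                                geom_ap: ProjectionGeometry,
                                geom_lat: ProjectionGeometry) -> float:
    """Perspective projection loss: the generated volume is re-projected
    through the same perspective ray caster and compared to the input
    radiographs by MSE, averaged over the two views."""
    ap_render = render_drr(generated, Pose6DoF(), geom_ap)
    lat_render = render_drr(generated, Pose6DoF(), geom_lat)
    return 0.5 * (_image_mse(ap_image.pixels, ap_render.pixels)
                  + _image_mse(lat_image.pixels, lat_render.pixels))


def total_generator_loss(l_lsgan: float, l_rl: float, l_rpl: float,
                         eps=(0.1, 10.0, 10.0)) -> float:
    """Weighted total generator loss: eps1 * adversarial + eps2 *
    reconstruction + eps3 * perspective projection (defaults 0.1/10/10)."""
    vals = np.array([l_lsgan, l_rl, l_rpl], dtype=float)
    w = np.asarray(eps, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("loss components must be finite")
    return float(w @ vals)


def contrast_adjust(image: DRRImage, level: str = "mid") -> DRRImage:
    """Monotone gamma remapping emulating different X-ray energies.

    The image is min-max normalized to [0, 1] and raised to the level's
    gamma exponent (low = 0.5, mid = 1.0, high = 2.0); the output stays in
    normalized display units, so ``mid`` is the identity after
    normalization.  Pixel ordering is always preserved.  The relation to
    physical beam energy is qualitative only.
    """
    if level not in CONTRAST_GAMMA:
        raise ValueError(f"contrast level must be one of {sorted(CONTRAST_GAMMA)}, got {level!r}")
    px = image.pixels.astype(float)
    lo, hi = float(px.min()), float(px.max())
    if hi > lo:
        norm = (px - lo) / (hi - lo)
    else:
        norm = np.zeros_like(px)
    out = norm ** CONTRAST_GAMMA[level]
    return DRRImage(out, image.pixel_spacing.copy(), view=image.view)


# ---------------------------------------------------------------------------
# DRR disk format: 16-bit PNG (min-max scaled) + JSON sidecar

def save_drr(image: DRRImage, png_path: str, geometry: ProjectionGeometry | None = None,
             pose: Pose6DoF | None = None) -> None:
    """Save a DRR as 16-bit PNG with a JSON sidecar holding the raw-value
    scale, geometry and pose, so the raw line integrals are recoverable."""
    import imageio.v3 as iio

    px = image.pixels
    lo, hi = float(px.min()), float(px.max())
    scale = (hi - lo) if hi > lo else 1.0
    u16 = np.round((px - lo) / scale * 65535.0).astype(np.uint16)
    iio.imwrite(png_path, u16)
    sidecar = {
        "raw_min": lo, "raw_max": hi,
        "pixel_spacing_mm": image.pixel_spacing.tolist(),
        "view": image.view,
        "geometry": geometry.to_json_dict() if geometry is not None else None,
        "pose": pose.to_json_dict() if pose is not None else None,
    }
    with open(str(png_path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_drr(png_path: str) -> DRRImage:
    """Load a DRR saved by :func:`save_drr`, restoring raw line integrals."""
    import imageio.v3 as iio

    with open(str(png_path) + ".json") as fh:
        sidecar = json.load(fh)
    u16 = iio.imread(png_path).astype(float)
    lo, hi = sidecar["raw_min"], sidecar["raw_max"]
    px = u16 / 65535.0 * (hi - lo) + lo
    return DRRImage(px, sidecar["pixel_spacing_mm"], view=sidecar["view"])
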