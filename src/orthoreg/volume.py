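"""Volume container, standard-format I/O, trilinear sampling, resampling.

A :class:`Volume` is an axis-aligned scalar grid (typically HU) with axis
order (x, y, z), per-axis spacing in mm and a world origin at the centre of
voxel (0, 0, 0), so ``world = origin + index * spacing``.  Only
axis-aligned acquisitions are supported: volumes whose direction matrix is
not the identity are rejected loudly rather than silently misregistered.

Sampling is trilinear everywhere ("pull-back" interpolation on the moving
grid); points outside the grid take a configurable fill value, 0 by
default, matching the background of bone-thresholded CT.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import RigidTransform, invert

__all__ = ["Volume", "DRRImage", "read_volume", "write_volume",
           "sample_trilinear", "resample_rigid"]


@dataclass
class Volume:
    """Axis-aligned 3-D scalar grid with spacing (mm) and world origin (mm)."""

    voxels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError(f"voxels must be a non-empty 3-D array, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite voxels")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self):
        return self.voxels.shape

    @property
    def center(self) -> np.ndarray:
        """World coordinate of the grid centre (mm)."""
        return self.origin + (np.array(self.shape) - 1) / 2.0 * self.spacing

    @property
    def extent(self) -> np.ndarray:
        """Physical size along each axis, voxel centre to voxel centre (mm)."""
        return (np.array(self.shape) - 1) * self.spacing

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def grid_world_coords(self) -> np.ndarray:
        """(nx*ny*nz, 3) world coordinates of every voxel centre, x fastest last axis order (C order over (x,y,z) index grid)."""
        nx, ny, nz = self.shape
        ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij")
        idx = np.stack([ix, iy, iz], axis=-1).reshape(-1, 3)
        return self.index_to_world(idx)

    def astype(self, dtype) -> "Volume":
        return Volume(self.voxels.astype(dtype), self.spacing.copy(), self.origin.copy())

    def copy(self) -> "Volume":
        return Volume(self.voxels.copy(), self.spacing.copy(), self.origin.copy())


@dataclass
class DRRImage:
    """2-D grid of perspective line integrals (intensity * mm) on a detector."""

    pixels: np.ndarray
    pixel_spacing: np.ndarray = field(default_factory=lambda: np.ones(2))
    view: str = "other"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"DRR pixels must be 2-D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("DRR contains non-finite pixels")
        self.pixel_spacing = np.asarray(self.pixel_spacing, dtype=float).reshape(2)
        if np.any(self.pixel_spacing <= 0):
            raise ValueError("pixel spacing must be strictly positive")

    @property
    def shape(self):
        return self.pixels.shape


# ---------------------------------------------------------------------------
# I/O

def _check_direction(direction: np.ndarray, path) -> None:
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise ValueError(
            f"unsupported orientation in {path}: only axis-aligned volumes "
            f"(identity direction matrix) are supported; got\n{direction}")


def _read_dicom_series(path: str) -> Volume:
    import pydicom

    files = sorted(os.path.join(path, f) for f in os.listdir(path)
                   if not f.startswith("."))
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if hasattr(ds, "pixel_array"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no readable DICOM slices in {path}")
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    rows_cols = {(int(ds.Rows), int(ds.Columns)) for ds in slices}
    if len(rows_cols) != 1:
        raise ValueError("DICOM series has inconsistent slice dimensions")
    first = slices[0]
    px_spacing = [float(v) for v in first.PixelSpacing]  # (row, col) mm
    positions = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    if len(slices) > 1:
        dz = np.diff(positions)
        if not np.allclose(dz, dz[0], atol=1e-3):
            raise ValueError("DICOM series has non-uniform slice spacing")
        slice_spacing = float(dz[0])
    else:
        slice_spacing = float(getattr(first, "SliceThickness", 1.0))
    arr = np.stack([ds.pixel_array.astype(np.float64) for ds in slices], axis=-1)
    slope = float(getattr(first, "RescaleSlope", 1.0))
    intercept = float(getattr(first, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    # pixel_array rows are y, columns x -> transpose to (x, y, z)
    arr = np.transpose(arr, (1, 0, 2))
    origin = np.array([float(first.ImagePositionPatient[0]),
                       float(first.ImagePositionPatient[1]),
                       positions[0]])
    spacing = np.array([px_spacing[1], px_spacing[0], slice_spacing])
    return Volume(arr, spacing, origin)


def read_volume(path: str) -> Volume:
    """Read a NIfTI (.nii/.nii.gz), MetaImage (.mhd/.mha) volume or a DICOM
    series directory into a :class:`Volume`.

    Spacing and origin are preserved.  Non-axis-aligned direction matrices
    raise an unsupported-orientation error.
    """
    path = str(path)
    if os.path.isdir(path):
        return _read_dicom_series(path)
    low = path.lower()
    if low.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        affine = img.affine
        spacing = np.linalg.norm(affine[:3, :3], axis=0)
        _check_direction(affine[:3, :3] / spacing, path)
        origin = affine[:3, 3].astype(float)
        data = np.asarray(img.dataobj)
        return Volume(np.ascontiguousarray(data, dtype=data.dtype), spacing, origin)
    if low.endswith((".mhd", ".mha")):
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        _check_direction(np.array(img.GetDirection()).reshape(3, 3), path)
        arr = sitk.GetArrayFromImage(img)  # (z, y, x)
        arr = np.ascontiguousarray(np.transpose(arr, (2, 1, 0)))
        return Volume(arr, np.array(img.GetSpacing()), np.array(img.GetOrigin()))
    raise ValueError(f"unknown volume format: {path}")


def write_volume(volume: Volume, path: str) -> None:
    """Write a volume as NIfTI or MetaImage, preserving spacing and origin."""
    path = str(path)
    low = path.lower()
    if low.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.eye(4)
        affine[:3, :3] = np.diag(volume.spacing)
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(volume.voxels, affine), path)
        return
    if low.endswith((".mhd", ".mha")):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(
            np.transpose(volume.voxels, (2, 1, 0))))
        img.SetSpacing(tuple(float(s) for s in volume.spacing))
        img.SetOrigin(tuple(float(o) for o in volume.origin))
        sitk.WriteImage(img, path)
        return
    raise ValueError(f"unknown volume format: {path}")


# ---------------------------------------------------------------------------
# Sampling

def sample_trilinear(volume: Volume, points, fill_value: float = 0.0) -> np.ndarray:
    """Trilinear interpolation of ``volume`` at world-mm ``points``.

    Points outside the grid return ``fill_value`` (out-of-bounds is defined,
    not an error).  This is a pure per-point map: results are independent of
    evaluation order or chunking.
    """
    p = np.asarray(points, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    idx = volume.world_to_index(p)
    vals = map_coordinates(volume.voxels.astype(float, copy=False), idx.T,
                           order=1, mode="constant", cval=fill_value)
    return float(vals[0]) if single else vals


def inbounds_mask(volume: Volume, points) -> np.ndarray:
    """True where a world point lies within the voxel-centre bounding box."""
    idx = volume.world_to_index(np.atleast_2d(np.asarray(points, dtype=float)))
    upper = np.array(volume.shape) - 1
    return np.all((idx >= 0) & (idx <= upper), axis=1)


def resample_rigid(moving: Volume, T: RigidTransform, reference: Volume,
                   fill_value: float = 0.0, return_mask: bool = False):
    """Resample ``moving`` under transform ``T`` onto the ``reference`` grid.

    Each output voxel at world coordinate p takes the pull-back value
    ``moving(T^-1 p)`` by trilinear interpolation — the standard way to
    apply a transform to the moving image without holes.

    With ``return_mask=True`` also returns the boolean overlap mask of
    output voxels whose pull-back landed inside the moving grid.
    """
    Tinv = invert(T)
    pts = reference.grid_world_coords()
    src = pts @ Tinv.rotation.T + Tinv.t
    vals = sample_trilinear(moving, src, fill_value=fill_value)
    out = Volume(vals.reshape(reference.shape),
                 reference.spacing.copy(), reference.origin.copy())
    if return_mask:
        mask = inbounds_mask(moving, src).reshape(reference.shape)
        return out, mask
    return out
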