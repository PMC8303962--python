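"""6-DoF rigid pose parameterization and homogeneous transforms.

A pose is three rotation angles ``(alpha, beta, gamma)`` about the fixed
x, y and z axes plus a translation ``(tx, ty, tz)`` in millimetres.  The
rotation matrix is composed extrinsically, x first::

    R = Rz(gamma) @ Ry(beta) @ Rx(alpha)

Angles are radians inside the library; degrees appear only at user-facing
boundaries (CLI, JSON).  Rotation is applied about a configurable centre
(by convention the moving volume's world-space centre), then translation:

    T(p) = R (p - c) + c + t

All transforms are plain 4x4 homogeneous matrices wrapped in
:class:`RigidTransform`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Pose6DoF",
    "RigidTransform",
    "LandmarkSet",
    "pose_to_matrix",
    "matrix_to_pose",
    "compose",
    "invert",
    "apply_points",
    "lat_view_transform",
]

_ORTHO_TOL = 1e-6


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} must be finite, got {v}")
    return v


@dataclass(frozen=True)
class Pose6DoF:
    """Rigid pose: rotations about x/y/z (radians) and translation (mm)."""

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma", "tx", "ty", "tz"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"pose component {name} is not finite: {v}")

    @property
    def angles(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma])

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz])

    def as_array(self) -> np.ndarray:
        """(alpha, beta, gamma, tx, ty, tz) as a float array."""
        return np.array([self.alpha, self.beta, self.gamma, self.tx, self.ty, self.tz])

    @classmethod
    def from_array(cls, a) -> "Pose6DoF":
        a = np.asarray(a, dtype=float).reshape(-1)
        if a.shape != (6,):
            raise ValueError(f"pose array must have 6 components, got {a.shape}")
        return cls(*a)

    @classmethod
    def from_degrees(cls, alpha_deg=0.0, beta_deg=0.0, gamma_deg=0.0,
                     tx=0.0, ty=0.0, tz=0.0) -> "Pose6DoF":
        return cls(math.radians(alpha_deg), math.radians(beta_deg),
                   math.radians(gamma_deg), tx, ty, tz)

    def to_json_dict(self, center=(0.0, 0.0, 0.0)) -> dict:
        """Serializable dict with angles in degrees (the boundary convention)."""
        return {
            "alpha_deg": math.degrees(self.alpha),
            "beta_deg": math.degrees(self.beta),
            "gamma_deg": math.degrees(self.gamma),
            "tx_mm": self.tx,
            "ty_mm": self.ty,
            "tz_mm": self.tz,
            "euler_convention": "extrinsic x-y-z (R = Rz @ Ry @ Rx)",
            "center_mm": list(np.asarray(center, dtype=float)),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "Pose6DoF":
        if "alpha_deg" not in d and isinstance(d.get("pose"), dict):
            d = d["pose"]  # accept a registration-result file as a pose
        return cls.from_degrees(d["alpha_deg"], d["beta_deg"], d["gamma_deg"],
                                d["tx_mm"], d["ty_mm"], d["tz_mm"])

    def save(self, path, center=(0.0, 0.0, 0.0)) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(center), fh, indent=2)

    @classmethod
    def load(cls, path) -> "Pose6DoF":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


class RigidTransform:
    """A 4x4 homogeneous rigid-body transform.

    The rotation block must be orthonormal with determinant +1 and the
    bottom row exactly (0, 0, 0, 1).
    """

    __slots__ = ("matrix", "center")

    def __init__(self, matrix, center=(0.0, 0.0, 0.0)):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"rigid transform must be 4x4, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("rigid transform contains non-finite entries")
        R = m[:3, :3]
        if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("rotation block is not orthonormal")
        if not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=_ORTHO_TOL):
            raise ValueError("rotation block has determinant != +1 (reflection?)")
        m = m.copy()
        m[3, :] = (0.0, 0.0, 0.0, 1.0)
        self.matrix = m
        self.center = _as_vec3(center, "center")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, R, t, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = np.asarray(R, dtype=float)
        m[:3, 3] = _as_vec3(t, "t")
        return cls(m, center)

    @classmethod
    def translation(cls, t) -> "RigidTransform":
        return cls.from_rotation_translation(np.eye(3), t)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def t(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return compose(self, other)

    def __repr__(self):
        return f"RigidTransform(matrix=\n{self.matrix},\ncenter={self.center})"


@dataclass(frozen=True)
class LandmarkSet:
    """Named 3-D landmark coordinates in world millimetres."""

    names: tuple
    coords: np.ndarray = field(repr=False)

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise ValueError(f"landmark coords must be (n>=1, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("landmark coordinates must be finite")
        if len(self.names) != coords.shape[0]:
            raise ValueError("number of names must match number of coordinates")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "names", tuple(self.names))

    def __len__(self):
        return self.coords.shape[0]

    def to_json_dict(self) -> dict:
        return {name: list(c) for name, c in zip(self.names, self.coords)}

    @classmethod
    def from_json_dict(cls, d: dict) -> "LandmarkSet":
        return cls(tuple(d.keys()), np.array(list(d.values()), dtype=float))


def _rx(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _ry(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def _rz(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def rotation_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """R = Rz(gamma) @ Ry(beta) @ Rx(alpha), extrinsic x->y->z."""
    return _rz(gamma) @ _ry(beta) @ _rx(alpha)


def rotation_matrix_derivatives(alpha: float, beta: float, gamma: float):
    """dR/dalpha, dR/dbeta, dR/dgamma for the extrinsic x-y-z composition."""
    ca, sa = math.cos(alpha), math.sin(alpha)
    cb, sb = math.cos(beta), math.sin(beta)
    cg, sg = math.cos(gamma), math.sin(gamma)
    rx, ry, rz = _rx(alpha), _ry(beta), _rz(gamma)
    drx = np.array([[0, 0, 0], [0, -sa, -ca], [0, ca, -sa]])
    dry = np.array([[-sb, 0, cb], [0, 0, 0], [-cb, 0, -sb]])
    drz = np.array([[-sg, -cg, 0], [cg, -sg, 0], [0, 0, 0]])
    return rz @ ry @ drx, rz @ dry @ rx, drz @ ry @ rx


def pose_to_matrix(pose: Pose6DoF, center=(0.0, 0.0, 0.0)) -> RigidTransform:
    """Build the homogeneous matrix for ``pose`` rotating about ``center``.

    The transform maps a point p to ``R (p - c) + c + t``: rotation about
    the centre first, then translation.
    """
    if not isinstance(pose, Pose6DoF):
        pose = Pose6DoF(*np.asarray(pose, dtype=float))
    c = _as_vec3(center, "center")
    R = rotation_matrix(pose.alpha, pose.beta, pose.gamma)
    m = np.eye(4)
    m[:3, :3] = R
    m[:3, 3] = pose.translation + c - R @ c
    return RigidTransform(m, center=c)


def matrix_to_pose(T: RigidTransform, center=(0.0, 0.0, 0.0)) -> Pose6DoF:
    """Recover the 6-DoF pose of a rigid transform about ``center``.

    Euler angles follow the Rz@Ry@Rx convention.  At gimbal lock
    (|beta| = pi/2) the decomposition is degenerate; the gamma = 0 branch is
    taken and the residual in-plane rotation folded into alpha, so the
    returned pose always re-synthesizes the same matrix.
    """
    if not isinstance(T, RigidTransform):
        T = RigidTransform(T)
    c = _as_vec3(center, "center")
    R = T.rotation
    # R[2,0] = -sin(beta)
    sb = -R[2, 0]
    sb = min(1.0, max(-1.0, float(sb)))
    beta = math.asin(sb)
    if abs(sb) < 1.0 - 1e-12:
        alpha = math.atan2(R[2, 1], R[2, 2])
        gamma = math.atan2(R[1, 0], R[0, 0])
    else:
        # gimbal lock: only alpha -/+ gamma is determined; fix gamma = 0
        gamma = 0.0
        alpha = math.atan2(-R[1, 2], R[1, 1]) if sb > 0 else math.atan2(R[1, 2], R[1, 1])
    Rr = rotation_matrix(alpha, beta, gamma)
    t = T.t - c + Rr @ c
    return Pose6DoF(alpha, beta, gamma, *t)


def compose(A: RigidTransform, B: RigidTransform) -> RigidTransform:
    """Composition A after B: (A o B)(p) = A(B(p))."""
    return RigidTransform(A.matrix @ B.matrix, center=A.center)


def invert(T: RigidTransform) -> RigidTransform:
    R = T.rotation
    m = np.eye(4)
    m[:3, :3] = R.T
    m[:3, 3] = -R.T @ T.t
    return RigidTransform(m, center=T.center)


def apply_points(T: RigidTransform, points) -> np.ndarray:
    """Apply a rigid transform to one point or an (n, 3) array of points."""
    p = np.asarray(points, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    if p.shape[1] != 3:
        raise ValueError(f"points must be (n, 3), got {p.shape}")
    out = p @ T.rotation.T + T.t
    return out[0] if single else out


def lat_view_transform(angle_deg: float = 90.0) -> RigidTransform:
    """Transform from the AP view frame to the second (lateral) view frame.

    A rotation by ``angle_deg`` about the cranio-caudal (z) axis; 90 deg
    gives the standard orthogonal biplanar setup.  The viewing direction of
    the AP frame (+x) maps onto the second view's direction.
    """
    if not (0.0 < angle_deg < 180.0):
        raise ValueError(f"view separation must lie in (0, 180) degrees, got {angle_deg}")
    return pose_to_matrix(Pose6DoF(gamma=math.radians(angle_deg)))
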