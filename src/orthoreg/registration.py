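"""Intensity-based 3-D/3-D rigid registration.

Registers a moving CT to a fixed (e.g. reconstructed) CT by minimizing the
voxelwise mean squared error

    MSE(J_T, J_F) = (1/N) * sum_i [J_T(i) - J_F(i)]^2

where J_T is the moving volume resampled under the current pose (trilinear
pull-back) and N counts the voxels admitted by the mask policy — by
default the overlap region, i.e. voxels whose pull-back sample fell inside
the moving grid, so transforms are not rewarded for pushing the volume out
of frame.

Optimization is plain gradient descent on the 6 pose parameters with an
analytic gradient (chain rule through the trilinear pull-back, image
gradient by central differences on the moving grid), a backtracking line
search that only accepts strictly decreasing steps — making the descent
monotone by construction — and an optional coarse-to-fine pyramid for
capture range.  Rotations are scaled by an equivalence radius (mm per
radian) so rotation and translation steps are commensurate.

All per-voxel work (resampling, metric, gradient) is expressed as pure
vectorized maps plus sum-reductions, so results are independent of
evaluation order and chunking up to floating-point reduction noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import (Pose6DoF, invert, pose_to_matrix,
                       rotation_matrix_derivatives)
from .volume import Volume, sample_trilinear

__all__ = ["RegistrationConfig", "RegistrationResult", "mse_3d",
           "mse_gradient", "register"]


@dataclass
class RegistrationConfig:
    """Hyper-parameters of the gradient-descent registration.

    ``rotation_scale_mm`` is the equivalence radius: a rotation of 1 rad is
    treated as a ``rotation_scale_mm`` millimetre move during line search,
    so one step size governs all six parameters.
    """

    max_iterations: int = 200          # per pyramid level
    initial_step_mm: float = 8.0       # first line-search step, scaled-mm units
    backtrack_factor: float = 0.5
    max_backtracks: int = 20
    min_step_mm: float = 1e-3          # give up shrinking below this
    tol_update_deg: float = 5e-4       # pose-update convergence tolerance
    tol_update_mm: float = 5e-4
    tol_rel_mse: float = 1e-9          # relative MSE change tolerance
    rotation_scale_mm: float = 50.0    # mm-per-radian equivalence radius
    pyramid: tuple = (4, 2, 1)         # descending integer downsample factors
    smoothing_sigma_voxels: float = 0.0  # optional per-level smoothing of both volumes
    compass_steps_mm: tuple = (2.0, 0.5, 0.125)  # stall-recovery probe scales
    normalize: bool = False            # z-score intensities before the metric
    fill_value: float = 0.0
    mask_policy: str = "overlap"       # "overlap" or "full"

    def __post_init__(self):
        if self.max_iterations < 1 or self.max_backtracks < 1:
            raise ValueError("iteration counts must be positive")
        for name in ("initial_step_mm", "backtrack_factor", "min_step_mm",
                     "tol_update_deg", "tol_update_mm", "tol_rel_mse",
                     "rotation_scale_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.smoothing_sigma_voxels < 0:
            raise ValueError("smoothing_sigma_voxels must be non-negative")
        if self.backtrack_factor >= 1:
            raise ValueError("backtrack_factor must be < 1")
        fs = tuple(self.pyramid)
        if not fs or any(f < 1 for f in fs) or list(fs) != sorted(fs, reverse=True):
            raise ValueError("pyramid must be a descending list of factors >= 1")
        if self.mask_policy not in ("overlap", "full"):
            raise ValueError("mask_policy must be 'overlap' or 'full'")


@dataclass
class RegistrationResult:
    """Outcome of one registration run."""

    pose: Pose6DoF
    mse: float
    trajectory: list = field(default_factory=list)  # (level, pose, mse) per accepted iterate
    iterations: int = 0
    converged: bool = False
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def to_json_dict(self) -> dict:
        return {
            "pose": self.pose.to_json_dict(self.center),
            "mse": self.mse,
            "iterations": self.iterations,
            "converged": self.converged,
            "trajectory": [
                {"level": lv, "pose": p.to_json_dict(self.center), "mse": m}
                for lv, p, m in self.trajectory
            ],
        }


def mse_3d(transformed: Volume, fixed: Volume, mask=None) -> float:
    """Mean squared voxel difference over the admitted region.

    ``mask`` is an optional boolean array (e.g. the resampling overlap
    mask); ``None`` means all voxels.  An empty mask raises a no-overlap
    error.
    """
    if transformed.shape != fixed.shape:
        raise ValueError(f"volume grids differ: {transformed.shape} vs {fixed.shape}")
    a = transformed.voxels.astype(float)
    b = fixed.voxels.astype(float)
    if mask is None:
        d = a - b
        return float(np.mean(d * d))
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no overlap between volumes (empty mask)")
    d = a[mask] - b[mask]
    return float(np.dot(d, d) / n)


def _grad_volumes(moving: Volume):
    """Central-difference image gradient of the moving volume, mm^-1 units."""
    gx, gy, gz = np.gradient(moving.voxels.astype(float), *moving.spacing)
    sp, org = moving.spacing, moving.origin
    return (Volume(gx, sp, org), Volume(gy, sp, org), Volume(gz, sp, org))


def _pullback_mse(moving: Volume, fixed: Volume, pose: Pose6DoF,
                  center, config: RegistrationConfig):
    """Overlap-masked MSE at ``pose`` plus the cached pull-back state
    (points p, samples q, selection mask, residuals) the gradient reuses.

    The pull-back is q = R^T (p - c - t) + c for every fixed-grid world
    point p; residuals r = J_m(q) - J_F(p) over the admitted region N give
    MSE = (1/N) sum r^2.
    """
    c = np.asarray(center, dtype=float)
    T = pose_to_matrix(pose, c)
    Tinv = invert(T)
    p = fixed.grid_world_coords()
    q = p @ Tinv.rotation.T + Tinv.t

    idx = moving.world_to_index(q)
    upper = np.array(moving.shape) - 1
    inb = np.all((idx >= 0) & (idx <= upper), axis=1)
    sel = inb if config.mask_policy == "overlap" else np.ones(len(q), dtype=bool)
    n = int(sel.sum())
    if n == 0 or not np.any(inb):
        raise ValueError("no overlap between moving and fixed volumes at this pose")

    jt = sample_trilinear(moving, q[sel], fill_value=config.fill_value)
    jf = fixed.voxels.reshape(-1)[sel].astype(float)
    r = jt - jf
    mse = float(np.dot(r, r) / n)
    return mse, (T, p, q, sel, r, n, c)


def _gradient_from_cache(cache, pose: Pose6DoF, grad_vols):
    """Chain-rule MSE gradient reusing the pull-back of :func:`_pullback_mse`:
        dMSE/dt     = -(2/N) R sum r * grad J_m(q)
        dMSE/dtheta =  (2/N) sum r * (dR/dtheta^T (p - c - t)) . grad J_m(q)
    with grad J_m by central differences on the moving grid, sampled at q.
    """
    T, p, q, sel, r, n, c = cache
    g = np.stack([sample_trilinear(gv, q[sel], fill_value=0.0)
                  for gv in grad_vols], axis=1)
    w = p[sel] - c - pose.translation
    dRs = rotation_matrix_derivatives(pose.alpha, pose.beta, pose.gamma)
    grad = np.empty(6)
    for j, dR in enumerate(dRs):
        grad[j] = (2.0 / n) * float(np.dot(r, np.sum(g * (w @ dR), axis=1)))
    grad[3:] = -(2.0 / n) * (T.rotation @ (r @ g))
    return grad


def _mse_and_gradient(moving: Volume, fixed: Volume, pose: Pose6DoF,
                      center, grad_vols, config: RegistrationConfig):
    mse, cache = _pullback_mse(moving, fixed, pose, center, config)
    return mse, _gradient_from_cache(cache, pose, grad_vols)


def mse_gradient(moving: Volume, fixed: Volume, pose: Pose6DoF,
                 config: RegistrationConfig | None = None,
                 center=None) -> np.ndarray:
    """Analytic MSE gradient with respect to (alpha, beta, gamma, tx, ty, tz).

    Rotation components are per radian and translations per millimetre,
    matching central finite differences of :func:`mse_3d` over the pose
    parameters.  The optimizer applies the equivalence-radius scaling on
    top of this raw gradient.
    """
    config = config or RegistrationConfig()
    c = moving.center if center is None else center
    _, grad = _mse_and_gradient(moving, fixed, pose, c, _grad_volumes(moving), config)
    return grad


def _compass_probe(mov_l: Volume, fix_l: Volume, pose: Pose6DoF, center,
                   mse: float, scale: np.ndarray, config: RegistrationConfig):
    """Stall recovery: probe +/- moves of each pose coordinate.

    A noisy target makes the MSE landscape locally rippled; the gradient
    direction can stall in a ripple minimum while a larger single-axis move
    still goes downhill.  Probes each of the 12 signed coordinate
    directions at each scale in ``compass_steps_mm`` (scaled-parameter mm)
    and returns the best strictly-decreasing move at the first scale that
    has one, or None if every probe fails — the convergence certificate.
    """
    base = pose.as_array()
    for st in config.compass_steps_mm:
        best = None
        for i in range(6):
            for sgn in (1.0, -1.0):
                trial_arr = base.copy()
                trial_arr[i] += sgn * st / scale[i]
                trial = Pose6DoF.from_array(trial_arr)
                try:
                    m, cache = _pullback_mse(mov_l, fix_l, trial, center, config)
                except ValueError:
                    continue
                if m < mse and (best is None or m < best[0]):
                    best = (m, trial, cache)
        if best is not None:
            return best + (st,)
    return None


def _downsample(vol: Volume, factor: int) -> Volume:
    """Anti-aliased decimation by an integer factor, preserving world
    coordinates of the kept voxel centres."""
    if factor == 1:
        return vol
    sm = gaussian_filter(vol.voxels.astype(float), sigma=factor / 2.0)
    return Volume(sm[::factor, ::factor, ::factor],
                  vol.spacing * factor, vol.origin.copy())


def register(moving: Volume, fixed: Volume, init: Pose6DoF | None = None,
             config: RegistrationConfig | None = None,
             center=None) -> RegistrationResult:
    """Gradient-descent rigid registration of ``moving`` onto ``fixed``.

    Runs coarse-to-fine over ``config.pyramid``; at each level performs
    normalized-gradient descent with backtracking line search (a step is
    accepted only if the MSE strictly decreases, so the accepted-iterate
    MSE sequence is non-increasing within a level).  Convergence is
    declared when the accepted pose update drops below the tolerance, the
    relative MSE change does, or the line search can no longer find a
    decreasing step.

    Returns the estimated pose (mapping moving into alignment with fixed,
    rotation about ``center`` — default the moving volume's world centre),
    the final full-resolution MSE, and the accepted-iterate trajectory.
    """
    config = config or RegistrationConfig()
    init = init or Pose6DoF()
    c = np.asarray(moving.center if center is None else center, dtype=float)

    if config.normalize:
        moving = _zscore(moving)
        fixed = _zscore(fixed)

    scale = np.array([config.rotation_scale_mm] * 3 + [1.0] * 3)
    pose = init
    trajectory = []
    total_iters = 0
    converged = False

    for level, factor in enumerate(config.pyramid):
        mov_l = _downsample(moving, int(factor))
        fix_l = _downsample(fixed, int(factor))
        if config.smoothing_sigma_voxels > 0:
            # isotropic smoothing commutes with rigid motion, so it leaves
            # the registration optimum in place while flattening the
            # noise-induced ripple that traps the line search
            s = config.smoothing_sigma_voxels
            mov_l = Volume(gaussian_filter(mov_l.voxels.astype(float), s),
                           mov_l.spacing, mov_l.origin)
            fix_l = Volume(gaussian_filter(fix_l.voxels.astype(float), s),
                           fix_l.spacing, fix_l.origin)
        grad_vols = _grad_volumes(mov_l)
        step = config.initial_step_mm
        mse, cache = _pullback_mse(mov_l, fix_l, pose, c, config)
        grad = _gradient_from_cache(cache, pose, grad_vols)
        trajectory.append((level, pose, mse))
        converged = False
        for _ in range(config.max_iterations):
            total_iters += 1
            if mse == 0.0:
                converged = True
                break
            # scaled parameters: s_rot = theta * radius (mm-like), s_trans = t
            gs = grad / scale
            gnorm = float(np.linalg.norm(gs))
            if gnorm == 0.0:
                converged = True
                break
            # steepest descent along -gs; the step length (in scaled mm) is
            # adapted by the line search, starting from the last accepted one
            direction = -(gs / gnorm) / scale
            accepted = False
            for _bt in range(config.max_backtracks):
                trial = Pose6DoF.from_array(pose.as_array() + step * direction)
                try:
                    mse_t, cache_t = _pullback_mse(mov_l, fix_l, trial, c, config)
                except ValueError:
                    mse_t = np.inf
                if mse_t < mse:
                    accepted = True
                    break
                step *= config.backtrack_factor
                if step < config.min_step_mm:
                    break
            if not accepted:
                probe = _compass_probe(mov_l, fix_l, pose, c, mse, scale, config)
                if probe is None:
                    converged = True
                    break
                mse_t, trial, cache_t, st = probe
                step = max(st, 8 * config.min_step_mm)
                accepted = True
            upd = np.abs(trial.as_array() - pose.as_array())
            rel = (mse - mse_t) / mse if mse > 0 else 0.0
            pose, mse = trial, mse_t
            grad = _gradient_from_cache(cache_t, pose, grad_vols)
            trajectory.append((level, pose, mse))
            # convergence: tiny accepted update while the line search is
            # already operating at a small step, or negligible MSE gain
            small_update = (np.all(np.degrees(upd[:3]) < config.tol_update_deg)
                            and np.all(upd[3:] < config.tol_update_mm))
            if small_update and step <= 4 * config.min_step_mm:
                converged = True
                break
            if rel < config.tol_rel_mse:
                converged = True
                break
            step = min(step * 2.0, config.initial_step_mm)

    # final full-resolution metric; guard against a pyramid excursion that
    # ends worse than where it started
    final_mse, _ = _pullback_mse(moving, fixed, pose, c, config)
    init_mse, _ = _pullback_mse(moving, fixed, init, c, config)
    if final_mse > init_mse:
        pose, final_mse, converged = init, init_mse, False
    return RegistrationResult(pose=pose, mse=final_mse, trajectory=trajectory,
                              iterations=total_iters, converged=converged,
                              center=c)


def _zscore(vol: Volume) -> Volume:
    v = vol.voxels.astype(float)
    sd = v.std()
    if sd == 0:
        return Volume(v - v.mean(), vol.spacing.copy(), vol.origin.copy())
    return Volume((v - v.mean()) / sd, vol.spacing.copy(), vol.origin.copy())
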