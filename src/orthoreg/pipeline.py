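"""End-to-end pipeline: phantom -> (pseudo-)reconstruction -> registration
-> evaluation.

The two-stage design keeps the reconstruction step pluggable: anything
that turns a biplanar radiograph pair into a volume on the moving CT's
grid can serve as the fixed target.  Here the bundled simulator
(:func:`orthoreg.benchmark.pseudo_reconstruct`) supplies that target, so
the whole loop runs at desk scale with no trained network and no external
data; an externally reconstructed volume can be substituted per case.

All randomness flows from one integer seed; re-running a configuration
reproduces the report bit-for-bit up to floating-point reduction noise.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from .benchmark import (default_benchmark_geometry, generate_case,
                        make_phantom, pseudo_reconstruct,
                        reconstruction_degradation, sample_pose)
from .evaluation import FAILURE_THRESHOLD_MM, EvaluationReport, evaluate_cases
from .geometry import pose_to_matrix
from .preprocess import threshold_bone
from .registration import RegistrationConfig, register
from .volume import write_volume

__all__ = ["E2EConfig", "run_e2e"]


@dataclass
class E2EConfig:
    """Configuration of one end-to-end run (all seeds explicit)."""

    n_cases: int = 10
    seed: int = 0
    shape: tuple = (64, 64, 64)
    spacing: tuple = (2.0, 2.0, 2.0)
    rot_range_deg: float = 10.0
    trans_range_mm: float = 20.0
    angle_deg: float = 90.0
    contrast: str = "mid"
    blur_sigma: float = 1.0        # reconstruction degradation at 90 degrees
    noise_frac: float = 0.05
    intensity_scale: float = 1.0
    angle_scales_degradation: bool = True
    threshold_mm: float = FAILURE_THRESHOLD_MM
    render_cases: bool = False     # also render benchmark DRRs per case
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        d["spacing"] = list(self.spacing)
        d["registration"]["pyramid"] = list(self.registration.pyramid)
        return d


def run_e2e(config: E2EConfig, out_dir=None) -> EvaluationReport:
    """Run the full pipeline and return the evaluation report.

    Per case: build a seeded phantom, threshold it to bone, draw a hidden
    ground-truth pose from the augmentation range, simulate the
    reconstructed target at that pose, register the bone volume to the
    target from the identity initialization, and score mTRE / per-DoF
    errors.  Artifacts (volumes, DRRs, manifest, report) are written when
    ``out_dir`` is given.
    """
    if config.n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if config.angle_scales_degradation:
        blur, noise = reconstruction_degradation(
            config.angle_deg, config.blur_sigma, config.noise_frac)
    else:
        blur, noise = config.blur_sigma, config.noise_frac

    rng = np.random.default_rng(config.seed)
    case_seeds = rng.integers(0, 2 ** 31 - 1, size=config.n_cases)

    case_ids, regs, gts, lm_sets, centers = [], [], [], [], []
    extras_cases = []
    for i, cs in enumerate(case_seeds):
        cs = int(cs)
        phantom, landmarks = make_phantom(cs, config.shape, config.spacing)
        bone = threshold_bone(phantom)
        pose_gt = sample_pose(cs + 1, config.rot_range_deg, config.trans_range_mm)
        fixed = pseudo_reconstruct(bone, pose_gt, blur, noise,
                                   config.intensity_scale, seed=cs + 2)
        result = register(bone, fixed, config=config.registration)
        center = bone.center
        case_ids.append(f"case_{i:04d}")
        regs.append(pose_to_matrix(result.pose, center))
        gts.append(pose_to_matrix(pose_gt, center))
        lm_sets.append(landmarks)
        centers.append(center)
        extras_cases.append({"seed": cs, "iterations": result.iterations,
                             "converged": result.converged,
                             "final_mse": result.mse})
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            write_volume(fixed, os.path.join(out_dir, f"case_{i:04d}_target.nii.gz"))
            if config.render_cases:
                from .projector import save_drr

                case = generate_case(bone, landmarks, pose_gt,
                                     angle_deg=config.angle_deg,
                                     contrast=config.contrast, seed=cs,
                                     case_id=f"case_{i:04d}")
                save_drr(case.ap, os.path.join(out_dir, f"case_{i:04d}_ap.png"))
                save_drr(case.lat, os.path.join(out_dir, f"case_{i:04d}_lat.png"))

    report = evaluate_cases(case_ids, regs, gts, lm_sets, centers,
                            threshold=config.threshold_mm)
    report.extras["config"] = config.to_json_dict()
    report.extras["per_case_runs"] = extras_cases
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report.to_json_dict(), fh, indent=2)
        with open(os.path.join(out_dir, "report.csv"), "w") as fh:
            fh.write(report.to_csv())
    return report
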