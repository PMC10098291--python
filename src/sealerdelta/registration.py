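"""Rigid superimposition of follow-up scans on their baseline.

Two stages, mirroring routine longitudinal surface-scan workflows: a
least-squares landmark alignment (orthogonal Procrustes with reflection
excluded) provides the initialization, and a trimmed point-to-point
iterative-closest-point (ICP) refinement polishes the pose.  Because the
sealer region genuinely changes between scans, correspondences above a
residual quantile are discarded each iteration and the sampling can be
restricted to the unchanged shaft side of the cutting plane, so the moving
material does not drag the fit.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import DegenerateConfigurationError, ValidationError
from .geometry import SurfaceLocator, sample_surface
from .transforms import LandmarkSet, RigidTransform


def kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping paired *source* onto *target*.

    Minimizes ``sum_i || R s_i + t - t_i ||^2`` over proper rotations
    (SVD solution; a reflection is corrected by flipping the smallest
    singular direction).
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValidationError("paired (n, 3) point sets required")
    cs = src.mean(axis=0)
    ct = tgt.mean(axis=0)
    H = (src - cs).T @ (tgt - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, ct - R @ cs)


def landmark_align(source: LandmarkSet, target: LandmarkSet) -> RigidTransform:
    """Initial rigid registration from manually placed landmarks.

    Labels are matched across the two sets; both configurations must contain
    at least three non-collinear points, otherwise the pose is
    underdetermined and a :class:`DegenerateConfigurationError` is raised.
    """
    src_pts, tgt_pts = source.matched(target)
    source.require_noncollinear()
    target.require_noncollinear()
    return kabsch(src_pts, tgt_pts)


@dataclass(frozen=True)
class ICPConfig:
    max_iterations: int = 100
    convergence_tol: float = 1e-5        # mm change in trimmed mean residual
    sample_count: int = 800              # points sampled from the moving surface
    correspondence_rejection_quantile: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if self.max_iterations < 1 or self.sample_count < 1:
            raise ValidationError("iterations and sample count must be positive")
        if self.convergence_tol <= 0:
            raise ValidationError("convergence tolerance must be positive")
        q = self.correspondence_rejection_quantile
        if not (0.0 < q <= 1.0):
            raise ValidationError("rejection quantile must lie in (0, 1]")


@dataclass
class ConvergenceReport:
    iterations: int
    residuals: list = field(default_factory=list)
    converged: bool = False
    n_samples: int = 0

    @property
    def final_residual(self) -> float:
        return self.residuals[-1] if self.residuals else float("nan")


def icp_refine(moving, fixed, init: RigidTransform | None = None,
               cfg: ICPConfig | None = None, exclude_plane=None):
    """Trimmed point-to-point ICP of *moving* onto *fixed*.

    Parameters
    ----------
    init : initial pose (e.g. from :func:`landmark_align`); identity if None.
    exclude_plane : optional :class:`~sealerdelta.volumetry.CuttingPlane`
        whose positive (away-from-ROI) side selects the sample region, so the
        changing sealer below the plane never enters the correspondence set.

    Returns ``(transform, report)``.  Non-convergence within the iteration
    budget is reported, not raised.  The trimmed mean residual is
    non-increasing over the retained iterations: an update that would
    increase it is rejected and the search stops at the previous pose.
    """
    if len(moving.faces) == 0 or len(fixed.faces) == 0:
        raise ValidationError("ICP requires two non-empty meshes")
    cfg = cfg or ICPConfig()
    T = init or RigidTransform.identity()
    rng = np.random.default_rng(cfg.seed)
    samples, _ = sample_surface(moving, cfg.sample_count, rng)
    if exclude_plane is not None:
        keep = exclude_plane.signed_distance(T.apply(samples)) >= 0.0
        if keep.sum() >= 10:  # need enough support to constrain the pose
            samples = samples[keep]
    locator = SurfaceLocator(fixed)
    q = cfg.correspondence_rejection_quantile

    report = ConvergenceReport(iterations=0, n_samples=len(samples))
    prev = np.inf
    T_prev = T
    for it in range(cfg.max_iterations):
        x = T.apply(samples)
        cp, d, _ = locator.closest(x)
        cutoff = np.quantile(d, q) if q < 1.0 else np.inf
        keep = d <= cutoff
        res = float(d[keep].mean())
        if res > prev + 1e-15:
            # update made the trimmed residual worse: revert and stop
            T = T_prev
            report.converged = True
            break
        report.residuals.append(res)
        report.iterations = it + 1
        if prev - res < cfg.convergence_tol:
            report.converged = True
            break
        prev = res
        T_prev = T
        T = kabsch(samples[keep], cp[keep]).orthonormalized()
    return T, report


def apply_transform(mesh, T: RigidTransform):
    """Return a copy of *mesh* with vertices mapped ``v -> R v + t``.

    Topology is untouched; rigid motion preserves areas and volumes.
    """
    out = trimesh.Trimesh(vertices=T.apply(mesh.vertices),
                          faces=np.array(mesh.faces, copy=True),
                          process=False)
    return out
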