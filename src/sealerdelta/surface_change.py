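"""Profilometric surface change: signed point-to-surface distances between
superimposed ROI surfaces, their RMS summary, and the increase / no-change /
decrease classification used for color maps.

Distances are sampled one-directionally, follow-up onto baseline (each
follow-up scan is superimposed on its own baseline model).  The sign follows
the baseline's outward orientation: positive means the follow-up surface lies
outside the baseline (dimensional increase), negative inside (decrease).  The
RMS uses unsigned magnitudes, so it expresses the size of the change without
its direction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import ValidationError
from .geometry import SurfaceLocator, sample_surface
from .registration import ICPConfig, icp_refine
from .transforms import RigidTransform


@dataclass
class DistanceMap:
    sample_points: np.ndarray       # (n, 3), on the follow-up surface (mm)
    signed_distance: np.ndarray     # (n,), mm; positive = increase
    seed: int | None = None

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.sample_points, dtype=float))
        d = np.asarray(self.signed_distance, dtype=float).ravel()
        if len(pts) != len(d) or len(d) < 1:
            raise ValidationError("distance map needs >= 1 paired sample")
        if not np.all(np.isfinite(d)):
            raise ValidationError("distances must be finite")
        self.sample_points = pts
        self.signed_distance = d

    @property
    def n(self) -> int:
        return len(self.signed_distance)

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.sample_points, self.signed_distance])
        np.savetxt(path, arr, delimiter=",", header="x,y,z,d", comments="")


def best_fit_superimpose(followup, baseline, init: RigidTransform | None = None,
                         cfg: ICPConfig | None = None, return_report: bool = False):
    """Best-fit rigid superimposition of the follow-up on the baseline.

    Thin wrapper over the trimmed ICP refinement, with identity (or a
    supplied landmark transform) as initialization.
    """
    T, report = icp_refine(followup, baseline, init=init, cfg=cfg)
    return (T, report) if return_report else T


def signed_distances(followup_roi, baseline_roi, sample_count: int = 2000,
                     seed: int = 0) -> DistanceMap:
    """Signed closest distances from the follow-up ROI to the baseline ROI.

    ``sample_count`` points are drawn uniformly by area from the follow-up
    surface (seeded, reproducible).  Each is assigned its unsigned closest
    distance to the baseline surface, signed by the side of the nearest
    baseline facet the sample lies on (outward normal positive).
    """
    if len(followup_roi.faces) == 0 or len(baseline_roi.faces) == 0:
        raise ValidationError("signed distances require two non-empty meshes")
    if sample_count < 1:
        raise ValidationError("sample_count must be >= 1")
    rng = np.random.default_rng(seed)
    pts, _ = sample_surface(followup_roi, sample_count, rng)
    locator = SurfaceLocator(baseline_roi)
    cp, d, tri = locator.closest(pts)
    side = np.einsum("ij,ij->i", pts - cp, locator.face_normals[tri])
    sign = np.where(side >= 0, 1.0, -1.0)
    return DistanceMap(pts, sign * d, seed=seed)


def rms(dmap: DistanceMap) -> float:
    """Root-mean-square surface offset: sqrt(mean of squared distances), mm.

    Squaring removes the sign, so the RMS accounts for the absolute offset
    between the overlapping models.
    """
    return float(np.sqrt(np.mean(dmap.signed_distance ** 2)))


@dataclass
class ChangeClassification:
    threshold: float                       # tau, mm
    labels: np.ndarray                     # per-point, in {-1, 0, +1}
    fractions: dict = field(default_factory=dict)

    LABEL_NAMES = {-1: "decrease", 0: "no_change", 1: "increase"}


def classify_change(dmap: DistanceMap, threshold: float = 0.05) -> ChangeClassification:
    """Classify each sample: increase (d > tau), decrease (d < -tau), else
    no change.  ``tau`` defaults to 0.05 mm and must be logged with results —
    it is a configuration value, not a measured quantity."""
    if threshold <= 0:
        raise ValidationError("classification threshold must be positive")
    d = dmap.signed_distance
    labels = np.zeros(len(d), dtype=int)
    labels[d > threshold] = 1
    labels[d < -threshold] = -1
    n = len(d)
    fractions = {name: float((labels == code).sum()) / n
                 for code, name in ChangeClassification.LABEL_NAMES.items()}
    return ChangeClassification(threshold=float(threshold), labels=labels,
                                fractions=fractions)


def color_mesh_by_change(followup_roi, baseline_roi, threshold: float = 0.05,
                         scale_mm: float | None = None):
    """Follow-up ROI with per-vertex colors encoding the signed distance to
    the baseline (blue/purple = decrease, green = no change, yellow/red =
    increase).  Export the result as PLY to inspect change maps."""
    locator = SurfaceLocator(baseline_roi)
    v = np.asarray(followup_roi.vertices, dtype=float)
    cp, d, tri = locator.closest(v)
    side = np.einsum("ij,ij->i", v - cp, locator.face_normals[tri])
    sd = np.where(side >= 0, 1.0, -1.0) * d
    span = scale_mm or max(3.0 * threshold, np.abs(sd).max(), 1e-9)
    x = np.clip(sd / span, -1.0, 1.0)
    colors = np.zeros((len(v), 4), dtype=np.uint8)
    colors[:, 3] = 255
    inc = x > 0
    colors[inc, 0] = np.uint8(255 * x[inc])          # toward red
    colors[inc, 1] = np.uint8(255 * (1 - x[inc]))
    colors[~inc, 2] = np.uint8(255 * (-x[~inc]))     # toward blue
    colors[~inc, 1] = np.uint8(255 * (1 + x[~inc]))
    within = np.abs(sd) <= threshold
    colors[within] = (0, 255, 0, 255)                # no change: green
    out = trimesh.Trimesh(vertices=v, faces=np.asarray(followup_roi.faces).copy(),
                          process=False)
    out.visual.vertex_colors = colors
    return out
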