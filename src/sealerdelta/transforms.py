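"""Rigid-body transforms and labelled landmark sets.

All coordinates are millimetres.  A :class:`RigidTransform` maps points
``v -> R @ v + t`` with a proper rotation ``R`` (orthonormal, det +1); the
group operations (composition, inversion) are closed, which the scan
superimposition pipeline relies on when chaining the landmark initialization
with the ICP refinement.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import CorrespondenceError, DegenerateConfigurationError, ValidationError

#: tolerance for orthonormality / unit-determinant checks
ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValidationError("non-finite transform entries")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-6:
            raise ValidationError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValidationError("rotation matrix must have determinant +1 (no reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- group operations -------------------------------------------------
    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array (or single point) through the transform."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self o other`` (apply *other* first, then *self*)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def orthonormalized(self) -> "RigidTransform":
        """Project the rotation back onto SO(3) (guards against drift)."""
        U, _, Vt = np.linalg.svd(self.rotation)
        d = np.sign(np.linalg.det(U @ Vt))
        R = U @ np.diag([1.0, 1.0, d]) @ Vt
        return RigidTransform(R, self.translation)

    # -- diagnostics -------------------------------------------------------
    def rotation_angle_deg(self) -> float:
        """Rotation magnitude in degrees (axis-angle)."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def translation_norm(self) -> float:
        return float(np.linalg.norm(self.translation))

    # -- serialization -----------------------------------------------------
    def to_matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    @staticmethod
    def from_matrix(M) -> "RigidTransform":
        M = np.asarray(M, dtype=float)
        if M.shape != (4, 4):
            raise ValidationError("homogeneous transform must be 4x4")
        return RigidTransform(M[:3, :3], M[:3, 3])

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({"matrix": self.to_matrix().tolist()}, indent=2))

    @staticmethod
    def from_json(path) -> "RigidTransform":
        data = json.loads(Path(path).read_text())
        return RigidTransform.from_matrix(np.asarray(data["matrix"]))


def random_small_transform(rng: np.random.Generator,
                           max_angle_deg: float = 10.0,
                           max_shift_mm: float = 2.0) -> RigidTransform:
    """Random rigid motion emulating per-session specimen placement.

    The rotation axis is uniform on the sphere, the angle uniform in
    ``[0, max_angle_deg]`` and the translation uniform in the cube of
    half-width ``max_shift_mm``.
    """
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, max_angle_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    t = rng.uniform(-max_shift_mm, max_shift_mm, size=3)
    return RigidTransform(R, t)


@dataclass(frozen=True)
class LandmarkSet:
    """Ordered, labelled 3D points; correspondence across scans is by label."""

    points: np.ndarray
    labels: tuple = field(default=None)

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValidationError("landmarks must be an (n, 3) array")
        if not np.all(np.isfinite(pts)):
            raise ValidationError("landmark coordinates must be finite")
        labels = self.labels
        if labels is None:
            labels = tuple(f"L{i + 1}" for i in range(len(pts)))
        labels = tuple(str(x) for x in labels)
        if len(labels) != len(pts):
            raise ValidationError("one label per landmark required")
        if len(set(labels)) != len(labels):
            raise ValidationError("landmark labels must be unique")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "labels", labels)

    def __len__(self):
        return len(self.points)

    def matched(self, other: "LandmarkSet"):
        """Return (self_points, other_points) reordered by shared labels."""
        if set(self.labels) != set(other.labels):
            raise CorrespondenceError(
                f"landmark label mismatch: {self.labels} vs {other.labels}")
        idx = [other.labels.index(lab) for lab in self.labels]
        return self.points, other.points[idx]

    def require_noncollinear(self, tol: float = 1e-9):
        if len(self) < 3:
            raise DegenerateConfigurationError("at least 3 landmarks required")
        centered = self.points - self.points.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        if s[1] <= tol * max(s[0], 1.0):
            raise DegenerateConfigurationError("landmarks are collinear")

    def transformed(self, T: RigidTransform) -> "LandmarkSet":
        return LandmarkSet(T.apply(self.points), self.labels)

    # plain-text file format: one "x y z" triple per line, millimetres;
    # labels are implicit in line order (L1, L2, ...)
    def to_file(self, path) -> None:
        lines = [" ".join(f"{c:.9f}" for c in p) for p in self.points]
        Path(path).write_text("\n".join(lines) + "\n")

    @staticmethod
    def from_file(path) -> "LandmarkSet":
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append([float(x) for x in line.split()[:3]])
        if not rows:
            raise ValidationError(f"no landmarks found in {path}")
        return LandmarkSet(np.asarray(rows))
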