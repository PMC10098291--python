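"""ROI volumetry: cut registered scans with a shared plane, close the apical
pieces, and difference their volumes.

The cutting plane is defined once, on the baseline scan, from the three shaft
landmarks; after rigid superimposition the *same* plane cuts baseline and
follow-up at the identical anatomical level, so the shaft contribution to the
enclosed ROI volume cancels in the difference and only sealer change remains.

Sign convention: ``delta_V = Vi - V0`` so that material loss is negative
(matching how longitudinal loss estimates are conventionally tabulated);
``loss_negative=False`` flips to the ``V0 - Vi`` reading.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from trimesh.intersections import slice_mesh_plane

from .errors import ClosureError, DegenerateConfigurationError, EmptyROIError, ValidationError
from .transforms import LandmarkSet

#: signed-distance tolerance (mm) for on-plane classification
PLANE_TOL = 1e-9


@dataclass(frozen=True)
class CuttingPlane:
    """Plane through ``point`` with unit ``normal`` pointing AWAY from the ROI
    (toward the retained, unchanging shaft)."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or norm < 1e-12:
            raise ValidationError("plane normal must be a nonzero vector")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n / norm)

    def signed_distance(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.point) @ self.normal

    def flipped(self) -> "CuttingPlane":
        return CuttingPlane(self.point, -self.normal)

    def to_dict(self):
        return {"point": self.point.tolist(), "normal": self.normal.tolist()}

    @staticmethod
    def from_dict(d) -> "CuttingPlane":
        return CuttingPlane(np.asarray(d["point"]), np.asarray(d["normal"]))


def plane_from_landmarks(landmarks: LandmarkSet, mesh=None,
                         roi_point=None) -> CuttingPlane:
    """Plane through three landmarks, oriented away from the ROI.

    The three shaft landmarks define the separation level.  The ROI side is
    resolved either by an explicit ``roi_point`` (e.g. the sealer blob
    centroid) or, given ``mesh``, by the vertex of greatest distance from the
    plane — the apical tip heuristic.  With neither, the sign is canonical
    (largest-magnitude normal component positive).  The result is invariant
    to landmark ordering.
    """
    if len(landmarks) != 3:
        raise DegenerateConfigurationError("exactly 3 landmarks define the cutting plane")
    landmarks.require_noncollinear()
    p0, p1, p2 = landmarks.points
    n = np.cross(p1 - p0, p2 - p0)
    n = n / np.linalg.norm(n)
    # canonical sign first, so landmark permutations give an identical plane
    k = int(np.argmax(np.abs(n)))
    if n[k] < 0:
        n = -n
    plane = CuttingPlane(p0, n)
    ref = None
    if roi_point is not None:
        ref = np.asarray(roi_point, dtype=float)
    elif mesh is not None:
        d = plane.signed_distance(mesh.vertices)
        ref = np.asarray(mesh.vertices)[int(np.argmax(np.abs(d)))]
    if ref is not None and plane.signed_distance(ref[None, :])[0] > 0:
        plane = plane.flipped()
    return plane


def cut_mesh(mesh, plane: CuttingPlane):
    """Open ROI piece of *mesh*: triangles on the ROI side of *plane*.

    Straddling triangles are split exactly at the plane, leaving boundary
    loops lying in the plane.  Raises :class:`EmptyROIError` when the plane
    leaves nothing on the ROI side.
    """
    # the ROI is on the side the stored normal points away from
    piece = slice_mesh_plane(mesh, plane_normal=-plane.normal,
                             plane_origin=plane.point, cap=False)
    if piece is None or len(piece.faces) == 0:
        raise EmptyROIError("cutting plane leaves no ROI piece")
    out = trimesh.Trimesh(vertices=np.asarray(piece.vertices, dtype=float),
                          faces=np.asarray(piece.faces), process=False)
    # weld coincident vertices introduced by the triangle splits so the cut
    # boundary chains into loops
    out.merge_vertices()
    out.update_faces(out.nondegenerate_faces(height=1e-12))
    out.remove_unreferenced_vertices()
    return out


def boundary_loops(mesh):
    """Ordered boundary loops (lists of vertex indices) of an open mesh.

    Boundary edges are the directed face edges without an opposing partner;
    for a manifold-with-boundary surface they chain into closed loops.
    """
    edges = np.asarray(mesh.edges)  # directed, 3 per face
    key = np.sort(edges, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    bdir = edges[counts[inv] == 1]
    if len(bdir) == 0:
        return []
    nxt = {}
    for a, b in bdir:
        if a in nxt:
            raise ClosureError("non-manifold boundary (branching loop)", loops=[[int(a)]])
        nxt[int(a)] = int(b)
    loops = []
    remaining = set(nxt)
    while remaining:
        start = min(remaining)  # deterministic loop ordering
        loop = [start]
        remaining.discard(start)
        cur = nxt[start]
        while cur != start:
            if cur not in remaining:
                raise ClosureError("open boundary chain does not close", loops=[loop])
            loop.append(cur)
            remaining.discard(cur)
            cur = nxt[cur]
        loops.append(loop)
    return loops


def _ear_clip(points2d):
    """Triangulate a simple polygon by ear clipping; returns index triples."""
    n = len(points2d)
    idx = list(range(n))
    # ensure counter-clockwise orientation
    area2 = 0.0
    for i in range(n):
        x1, y1 = points2d[i]
        x2, y2 = points2d[(i + 1) % n]
        area2 += x1 * y2 - x2 * y1
    if area2 < 0:
        idx.reverse()
    tris = []
    guard = 0
    while len(idx) > 3 and guard < 4 * n * n:
        guard += 1
        for j in range(len(idx)):
            a, b, c = idx[j - 1], idx[j], idx[(j + 1) % len(idx)]
            pa, pb, pc = points2d[a], points2d[b], points2d[c]
            cross = (pb[0] - pa[0]) * (pc[1] - pa[1]) - (pb[1] - pa[1]) * (pc[0] - pa[0])
            if cross <= 0:
                continue  # reflex corner
            # no other polygon vertex inside the candidate ear
            ok = True
            for k in idx:
                if k in (a, b, c):
                    continue
                p = points2d[k]
                d1 = (pb[0] - pa[0]) * (p[1] - pa[1]) - (pb[1] - pa[1]) * (p[0] - pa[0])
                d2 = (pc[0] - pb[0]) * (p[1] - pb[1]) - (pc[1] - pb[1]) * (p[0] - pb[0])
                d3 = (pa[0] - pc[0]) * (p[1] - pc[1]) - (pa[1] - pc[1]) * (p[0] - pc[0])
                if d1 >= 0 and d2 >= 0 and d3 >= 0:
                    ok = False
                    break
            if ok:
                tris.append((a, b, c))
                idx.pop(j)
                break
        else:
            raise ClosureError("ear clipping failed (self-intersecting boundary loop?)")
    tris.append(tuple(idx))
    return tris


def close_mesh(open_roi):
    """Cap every boundary loop of *open_roi*, returning a watertight mesh.

    Planar loops from a plane cut are star-shaped about their centroid in
    practice, so each loop is capped by a centroid fan; should the fan
    degenerate, an ear-clipping triangulation of the loop is used instead.
    An already-closed mesh is returned unchanged.  The output is oriented so
    the enclosed signed volume is positive (outward normals).
    """
    loops = boundary_loops(open_roi)
    if not loops:
        return open_roi
    V = np.asarray(open_roi.vertices, dtype=float)
    F = [np.asarray(open_roi.faces)]
    newverts = []
    nv = len(V)
    for loop in loops:
        pts = V[loop]
        centroid = pts.mean(axis=0)
        # fan validity: all fan triangles must have nonvanishing area
        e1 = pts - centroid
        e2 = np.roll(pts, -1, axis=0) - centroid
        areas = np.linalg.norm(np.cross(e1, e2), axis=1)
        scale = max(np.ptp(pts), 1.0)
        if np.all(areas > 1e-12 * scale * scale):
            cidx = nv + len(newverts)
            newverts.append(centroid)
            m = len(loop)
            # boundary edge (loop[i] -> loop[i+1]) appears in existing faces;
            # the cap triangle reverses it to keep the winding consistent
            fan = np.array([[loop[(i + 1) % m], loop[i], cidx] for i in range(m)])
            F.append(fan)
        else:
            # fall back to ear clipping in the loop's best-fit plane
            c = pts.mean(axis=0)
            u, s, vt = np.linalg.svd(pts - c)
            basis = vt[:2]
            p2 = (pts - c) @ basis.T
            tris = _ear_clip(p2)
            F.append(np.array([[loop[b], loop[a], loop[c_]] for a, b, c_ in tris]))
    allv = np.vstack([V] + newverts) if newverts else V
    closed = trimesh.Trimesh(vertices=allv, faces=np.vstack(F), process=False)
    if len(boundary_loops(closed)) != 0:
        raise ClosureError("capping did not produce a watertight surface", loops=loops)
    if _signed_volume(closed) < 0:
        closed.invert()
    return closed


def _signed_volume(mesh) -> float:
    tri = np.asarray(mesh.triangles, dtype=float)
    return float(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0)


def mesh_volume(closed) -> float:
    """Enclosed volume of a watertight mesh by the divergence theorem:
    ``V = | sum_faces v1 . (v2 x v3) / 6 |``.

    Raises a :class:`ValidationError` reporting the boundary-edge count when
    the input is not watertight.
    """
    edges = np.asarray(closed.edges)
    key = np.sort(edges, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    n_boundary = int((counts[inv] == 1).sum())
    if n_boundary:
        raise ValidationError(
            f"mesh is not watertight: {n_boundary} boundary edges")
    if not closed.is_winding_consistent:
        raise ValidationError("mesh winding is inconsistent; orientation "
                              "must be consistent for a volume")
    return abs(_signed_volume(closed))


def volume_noise_floor(mesh, noise_sd: float) -> float:
    """1-sigma volume uncertainty from i.i.d. normal-direction surface noise.

    A vertex displacement delta along the normal perturbs the enclosed volume
    by ~ delta * A_v, with A_v one third of the adjacent face area, so
    ``sigma_V = noise_sd * sqrt(sum A_v^2)``.  For a scan *pair* the floors
    add in quadrature.
    """
    areas = np.asarray(mesh.area_faces, dtype=float)
    a_v = np.zeros(len(mesh.vertices))
    np.add.at(a_v, np.asarray(mesh.faces).ravel(),
              np.repeat(areas / 3.0, 3))
    return float(noise_sd * np.sqrt((a_v ** 2).sum()))


def volume_change(V0: float, Vi: float, loss_negative: bool = True) -> float:
    """Volume change of the closed ROI between baseline (V0) and follow-up (Vi).

    Default returns ``Vi - V0`` (loss negative); ``loss_negative=False``
    returns the ``V0 - Vi`` convention instead.
    """
    return (Vi - V0) if loss_negative else (V0 - Vi)


@dataclass
class ROIVolumeRecord:
    specimen_id: str
    time_label: str
    V: float                      # closed ROI volume, mm^3
    delta_V: float = 0.0          # Vi - V0, mm^3 (0 at baseline)
    group: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.V <= 0:
            raise ValidationError("ROI volume must be positive")
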