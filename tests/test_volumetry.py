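import numpy as np
import pytest
import trimesh
from scipy.spatial import ConvexHull

from sealerdelta.errors import DegenerateConfigurationError, EmptyROIError, \
    ValidationError
from sealerdelta.registration import apply_transform
from sealerdelta.transforms import LandmarkSet, RigidTransform
from sealerdelta.volumetry import CuttingPlane, ROIVolumeRecord, close_mesh, \
    cut_mesh, mesh_volume, plane_from_landmarks, volume_change

from conftest import random_rotation


def unit_cube():
    return trimesh.creation.box(extents=(1.0, 1.0, 1.0))  # centered at origin


class TestPlaneFromLandmarks:
    def test_axis_aligned_plane(self):
        lm = LandmarkSet(np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]))
        plane = plane_from_landmarks(lm)
        assert np.allclose(np.abs(plane.normal), [0, 0, 1.0], atol=1e-12)
        plane2 = plane_from_landmarks(lm, roi_point=[0, 0, -5.0])
        assert np.allclose(plane2.normal, [0, 0, 1.0], atol=1e-12)

    def test_invariant_to_landmark_permutation(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(3, 3))
        planes = [plane_from_landmarks(LandmarkSet(pts[list(perm)]))
                  for perm in [(0, 1, 2), (1, 2, 0), (2, 1, 0)]]
        for p in planes[1:]:
            assert np.allclose(p.normal, planes[0].normal, atol=1e-12)
            assert abs(planes[0].signed_distance(p.point[None])[0]) < 1e-9

    def test_collinear_raises(self):
        lm = LandmarkSet(np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]]))
        with pytest.raises(DegenerateConfigurationError):
            plane_from_landmarks(lm)

    def test_separates_blob_from_shaft_on_phantom(self, coarse_baseline):
        """The landmark plane puts the sealer centroid on the negative (ROI)
        side and the shaft-top centroid on the positive side."""
        plane = plane_from_landmarks(coarse_baseline.landmarks,
                                     mesh=coarse_baseline.mesh)
        blob_c = coarse_baseline.sealer_mesh.vertices.mean(axis=0)
        top = coarse_baseline.root_mesh.vertices[
            np.argsort(plane.signed_distance(coarse_baseline.root_mesh.vertices))[-50:]
        ].mean(axis=0)
        assert plane.signed_distance(blob_c[None])[0] < 0
        assert plane.signed_distance(top[None])[0] > 0


class TestCutMesh:
    def test_unit_cube_half_cut(self):
        """Cutting z=0.25 keeps an open box whose boundary vertices all lie
        exactly in the plane; closing gives the half-space volume."""
        plane = CuttingPlane([0, 0, 0.25], [0, 0, 1.0])  # ROI below
        piece = cut_mesh(unit_cube(), plane)
        # open piece: boundary loop lies in the plane
        sd = plane.signed_distance(piece.vertices)
        assert sd.max() < 1e-9
        closed = close_mesh(piece)
        assert closed.is_watertight
        assert abs(mesh_volume(closed) - 0.75) < 1e-9

    def test_plane_missing_mesh_raises(self):
        plane = CuttingPlane([0, 0, 10.0], [0, 0, -1.0])  # ROI above z=10
        with pytest.raises(EmptyROIError):
            cut_mesh(unit_cube(), plane)

    def test_plane_grazing_vertex_emits_no_degenerate_faces(self):
        octa = trimesh.creation.icosphere(subdivisions=0)  # vertices on axes
        plane = CuttingPlane([0, 0, 1.0], [0, 0, 1.0])     # grazes apex vertex
        # grazing from below keeps the whole solid
        whole = close_mesh(cut_mesh(octa, plane))
        assert whole.is_watertight
        assert abs(mesh_volume(whole) - mesh_volume(octa)) < 1e-9
        areas = whole.area_faces
        assert areas.min() > 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_convex_polyhedron_matches_halfspace_clip_oracle(self, seed):
        """Cut + close volume of a random convex polyhedron equals the exact
        convex half-space clip (qhull oracle) to 1e-9."""
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(40, 3))
        hull_mesh = trimesh.convex.convex_hull(pts)
        plane = CuttingPlane(rng.normal(scale=0.3, size=3),
                             rng.normal(size=3))
        try:
            piece = cut_mesh(hull_mesh, plane)
        except EmptyROIError:
            return
        vol = mesh_volume(close_mesh(piece))
        oracle = _convex_clip_volume(np.asarray(hull_mesh.vertices), plane)
        assert abs(vol - oracle) < 1e-9

    def test_cut_complement_conservation(self, coarse_baseline):
        """ROI piece + complement piece volumes equal the full closed volume
        to 1e-6 relative."""
        plane = plane_from_landmarks(coarse_baseline.landmarks,
                                     mesh=coarse_baseline.mesh)
        mesh = coarse_baseline.mesh
        v_roi = mesh_volume(close_mesh(cut_mesh(mesh, plane)))
        v_rest = mesh_volume(close_mesh(cut_mesh(mesh, plane.flipped())))
        v_all = mesh_volume(mesh)
        assert abs(v_roi + v_rest - v_all) / v_all < 1e-6

    def test_rigid_invariance_of_roi_volume(self, coarse_baseline):
        """Transforming mesh and plane by the same rigid motion leaves the
        closed ROI volume unchanged to 1e-9 relative."""
        rng = np.random.default_rng(11)
        T = RigidTransform(random_rotation(rng), rng.normal(scale=3.0, size=3))
        plane = plane_from_landmarks(coarse_baseline.landmarks,
                                     mesh=coarse_baseline.mesh)
        v0 = mesh_volume(close_mesh(cut_mesh(coarse_baseline.mesh, plane)))
        plane_t = CuttingPlane(T.apply(plane.point), T.rotation @ plane.normal)
        v1 = mesh_volume(close_mesh(cut_mesh(
            apply_transform(coarse_baseline.mesh, T), plane_t)))
        assert abs(v1 - v0) / v0 < 1e-9


class TestCloseMesh:
    def test_already_closed_returned_unchanged(self):
        cube = unit_cube()
        out = close_mesh(cube)
        assert out is cube

    def test_open_tube_gets_both_loops_capped(self):
        cyl = trimesh.creation.cylinder(radius=1.0, height=2.0, sections=32)
        side_only = cyl.copy()
        keep = np.abs(side_only.face_normals[:, 2]) < 0.99
        side_only.update_faces(keep)
        side_only.remove_unreferenced_vertices()
        closed = close_mesh(side_only)
        assert closed.is_watertight
        assert closed.euler_number == 2  # sphere topology per component
        assert abs(mesh_volume(closed) - mesh_volume(cyl)) / mesh_volume(cyl) < 0.02


class TestMeshVolume:
    def test_unit_cube_exact(self):
        assert mesh_volume(unit_cube()) == pytest.approx(1.0, abs=1e-12)

    def test_tetrahedron_exact(self):
        verts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
        tet = trimesh.Trimesh(verts, faces, process=False)
        assert mesh_volume(tet) == pytest.approx(1.0 / 6.0, abs=1e-12)

    def test_icosphere_close_to_analytic(self):
        ico = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        assert abs(mesh_volume(ico) - 4.0 * np.pi / 3.0) / (4 * np.pi / 3) < 0.005

    def test_non_watertight_rejected_with_boundary_count(self):
        cube = unit_cube()
        open_cube = cube.copy()
        open_cube.update_faces(np.arange(len(cube.faces)) > 1)
        with pytest.raises(ValidationError, match="boundary edges"):
            mesh_volume(open_cube)


class TestVolumeChange:
    def test_conventions_and_signs(self):
        assert volume_change(5.0, 5.0) == 0.0
        assert volume_change(5.0, 4.0) == pytest.approx(-1.0)   # loss negative
        assert volume_change(5.0, 4.0, loss_negative=False) == pytest.approx(1.0)
        assert volume_change(5.0, 5.5) > 0                      # swelling positive

    def test_record_validation(self):
        rec = ROIVolumeRecord("s1", "baseline", 2.0)
        assert rec.delta_V == 0.0
        with pytest.raises(ValidationError):
            ROIVolumeRecord("s1", "1m", -1.0)


def _convex_clip_volume(points, plane):
    """Exact half-space clip volume of the convex hull of *points* (oracle)."""
    hull = ConvexHull(points)
    pts = points[hull.vertices]
    sd = plane.signed_distance(pts)
    kept = pts[sd <= 1e-12]
    inter = []
    sd_all = plane.signed_distance(points)
    for simplex in hull.simplices:
        for a, b in ((0, 1), (1, 2), (2, 0)):
            i, j = simplex[a], simplex[b]
            if sd_all[i] * sd_all[j] < 0:
                t = sd_all[i] / (sd_all[i] - sd_all[j])
                inter.append(points[i] + t * (points[j] - points[i]))
    if len(kept) == 0:
        return 0.0
    allpts = np.vstack([kept] + ([np.asarray(inter)] if inter else []))
    if len(allpts) < 4:
        return 0.0
    return ConvexHull(allpts).volume
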