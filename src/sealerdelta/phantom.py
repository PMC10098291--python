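"""Synthetic root-with-extruded-sealer phantoms with known ground truth.

A specimen is modelled as a tapered root shaft (frustum, apex pointing down
the -z axis) with a spherical sealer blob attached at the apex tip.  Each
"scanning session" applies i.i.d. Gaussian surface noise along the vertex
normals (default SD 10 um, the scanner's stated resolution scale) and an
unknown rigid placement, so every downstream stage — landmark initialization,
ICP, plane cutting, volumetry, distance maps, subtraction radiography — can
be validated against exact bookkeeping:

* the sealer blob's mesh volume is known analytically and by an independent
  column-occupancy (voxel-pitch) oracle;
* dimensional change is uniform scaling of the blob about its centroid, so a
  volume-change fraction ``f`` scales the meshed blob volume by exactly
  ``1 + f``;
* radiographs are parallel projections at fixed geometry (the positioning
  accessory of the physical set-up), with the sealer silhouette pixel count
  recorded as the projected-area ground truth.

Radiopacity is a linear thickness projection: gray = 255 * (1 - D / D_max)
with optical density D = sum of (attenuation x thickness) per material,
clipped and quantized to 8 bits.  Only silhouette areas are consumed
downstream, so no beam physics is modelled.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import ValidationError
from .geometry import column_volume, raster_thickness
from .radiography import Radiograph
from .transforms import LandmarkSet, RigidTransform, random_small_transform
from .volumetry import mesh_volume


@dataclass(frozen=True)
class PhantomSpec:
    seed: int = 0
    root_length: float = 12.0          # mm
    root_radius: float = 1.6           # mm, at the shaft top (major semi-axis)
    cross_section_ratio: float = 0.8   # minor/major axis of the oval shaft
    lobe_amplitude: float = 0.10       # relative depth of longitudinal surface lobes
    lobe_count: int = 3                # lobes around the circumference
    lobe_twist_deg_per_mm: float = 4.0 # helical twist of the lobes along the shaft
    apex_radius_fraction: float = 0.3  # apex-tip radius / shaft radius
    sealer_radius: float = 1.5         # mm, apical blob
    mesh_edge_length: float = 0.15     # mm, target triangle size
    surface_noise_sd: float = 0.010    # mm (~10 um scan jitter)
    session_transform: RigidTransform | None = None  # None -> random placement
    volume_change_fraction: float = 0.0
    landmark_level_fraction: float = 0.6  # shaft level of the 3 landmarks

    def validate(self):
        if min(self.root_length, self.root_radius, self.sealer_radius,
               self.mesh_edge_length) <= 0:
            raise ValidationError("phantom dimensions must be positive")
        if not (0 < self.apex_radius_fraction < 1):
            raise ValidationError("apex radius fraction must be in (0, 1)")
        if not (0 < self.cross_section_ratio <= 1):
            raise ValidationError("cross-section ratio must lie in (0, 1]")
        if not (0 <= self.lobe_amplitude < 0.3) or self.lobe_count < 0:
            raise ValidationError("lobe amplitude must lie in [0, 0.3)")
        if self.surface_noise_sd < 0:
            raise ValidationError("surface noise SD must be non-negative")
        if self.sealer_radius >= 3.0 * self.root_radius:
            raise ValidationError("sealer blob too large to be apex-attached")
        if self.volume_change_fraction <= -1.0:
            raise ValidationError("volume change fraction must exceed -1")
        if not (0.1 <= self.landmark_level_fraction <= 0.9):
            raise ValidationError("landmark level must sit on the shaft")


def _frustum(length, r_top, r_bottom, edge):
    """Closed frustum along -z: top disc (radius r_top) at z=0, bottom at z=-length."""
    n_seg = max(12, int(np.ceil(2 * np.pi * max(r_top, r_bottom) / edge)))
    n_rows = max(2, int(np.ceil(length / edge)))
    theta = np.linspace(0.0, 2 * np.pi, n_seg, endpoint=False)
    zs = np.linspace(0.0, -length, n_rows + 1)
    radii = r_top + (r_bottom - r_top) * (-zs / length)
    rings = [np.column_stack([r * np.cos(theta), r * np.sin(theta), np.full(n_seg, z)])
             for r, z in zip(radii, zs)]
    verts = np.vstack(rings)
    faces = []
    for i in range(n_rows):
        a = i * n_seg + np.arange(n_seg)
        b = i * n_seg + (np.arange(n_seg) + 1) % n_seg
        c = a + n_seg
        d = b + n_seg
        # outward-facing winding, consistent with both caps
        faces.append(np.column_stack([a, c, b]))
        faces.append(np.column_stack([b, c, d]))
    top_c = len(verts)
    bot_c = len(verts) + 1
    verts = np.vstack([verts, [0.0, 0.0, 0.0], [0.0, 0.0, -length]])
    top = np.arange(n_seg)
    bot = n_rows * n_seg + np.arange(n_seg)
    faces.append(np.column_stack([top, (top + 1) % n_seg, np.full(n_seg, top_c)]))
    faces.append(np.column_stack([n_rows * n_seg + (np.arange(n_seg) + 1) % n_seg,
                                  bot, np.full(n_seg, bot_c)]))
    mesh = trimesh.Trimesh(vertices=verts, faces=np.vstack(faces), process=False)
    tri = np.asarray(mesh.triangles)
    if np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) < 0:
        mesh.invert()
    return mesh


def _blob(radius, edge):
    """Icosphere with edge length close to the target."""
    subdiv = max(1, int(np.ceil(np.log2(1.0515 * radius / edge))))
    return trimesh.creation.icosphere(subdivisions=min(subdiv, 6), radius=radius)


def _lobe_factor(theta, z, spec: PhantomSpec):
    """Radial modulation of the shaft: shallow helical lobes.

    A smooth surface of revolution would leave rotation about the shaft axis
    undetermined by any surface-based registration; real roots are oval with
    longitudinal developmental grooves.  The lobes (default: three, ~6% deep,
    gently twisted) give every rigid mode a strong surface signature.
    """
    twist = np.radians(spec.lobe_twist_deg_per_mm) * z
    return 1.0 + spec.lobe_amplitude * np.cos(spec.lobe_count * theta + twist)


def _canonical_geometry(spec: PhantomSpec, change_fraction: float = 0.0):
    """Noise-free root + blob in the canonical specimen frame."""
    root = _frustum(spec.root_length, spec.root_radius,
                    spec.apex_radius_fraction * spec.root_radius,
                    spec.mesh_edge_length)
    v = np.asarray(root.vertices)
    theta = np.arctan2(v[:, 1], v[:, 0])
    v[:, :2] *= _lobe_factor(theta, v[:, 2], spec)[:, None]
    v[:, 1] *= spec.cross_section_ratio
    root.vertices = v
    blob = _blob(spec.sealer_radius, spec.mesh_edge_length)
    center = np.array([0.0, 0.0, -spec.root_length - spec.sealer_radius])
    blob.vertices += center
    if change_fraction != 0.0:
        s = (1.0 + change_fraction) ** (1.0 / 3.0)
        blob.vertices = center + s * (blob.vertices - center)
    return root, blob


def _canonical_landmarks(spec: PhantomSpec) -> np.ndarray:
    z = -spec.landmark_level_fraction * spec.root_length
    r = spec.root_radius * (1 + (spec.apex_radius_fraction - 1)
                            * (-z / spec.root_length))
    ang = np.radians([0.0, 120.0, 240.0])
    r_mod = r * _lobe_factor(ang, z, spec)
    return np.column_stack([r_mod * np.cos(ang),
                            spec.cross_section_ratio * r_mod * np.sin(ang),
                            np.full(3, z)])


def _add_noise(mesh, sd, rng):
    if sd <= 0:
        return mesh.copy()
    disp = rng.normal(0.0, sd, size=len(mesh.vertices))
    v = np.asarray(mesh.vertices) + disp[:, None] * np.asarray(mesh.vertex_normals)
    return trimesh.Trimesh(vertices=v, faces=np.asarray(mesh.faces).copy(),
                           process=False)


@dataclass
class PhantomScene:
    """One scanning session of one phantom specimen at one time point."""

    root_mesh: trimesh.Trimesh          # session frame, noisy
    sealer_mesh: trimesh.Trimesh
    landmarks: LandmarkSet              # session frame
    true_sealer_volume: float           # mm^3, column/voxel oracle
    true_sealer_volume_mesh: float      # mm^3, divergence theorem on the ideal blob
    true_change_fraction: float
    time_label: str
    session_transform: RigidTransform
    spec: PhantomSpec
    true_projected_area: float | None = None  # mm^2, set when rendered
    meta: dict = field(default_factory=dict)

    @property
    def mesh(self) -> trimesh.Trimesh:
        """The full scanned surface (root + sealer), as an STL scan would be."""
        return trimesh.Trimesh(
            vertices=np.vstack([self.root_mesh.vertices, self.sealer_mesh.vertices]),
            faces=np.vstack([self.root_mesh.faces,
                             self.sealer_mesh.faces + len(self.root_mesh.vertices)]),
            process=False)

    def canonical_frame(self):
        """Root and sealer meshes repositioned to the canonical specimen frame
        (what the radiographic positioning accessory realizes)."""
        inv = self.session_transform.inverse()
        from .registration import apply_transform
        return apply_transform(self.root_mesh, inv), apply_transform(self.sealer_mesh, inv)

    def manifest(self) -> dict:
        return {
            "time_label": self.time_label,
            "seed": self.spec.seed,
            "true_change_fraction": self.true_change_fraction,
            "true_sealer_volume_mm3": self.true_sealer_volume,
            "true_sealer_volume_mesh_mm3": self.true_sealer_volume_mesh,
            "true_projected_area_mm2": self.true_projected_area,
            "session_transform": self.session_transform.to_matrix().tolist(),
            "surface_noise_sd_mm": self.spec.surface_noise_sd,
            "mesh_edge_length_mm": self.spec.mesh_edge_length,
        }

    def write(self, out_dir, stem: str):
        """Write STL scan, landmark text file and ground-truth manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.mesh.export(out / f"{stem}.stl")
        self.landmarks.to_file(out / f"{stem}_landmarks.txt")
        (out / f"{stem}_truth.json").write_text(json.dumps(self.manifest(), indent=2))


def _assemble_scene(spec, root_c, blob_c, f, time_label, rng,
                    session_transform=None) -> PhantomScene:
    root = _add_noise(root_c, spec.surface_noise_sd, rng)
    blob = _add_noise(blob_c, spec.surface_noise_sd, rng)
    lm = _canonical_landmarks(spec) + rng.normal(
        0.0, spec.surface_noise_sd, size=(3, 3))
    T = session_transform or random_small_transform(rng)
    from .registration import apply_transform
    v_mesh = mesh_volume(blob_c)
    v_vox = column_volume(blob_c, spec.mesh_edge_length / 2.0)
    return PhantomScene(
        root_mesh=apply_transform(root, T),
        sealer_mesh=apply_transform(blob, T),
        landmarks=LandmarkSet(T.apply(lm)),
        true_sealer_volume=v_vox,
        true_sealer_volume_mesh=v_mesh,
        true_change_fraction=f,
        time_label=time_label,
        session_transform=T,
        spec=spec)


def make_baseline(spec: PhantomSpec, time_label: str = "baseline") -> PhantomScene:
    """Baseline scan of a fresh specimen (change fraction 0)."""
    spec.validate()
    rng = np.random.default_rng([int(spec.seed), 0])
    root_c, blob_c = _canonical_geometry(spec, 0.0)
    return _assemble_scene(spec, root_c, blob_c, 0.0, time_label, rng,
                           spec.session_transform)


def make_followup(base: PhantomScene, change_fraction: float,
                  spec: PhantomSpec | None = None, time_label: str = "followup",
                  time_index: int = 1,
                  session_transform: RigidTransform | None = None) -> PhantomScene:
    """Follow-up scan: sealer blob volume scaled by ``1 + change_fraction``.

    The root shaft geometry is unchanged (the no-change region); only fresh
    surface noise and a new session placement are applied.  ``time_index``
    separates the random streams of successive follow-ups of one specimen.
    """
    spec = spec or base.spec
    if change_fraction <= -1.0:
        raise ValidationError("change fraction must exceed -1 (volume stays positive)")
    spec.validate()
    rng = np.random.default_rng([int(spec.seed), int(time_index)])
    root_c, blob_c = _canonical_geometry(spec, change_fraction)
    scene = _assemble_scene(spec, root_c, blob_c, change_fraction, time_label,
                            rng, session_transform)
    scene.meta["baseline_true_sealer_volume_mesh_mm3"] = base.true_sealer_volume_mesh
    scene.meta["true_delta_V_mm3"] = change_fraction * base.true_sealer_volume_mesh
    return scene


# ---------------------------------------------------------------------------
# radiograph rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProjectionSpec:
    """Fixed parallel-projection geometry, shared by all time points of a
    specimen (period-identical radiographs)."""

    mm_per_px: float = 0.02
    width: int = 620
    height: int = 800
    x0: float = -6.0                  # mm, left edge of the field
    z0: float = -17.0                 # mm, bottom edge of the field
    ball_center: tuple = (3.9, -3.0)  # (x, z) mm
    ball_diameter: float = 5.0        # mm
    mu_root: float = 0.3              # attenuation per mm of acrylic root
    mu_sealer: float = 250.0          # sealer: heavily radiopacified (ZrO2 /
                                      # CaWO4 fillers), silhouette saturates
                                      # within ~0.02 mm of material
    mu_ball: float = 25.0             # stainless-steel calibration ball
    d_max: float = 5.0                # optical density mapped to full black
    image_noise_sd: float = 0.0       # gray levels; 0 = noiseless exposure

    @classmethod
    def for_scene(cls, scene: PhantomScene, mm_per_px: float = 0.02,
                  margin_mm: float = 1.0, growth_allowance_mm: float = 1.0,
                  **overrides) -> "ProjectionSpec":
        """Frame the specimen and the calibration ball at fixed geometry.

        Derived once from the baseline scene and reused for every follow-up
        so the projection axis and field never move between time points.
        """
        spec = scene.spec
        xmax_root = spec.root_radius
        x0 = -xmax_root - margin_mm
        ball_r = float(overrides.get("ball_diameter", 5.0))
        ball_x = xmax_root + margin_mm + ball_r / 2.0 + 0.5
        field_w = 620 * mm_per_px
        if ball_x + ball_r / 2.0 + margin_mm > x0 + field_w:
            raise ValidationError("scene too wide for the 620-px field at this scale")
        z_top = margin_mm
        z_bot = -(spec.root_length + 2 * spec.sealer_radius
                  + growth_allowance_mm + margin_mm)
        height = int(np.ceil((z_top - z_bot) / mm_per_px))
        return cls(mm_per_px=mm_per_px, width=620, height=height, x0=x0, z0=z_bot,
                   ball_center=(ball_x, -0.25 * spec.root_length), **overrides)


def render_radiograph(scene: PhantomScene | None, geometry: ProjectionSpec,
                      rng: np.random.Generator | None = None) -> Radiograph:
    """8-bit parallel-projection radiograph of a scene, width exactly 620 px.

    The specimen is imaged in its canonical frame (positioning accessory);
    the 5-mm calibration ball is rendered analytically at its configured
    position.  The sealer silhouette pixel count (the projected-area ground
    truth) is recorded in ``meta['true_sealer_area_mm2']`` together with the
    silhouette mask and the true scale.  An empty scene (``None``) yields the
    uniform background with true area 0.
    """
    g = geometry
    s = g.mm_per_px
    D = np.zeros((g.height, g.width), dtype=float)
    sealer_mask = np.zeros_like(D, dtype=bool)
    if scene is not None:
        root_c, blob_c = scene.canonical_frame()
        D += g.mu_root * raster_thickness(root_c.vertices, root_c.faces,
                                          s, g.x0, g.z0, g.width, g.height)
        t_sealer = raster_thickness(blob_c.vertices, blob_c.faces,
                                    s, g.x0, g.z0, g.width, g.height)
        D += g.mu_sealer * t_sealer
        sealer_mask = t_sealer > 1e-9
        # calibration ball (only rendered alongside a specimen)
        gi = g.x0 + (np.arange(g.width) + 0.5) * s
        gj = g.z0 + (np.arange(g.height) + 0.5) * s
        rho2 = (gi[None, :] - g.ball_center[0]) ** 2 \
            + (gj[:, None] - g.ball_center[1]) ** 2
        R = g.ball_diameter / 2.0
        t_ball = 2.0 * np.sqrt(np.maximum(R * R - rho2, 0.0))
        D += g.mu_ball * t_ball
    # raster rows run with increasing z; flip to standard image orientation
    # (row 0 at the top, apex and sealer toward the bottom rows)
    D = D[::-1]
    sealer_mask = sealer_mask[::-1]
    gray = 255.0 * (1.0 - np.clip(D / g.d_max, 0.0, 1.0))
    if g.image_noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        gray = gray + rng.normal(0.0, g.image_noise_sd, size=gray.shape)
    pixels = np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    area = float(sealer_mask.sum() * s * s)
    rad = Radiograph(pixels, mm_per_px=None,
                     time_label=scene.time_label if scene is not None else None,
                     meta={"true_sealer_area_mm2": area,
                           "true_mm_per_px": s,
                           "sealer_mask": sealer_mask})
    if scene is not None:
        scene.true_projected_area = area
    return rad
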