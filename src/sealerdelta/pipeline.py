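"""End-to-end orchestration: study manifest -> per-specimen measurement
records -> study-level statistics.

A study manifest lists, per (blinded) specimen, the mesh / landmark /
radiograph files of the baseline and each follow-up session, plus the run
configuration (ICP settings, thresholds, the study seed).  Measurements are
computed fully blinded: group codes are joined onto the finished records as a
pure relabelling step just before the statistical synthesis.  Any stage
failure flags the affected specimen/time as excluded with the stage and
reason — mirroring how misaligned scans or lost specimens are handled — and
never fails silently.

All randomness (ICP sampling, distance-map sampling) flows from the single
study seed through per-specimen/per-stage derived seeds recorded in the
outputs, so a rerun of the same manifest is byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from . import radiography as rg
from .errors import ValidationError
from .registration import ICPConfig, apply_transform, icp_refine, landmark_align
from .stats import comparisons_to_frame, fit_cs_model
from .surface_change import classify_change, rms, signed_distances
from .transforms import LandmarkSet
from .volumetry import (ROIVolumeRecord, close_mesh, cut_mesh, mesh_volume,
                        plane_from_landmarks, volume_change)

BASELINE = "baseline"
RESPONSE_TYPES = ("volume_mm3", "rms_mm", "area_mm2")


def derive_seed(study_seed: int, *keys) -> int:
    """Deterministic per-stage seed below 2^31, derived from the study seed."""
    text = f"{study_seed}|" + "|".join(str(k) for k in keys)
    return zlib.crc32(text.encode()) % (2 ** 31)


DEFAULT_CONFIG = {
    "icp": {"max_iterations": 100, "convergence_tol": 1e-5,
            "sample_count": 800, "correspondence_rejection_quantile": 0.95},
    "distance_sample_count": 2000,
    "change_threshold_mm": 0.05,       # tau for the color-map classification
    "radiography_intensity_threshold": None,  # None -> robust MAD threshold
    "roi_row_fraction": 0.55,          # radiographic ROI: rows below this fraction
    "study_seed": 0,
}


def _merge_config(cfg: dict | None) -> dict:
    out = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in (cfg or {}).items():
        if k == "icp" and isinstance(v, dict):
            out["icp"].update(v)
        else:
            out[k] = v
    return out


def config_hash(cfg: dict) -> str:
    return hashlib.sha1(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class SpecimenEntry:
    specimen_id: str                      # blinded code
    files: dict                           # time_label -> {mesh, landmarks, radiograph}

    def times(self):
        return [t for t in self.files if t != BASELINE]


@dataclass
class StudyManifest:
    specimens: list
    config: dict = field(default_factory=dict)
    codes: dict | None = None             # blinded code -> group (kept separate)
    base_dir: Path = Path(".")

    def __post_init__(self):
        self.config = _merge_config(self.config)
        for s in self.specimens:
            if BASELINE not in s.files:
                raise ValidationError(
                    f"specimen {s.specimen_id}: baseline entry is required")

    @staticmethod
    def from_yaml(path) -> "StudyManifest":
        path = Path(path)
        doc = yaml.safe_load(path.read_text())
        specimens = [SpecimenEntry(str(s["id"]), s["files"]) for s in doc["specimens"]]
        codes = doc.get("codes")
        if isinstance(codes, str):
            codes = yaml.safe_load((path.parent / codes).read_text())
        return StudyManifest(specimens=specimens, config=doc.get("config", {}),
                             codes=codes, base_dir=path.parent)

    def path(self, rel) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else self.base_dir / p


@dataclass
class Exclusion:
    specimen_id: str
    time_label: str
    stage: str
    reason: str


@dataclass
class SpecimenResult:
    specimen_id: str
    volume_records: list = field(default_factory=list)
    rms_records: list = field(default_factory=list)
    area_records: list = field(default_factory=list)
    exclusions: list = field(default_factory=list)


def _roi_mask(shape, row_fraction: float) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[int(round(row_fraction * shape[0])):, :] = True
    return mask


def run_specimen(entry: SpecimenEntry, config: dict | None = None,
                 manifest: StudyManifest | None = None) -> SpecimenResult:
    """Measure one blinded specimen across all its time points.

    Per follow-up: landmark initialization -> trimmed ICP (restricted to the
    shaft side of the baseline cutting plane) -> shared-plane cut -> cap ->
    volume difference; signed distance map -> RMS and classification; and the
    calibrated radiograph subtraction.  Stage failures are recorded as
    exclusions for that time point only.
    """
    cfg = _merge_config(config)
    seed0 = int(cfg["study_seed"])
    resolve = manifest.path if manifest is not None else (lambda p: Path(p))
    result = SpecimenResult(entry.specimen_id)
    chash = config_hash(cfg)
    sid = entry.specimen_id

    # ---- baseline 3D ----
    base_files = entry.files[BASELINE]
    try:
        base_mesh = trimesh.load_mesh(resolve(base_files["mesh"]), process=False)
        base_lms = LandmarkSet.from_file(resolve(base_files["landmarks"]))
        plane = plane_from_landmarks(base_lms, mesh=base_mesh)
        base_roi = close_mesh(cut_mesh(base_mesh, plane))
        V0 = mesh_volume(base_roi)
        result.volume_records.append(ROIVolumeRecord(
            sid, BASELINE, V0, 0.0,
            meta={"seed": seed0, "config": chash}))
        three_d_ok = True
    except Exception as exc:
        result.exclusions.append(Exclusion(sid, BASELINE, "baseline-3d", str(exc)))
        three_d_ok = False

    # ---- baseline radiograph ----
    base_rad = scale = None
    if "radiograph" in base_files:
        try:
            base_rad = rg.load_and_standardize(resolve(base_files["radiograph"]),
                                               time_label=BASELINE)
            scale = rg.calibrate_scale(rg.detect_ball(base_rad))
            base_rad.mm_per_px = scale
        except Exception as exc:
            result.exclusions.append(Exclusion(sid, BASELINE, "baseline-radiograph",
                                               str(exc)))
            base_rad = None

    icp_cfg = dict(cfg["icp"])
    for k, time_label in enumerate(entry.times(), start=1):
        files = entry.files[time_label]
        # ---- 3D chain ----
        if three_d_ok and "mesh" in files:
            try:
                mesh_i = trimesh.load_mesh(resolve(files["mesh"]), process=False)
                lms_i = LandmarkSet.from_file(resolve(files["landmarks"]))
                T0 = landmark_align(lms_i, base_lms)
                T, report = icp_refine(
                    mesh_i, base_mesh, init=T0,
                    cfg=ICPConfig(seed=derive_seed(seed0, sid, time_label, "icp"),
                                  **icp_cfg),
                    exclude_plane=plane)
                moved = apply_transform(mesh_i, T)
                roi_i = close_mesh(cut_mesh(moved, plane))
                Vi = mesh_volume(roi_i)
                result.volume_records.append(ROIVolumeRecord(
                    sid, time_label, Vi, volume_change(V0, Vi),
                    meta={"seed": derive_seed(seed0, sid, time_label, "icp"),
                          "config": chash, "icp_iterations": report.iterations,
                          "icp_residual": report.final_residual,
                          "icp_converged": report.converged}))
                dseed = derive_seed(seed0, sid, time_label, "distance")
                dmap = signed_distances(roi_i, base_roi,
                                        sample_count=int(cfg["distance_sample_count"]),
                                        seed=dseed)
                cls = classify_change(dmap, float(cfg["change_threshold_mm"]))
                result.rms_records.append({
                    "specimen_id": sid, "time_label": time_label,
                    "rms_mm": rms(dmap), "mean_signed_mm": float(np.mean(dmap.signed_distance)),
                    "frac_increase": cls.fractions["increase"],
                    "frac_decrease": cls.fractions["decrease"],
                    "frac_no_change": cls.fractions["no_change"],
                    "threshold_mm": cls.threshold, "seed": dseed, "config": chash})
            except Exception as exc:
                result.exclusions.append(Exclusion(sid, time_label, "3d", str(exc)))
        elif three_d_ok:
            result.exclusions.append(Exclusion(sid, time_label, "3d", "missing mesh"))

        # ---- radiograph chain ----
        if base_rad is not None and "radiograph" in files:
            try:
                rad_i = rg.load_and_standardize(resolve(files["radiograph"]),
                                                time_label=time_label)
                rad_i.mm_per_px = scale
                diff = rg.subtract(rad_i, base_rad)
                mask = _roi_mask(diff.data.shape, float(cfg["roi_row_fraction"]))
                rec = rg.measure_area_change(
                    diff, mask,
                    intensity_threshold=cfg["radiography_intensity_threshold"],
                    mm_per_px=scale, specimen_id=sid, time_label=time_label)
                result.area_records.append(rec)
            except Exception as exc:
                result.exclusions.append(Exclusion(sid, time_label, "radiograph",
                                                   str(exc)))
        elif base_rad is not None:
            result.exclusions.append(Exclusion(sid, time_label, "radiograph",
                                               "missing radiograph"))
    return result


# ---------------------------------------------------------------------------
# study level
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    dataset: pd.DataFrame                 # tidy longitudinal table (unblinded)
    tables: dict                          # response_type -> {"groups": df, "times": df, "ls_means": df}
    exclusions: pd.DataFrame
    config: dict

    def write(self, out_dir):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.dataset.to_csv(out / "records.csv", index=False)
        self.exclusions.to_csv(out / "exclusions.csv", index=False)
        for resp, tabs in self.tables.items():
            for name, df in tabs.items():
                df.to_csv(out / f"{name}_{resp}.csv", index=False)
        (out / "run.json").write_text(json.dumps(
            {"config": self.config, "config_hash": config_hash(self.config),
             "n_rows": int(len(self.dataset))}, indent=2))


def collect_dataset(results: list, codes: dict | None) -> pd.DataFrame:
    """Tidy (specimen, group, time, response, response_type) table.

    Measurement records are produced blinded; the group column is joined here
    from the code map as a pure relabelling.
    """
    rows = []
    for res in results:
        for rec in res.volume_records:
            if rec.time_label != BASELINE:
                rows.append((res.specimen_id, rec.time_label, "volume_mm3",
                             rec.delta_V))
        for rec in res.rms_records:
            rows.append((res.specimen_id, rec["time_label"], "rms_mm", rec["rms_mm"]))
        for rec in res.area_records:
            rows.append((res.specimen_id, rec.time_label, "area_mm2", rec.delta_area))
    df = pd.DataFrame(rows, columns=["specimen_id", "time", "response_type",
                                     "response"])
    df["group"] = (df["specimen_id"].map(codes) if codes else pd.NA)
    return df[["specimen_id", "group", "time", "response_type", "response"]]


def run_study(manifest: StudyManifest) -> StudyReport:
    """Run every specimen, unblind, and fit the per-response mixed models.

    Produces pairwise-group and period-versus-baseline comparison tables and
    the per-cell LS means (the group-mean +/- CI profiles over time) for each
    response type with enough data; groups with too few specimens yield
    estimability flags inside the tables rather than hard failures.
    """
    results = [run_specimen(s, manifest.config, manifest) for s in manifest.specimens]
    dataset = collect_dataset(results, manifest.codes)
    exclusions = pd.DataFrame(
        [(e.specimen_id, e.time_label, e.stage, e.reason)
         for r in results for e in r.exclusions],
        columns=["specimen_id", "time", "stage", "reason"])
    tables = {}
    if manifest.codes:
        for resp in RESPONSE_TYPES:
            sub = dataset[dataset["response_type"] == resp]
            if sub.empty:
                continue
            try:
                fit = fit_cs_model(sub, response="response", group="group",
                                   time="time", subject="specimen_id")
                tables[resp] = {
                    "group_comparisons": comparisons_to_frame(fit.pairwise_groups()),
                    "time_effects": comparisons_to_frame(fit.time_effects()),
                    "ls_means": fit.ls_means(by="cell"),
                }
            except ValidationError as exc:
                tables[resp] = {"error": pd.DataFrame([{"error": str(exc)}])}
    return StudyReport(dataset=dataset, tables=tables, exclusions=exclusions,
                       config=manifest.config)


# ---------------------------------------------------------------------------
# phantom-backed study simulation
# ---------------------------------------------------------------------------

#: per-period cumulative volume-change fractions emulating the qualitative
#: longitudinal behaviour of the five obturation materials: a stable
#: epoxy sealer (slight initial uptake), a strongly dissolving calcium
#: hydroxide sealer, a calcium silicate sealer that swells then loses
#: material, a slowly dissolving zinc oxide sealer, and the inert
#: gutta-percha control.
DEFAULT_GROUP_PROFILES = {
    "AH": [0.02, 0.02, 0.02, 0.02],
    "AX": [-0.05, -0.15, -0.27, -0.28],
    "BR": [0.06, 0.00, -0.06, -0.17],
    "TS": [-0.03, -0.03, -0.08, -0.11],
    "GP": [0.0, 0.0, 0.0, 0.0],
}
DEFAULT_TIMES = ["1w", "1m", "3m", "18m"]


def simulate_study(out_dir, n_per_group: int = 10, seed: int = 0,
                   profiles: dict | None = None, times: list | None = None,
                   phantom_kwargs: dict | None = None,
                   fraction_rel_sd: float = 0.20,
                   mm_per_px: float = 0.02,
                   config: dict | None = None) -> Path:
    """Generate a blinded phantom study on disk and return the manifest path.

    Each specimen gets a baseline and one follow-up scan per period, with its
    group's change-fraction profile perturbed by a specimen-level
    multiplicative jitter (relative SD ``fraction_rel_sd``, matching the 20%
    dispersion assumed by the power calculation).  Scans, landmark files,
    radiographs, per-scene ground-truth manifests, the blinded manifest and
    the separate code map are all written under ``out_dir``.
    """
    from .phantom import PhantomSpec, ProjectionSpec, make_baseline, make_followup, \
        render_radiograph

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profiles = profiles or DEFAULT_GROUP_PROFILES
    times = times or DEFAULT_TIMES
    rng = np.random.default_rng(derive_seed(seed, "study"))
    specs = []
    codes = {}
    idx = 0
    order = []
    for group, profile in profiles.items():
        for j in range(n_per_group):
            order.append((group, profile, idx))
            idx += 1
    # blinded codes: shuffled specimen numbering so code order betrays no group
    perm = rng.permutation(len(order))
    for (group, profile, idx), code_i in zip(order, perm):
        code = f"SP{code_i:03d}"
        codes[code] = group
        pspec = PhantomSpec(seed=derive_seed(seed, "phantom", code),
                            **(phantom_kwargs or {}))
        base = make_baseline(pspec)
        proj = ProjectionSpec.for_scene(base, mm_per_px=mm_per_px)
        sdir = out / code
        base.write(sdir, BASELINE)
        render_radiograph(base, proj).save(sdir / f"{BASELINE}.tiff")
        files = {BASELINE: {"mesh": f"{code}/{BASELINE}.stl",
                            "landmarks": f"{code}/{BASELINE}_landmarks.txt",
                            "radiograph": f"{code}/{BASELINE}.tiff"}}
        jitter = 1.0 + rng.normal(0.0, fraction_rel_sd)
        for k, (t, f) in enumerate(zip(times, profile), start=1):
            scene = make_followup(base, f * jitter, time_label=t, time_index=k)
            scene.write(sdir, t)
            render_radiograph(scene, proj).save(sdir / f"{t}.tiff")
            files[t] = {"mesh": f"{code}/{t}.stl",
                        "landmarks": f"{code}/{t}_landmarks.txt",
                        "radiograph": f"{code}/{t}.tiff"}
        specs.append({"id": code, "files": files})
    cfg = _merge_config(config)
    cfg["study_seed"] = seed
    (out / "codes.yaml").write_text(yaml.safe_dump(codes))
    manifest = {"config": cfg, "codes": "codes.yaml", "specimens": specs}
    mpath = out / "study.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return mpath
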