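# Methods

This note records the models, defaults and numerical choices behind
`sealerdelta`, and what the phantom-based validation does and does not show
about real scan data.

## Measurement model

A specimen is observed as a triangle surface mesh per session (baseline and
follow-ups), three labelled shaft landmarks per scan, and one radiograph per
session acquired in period-identical geometry.  The quantities of interest
are, per follow-up: the volume change ΔV = Vᵢ − V₀ of the closed periapical
region of interest (ROI), the RMS of signed point-to-surface distances over
the ROI, and the net radiopaque area change on the subtracted radiograph.
Loss is negative under all three conventions (a flag restores the
V₀ − Vᵢ reading for the volume).

### Registration

* Landmark initialization is the closed-form orthogonal Procrustes solution
  (SVD; reflections excluded by flipping the smallest singular direction).
  Three non-collinear landmarks are required; collinearity is detected from
  the singular values of the centered configuration at 1e-9 relative.
* ICP is point-to-point: area-uniform seeded samples from the moving
  surface, exact closest-point-on-triangle correspondence on the fixed
  surface, trimmed Procrustes update.  Correspondences above the 0.95
  residual quantile are rejected each iteration; when a cutting plane is
  supplied, sampling is restricted to its shaft side, so the physically
  changing sealer never enters the correspondence set.  Iteration stops when
  the trimmed mean residual improves by less than `convergence_tol`
  (default 1e-5 mm; precision experiments in the acceptance script use
  1e-6 mm with 250 iterations, because the weakly constrained pose modes
  converge slowly near the optimum) or when an update would increase the
  residual, in which case the previous pose is kept — making the reported
  residual sequence non-increasing by construction.
* Closest-point queries are exact: the distance to the nearest vertex
  bounds the search radius, a centroid k-d tree prunes candidate triangles
  (any triangle whose centroid lies beyond bound + max circumradius cannot
  win), and the exact point-triangle distance is minimized over the
  survivors.  Ties break toward the lowest triangle index, so runs are
  deterministic.

### ROI volumetry

* The cutting plane passes through the three baseline landmarks, oriented
  away from the ROI (resolved by the apical-extent heuristic or an explicit
  reference point, so landmark ordering is irrelevant).  The same
  baseline-defined plane cuts the registered follow-up; it is never
  re-derived from follow-up landmarks.
* Plane cutting splits straddling triangles exactly at the plane
  (via trimesh's slicer) and welds the duplicate vertices it introduces so
  the cut boundary chains into loops.  Each loop is capped by a centroid
  fan; if a fan triangle degenerates, an ear-clipping triangulation of the
  loop in its best-fit plane is used instead.  Output orientation is fixed
  by requiring positive signed volume.
* Volume is the divergence-theorem sum V = |Σ v₁·(v₂×v₃)/6| over faces,
  accepted only for watertight (zero boundary edges), consistently wound
  meshes — both conditions are checked and reported on failure.
* Surface noise propagates to volume as σ_V = σ √(Σ A_v²) with A_v one
  third of the vertex-adjacent face area; the null-specimen check uses
  3 × √2 σ_V (two independent scans) as its floor.

### Surface change

Distances are sampled one-directionally (follow-up onto baseline, the
direction in which each follow-up is superimposed on its own baseline),
uniformly by area with a fixed seed.  The sign comes from the side of the
nearest baseline facet; RMS uses unsigned magnitudes.  The classification
threshold τ defaults to 0.05 mm — there is no canonical published value, so
τ is treated as a required, logged configuration entry rather than a
constant.

### Subtraction radiography

Images are 8-bit grayscale, standardized to 620 px width
(aspect-preserving bilinear when rescaling is needed).  The scale comes
from the 5-mm calibration ball: Otsu threshold, connected components,
circularity 4πA/P² > 0.9 with the Crofton perimeter, largest survivor,
equivalent-circle diameter.  The difference image is int16 (no clipping);
changed pixels are those beyond a threshold that defaults to 3 robust SDs
(1.4826 × MAD) of the background difference, floored at 5 gray levels — the
floor guards noiseless backgrounds, where the MAD collapses to zero, and
8-bit quantization flicker near silhouette edges.  Denser material renders
darker, so material gain makes the difference negative; the default maps
`gained = diff < −τ`, and a flag restores the opposite convention.  No 2D
re-registration is applied by default (the physical workflow relies on a
positioning accessory and discards misaligned radiographs rather than
warping them).

### Statistics

* The repeated-measures model is y = μ + group + time + group×time + b + ε
  with a specimen random intercept (equivalent to compound symmetry with
  non-negative within-specimen correlation), fitted by REML through
  statsmodels MixedLM.  Responses are changes from baseline, so baseline is
  not a modelled time level; each period's LS mean is tested against zero.
  Missing rows are simply omitted (no imputation); an entirely missing
  group×time cell drops its design column and flags every contrast that
  needs it as non-estimable instead of silently skipping it.
* LS means are model-based cell means averaged at equal weights.  Pairwise
  group differences form a Bonferroni family of C(g,2); within-group time
  effects adjust per group by default (m = number of periods), with a
  global-family option.  CIs are unadjusted t intervals by default while p
  values are Bonferroni-adjusted (a flag produces adjusted CIs), matching
  the common reporting style in which adjusted significance coexists with
  plain 95% CIs.
* Denominator df use a between-within split: group contrasts get
  n_specimens − g, time/interaction contrasts get the residual within df.
  This is one of the standard mixed-model df families and was chosen over a
  Satterthwaite approximation because the latter needs the variance-
  component information matrix, which the fitting backend does not expose;
  for the balanced-to-moderately-unbalanced designs targeted here the two
  agree closely, and no exact reproduction of any particular software's
  default is claimed.
* Sample sizing inverts the exact noncentral-t power of the two-sided
  two-sample t test, started from the normal approximation
  n = 2(z₁₋α/₂ + z₁₋β)²(σ/δ)²; dropout inflation is ⌈n/(1−d)⌉.
  Measurement uncertainty is u = S/√n (S the n−1 sample SD) with
  U = k·u, k = 2 by default.

## The phantom

The phantom emulates the study conditions, not any particular tooth:

* Geometry: a tapered shaft (12 mm long, 1.6 mm top radius, apex 30% of
  that) with an oval cross-section (minor/major 0.8) and three shallow
  helical lobes (10% radial amplitude, 4°/mm twist), plus a spherical
  sealer blob (radius 1.5 mm) tangent at the apex tip.  The lobes and
  ovality mirror the developmental grooves of real roots and matter
  mechanically: a smooth surface of revolution would leave rotation about
  the shaft axis undetermined by any surface-based registration.
* Scanning: i.i.d. Gaussian displacement along vertex normals,
  SD 10 µm (the scanner's stated resolution scale), fresh per session, plus
  a random rigid placement (≤10°, ≤2 mm) per session.  Landmarks sit at
  60% shaft depth at three azimuths and receive the same 10 µm jitter.
* Truth: dimensional change is uniform scaling of the blob about its
  centroid, so the meshed blob volume scales by exactly 1 + f; the manifest
  also records an independent column-occupancy oracle volume at half the
  mesh edge pitch (occupancy integrated exactly along parallel columns;
  agreement with the divergence-theorem value is ~0.1% at default
  resolution and tightens with refinement).
* Radiographs: parallel projection at fixed geometry (the positioning
  accessory), 620 px wide at 0.02 mm/px by default.  Gray levels are a
  linear thickness map, 255·(1 − min(Σμt, D_max)/D_max), with μ chosen so
  the acrylic root is faintly gray (0.3/mm), the heavily radiopacified
  sealer saturates within ~0.02 mm of material (250/mm — sealers carry
  ZrO₂/CaWO₄ fillers precisely so their outline is sharp), and the steel
  ball is solid black.  The sealer silhouette pixel count is the
  projected-area truth.  The rasterizer detects columns with unpaired
  surface crossings (possible where facets graze the projection direction)
  and repairs them from consistent neighbours.
* Study simulation: five material profiles (stable epoxy with slight
  uptake; strongly dissolving calcium hydroxide sealer; calcium silicate
  sealer that swells then loses material; slowly dissolving zinc oxide
  sealer; inert control) with a specimen-level multiplicative jitter of
  relative SD 0.20 — the dispersion the power calculation assumes.

What passing phantom tests shows: the registration, cutting, capping,
differencing, distance, calibration, subtraction and statistics machinery
recovers known changes at the stated tolerances under realistic noise,
placement and blinding conditions.  What it does not show: robustness to
scanner artefacts the phantom lacks (holes, topological defects, specular
dropouts), to sealer that smears along the shaft and defeats the no-change
assumption of the trimmed fit, to truly non-rigid specimen change, or to
radiographic exposure/angulation variation — real studies discard such
cases rather than correct them, and so does this pipeline (as logged
exclusions, never silently).

## Problem sizes and determinism

Unit tests run coarse phantoms (0.3–0.35 mm edge, a few thousand faces);
the end-to-end recovery checks use the default 0.15 mm resolution.  The
registration-recovery experiments use 20 seeded perturbations per noise
level; the statistics suite uses 1,000 null replicates for the family-wise
error and 200 for CI coverage.  Every random draw — mesh noise, placements,
ICP and distance sampling, simulations — flows from explicit seeds (in the
pipeline, from one study seed via stable per-stage derived seeds recorded
in the outputs), so a rerun of the same manifest is byte-identical.

## Known limitations

* Point-to-point ICP converges slowly along weakly constrained pose modes;
  the residual-change stopping rule can park ~0.1–0.3° of azimuthal error
  on noisy scans of smooth shafts.  The phantom's lobes keep that mode well
  within the volumetric error budget (and such relief is typical of real
  roots), but a point-to-plane update would converge faster if needed.
* The cap triangulation assumes boundary loops that are star-shaped about
  their centroid (true for plane cuts of these shapes); genuinely
  self-intersecting loops raise a closure error with diagnostics rather
  than producing a wrong volume.
* The radiographic area measure counts thresholded pixels; material thinned
  below the visibility threshold but not removed is scored as lost area —
  a property of subtraction radiography itself, visible here only at
  tangential rims.
* Between-within df are approximate for severely unbalanced designs; the
  variance-component point estimates, not their uncertainty, drive the
  reported SEs.
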