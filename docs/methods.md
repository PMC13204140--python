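# Methods

## Scope and model

`fbmorph` quantifies the geometry of a small physical object two ways and
relates it to pediatric airway anatomy:

1. **3D morphometry** of a triangulated surface (STL, mm units): volume,
   surface area, principal frame, dimensionless shape descriptors,
   convexity, dihedral sharpness.
2. **2D morphometry** of a single planar photograph beside a ruler:
   silhouette area, perimeter, Feret diameters, aspect ratio, circularity,
   solidity, minimum curvature radius. A single projection reflects the
   silhouette in the orientation photographed, not the full 3D extent, so
   the 3D principal axes are the conservative reference when comparing
   against airway dimensions; the 2D max Feret diameter can only be
   smaller than or equal to the 3D major extent.
3. A **rule engine** that compares descriptors with a normative airway
   table and aggregates binary indicators into a qualitative tier, and a
   **report builder** that assembles a deterministic prompt/narrative.

## 3D descriptors

**Volume** is the absolute value of the sum of signed tetrahedra formed by
each face and the origin — exact and origin-independent for closed meshes.
Non-watertight meshes are computed anyway and flagged (real scans are
imperfect); the watertight-only exactness guarantee applies per descriptor.
An independent divergence-theorem computation (flux of the field `(x,0,0)`)
is exposed as a diagnostic; the two agree to well below 0.1% on every
watertight fixture, and a test enforces that bound.

**Principal frame.** PCA eigenvalues measure variance of the vertex cloud,
not physical size, so the frame uses the eigenvectors for orientation only
and reports extents `L1 >= L2 >= L3` as projection spans (max minus min
coordinate along each axis). Axis signs follow a deterministic convention
(largest-magnitude component positive); eigenvalue ties are broken
lexicographically. A uniform-density inertia frame (second-moment integral
over the enclosed volume, computed by signed tetrahedra) provides the
cross-check; PCA-frame and inertia-frame extents agree within 2% on
fixture meshes.

Note that vertex-covariance PCA weights vertices, not area or volume, so
its axes can diverge from the inertia axes on meshes with very uneven
tessellation density; the fixtures used for the 2% bound (boxes,
ellipsoids, capsules) have near-uniform tessellation, which is also the
regime structured-light scanners produce.

**Dimensionless descriptors.** Elongation `e = 1 - (L3/L1)^2` and flatness
`f = 1 - (L2/L1)^2` are implemented exactly as printed in the source
formulas, with flatness deliberately relating the *intermediate* span to
the major axis (the conventional `1 - (L3/L2)^2` variant and square-root
variants are exposed under `shape_diagnostics`, because published values
for the worked case match the square-root forms rather than the printed
quadratic forms — the package follows the printed equations and surfaces
the alternatives as diagnostics, not outputs). Sphericity
`psi = (36 pi V^2)^(1/3)/A` is bounded by 1 (isoperimetric inequality);
a property test asserts `psi <= 1 + 1e-6` on all fixtures.

**Dihedral census.** For every edge shared by exactly two faces, the
interior dihedral angle is computed from outward normals, with concavity
resolved by the neighbour-centroid side test (convex edges < 180°, concave
> 180°). "Sharp" is strictly `angle < threshold` (default 90°) with a
1e-6-degree guard so exactly-at-threshold edges (a box's 90° edges after a
rigid motion) do not flip on floating-point noise. Boundary edges are
skipped with a warning.

**Conventions that matter downstream.** The axis-aligned bounding box is
computed in the input (scanner) frame and sorted descending; the risk
engine's "object width" defaults to the second AABB span (configurable to
`L2`), because published worked-case tables mix the two conventions.
Vertex merge tolerance defaults to 1e-6 mm (grid hash). All values are
stored at full precision; two-decimal rounding happens only in reports.

## 2D pipeline

**Calibration.** Manual mode fits a least-squares scale through the origin
over all pairwise pixel/mm distances. Tick mode segments the bright yellow
ruler band (RGB rule), fills it, finds dark tick blobs, projects their
centroids onto the band's PCA axis and uses the median spacing; a spacing
dispersion above 10% of the median aborts with an error rather than
returning an unreliable scale.

**Segmentation.** Luma grayscale, global Otsu threshold with dark-side
selection (fixed threshold available), disk-element morphological opening
(radius 2 px default), largest 8-connected component; ties broken by first
label. The ruler is excluded automatically by the dilated yellow mask (or
an explicit crop box) — the exclusion procedure is an implementation
choice, since thresholding alone would pick up the dark tick marks.
Border contact sets a warning flag.

**Contour.** Marching squares runs on the lightly smoothed (sigma 0.8 px)
working grayscale at the segmentation threshold, so the boundary
interpolates the true intensity crossing at subpixel accuracy; when only a
binary mask exists, the mask itself is smoothed (sigma 1 px) and traced at
0.5. Binary-only tracing is the fallback because raw marching squares on a
binary image overestimates the perimeter of smooth shapes enough to push
circularity above 1. Area is the shoelace formula on the contour,
perimeter the polyline length; the pixel-count area is kept as a
diagnostic and agrees within 2%. Inner holes are ignored with a warning.

**Feret diameters** use rotating calipers on the convex hull: antipodal
pairs for `dmax`, edge-flush support lines for `dmin` (exact for convex
polygons). Brute-force oracles (all vertex pairs; a 0.1° direction grid)
back both in tests.

**Curvature.** The contour is resampled to uniform arc length at 4x its
native point spacing (grid-level wiggle must stay small against the
sagitta of the fitted arc), then an algebraic least-squares circle is
fitted at every point over a symmetric 5-point-radius window. Fits whose
RMS residual exceeds 15% of the fitted radius (floor: half the point
spacing) are discarded; the minimum accepted radius is reported. On
fixtures this recovers a 5 mm disk radius within 5% and 1 mm stadium caps
within 8%. Radii well below the pixel scale (the regime of a genuinely
sharp metal tip) are reported but are resolution-limited.

## Normative airway table

The built-in table transcribes radiographic means for children up to 4
years (glottis 9.8 ± 1.1 × 3.4 ± 0.9 mm, area 26.5 mm²; subglottis
8.5 ± 0.6 × 5.6 ± 0.8 mm, 38.1 mm²; cricoid 7.4 × 6.8 mm, 40.5 mm²),
ultrasonographic median proximal-tracheal diameters (7.3 mm boys / 6.5 mm
girls; unspecified sex takes the conservative minimum) and 2-year-old
endotracheal tube diameters (internal 4.0–4.5 mm, outer 5.3–6.0 mm).
No interpolation across ages is attempted — only the under-4-year block is
published, so any pediatric age returns the same constants flagged
"approximate reference". CT/MR ranges and the "1 mm narrowing halves the
cross-section" heuristic are carried as context strings for prompts, not
applied numerically. A user table in the same JSON schema can override the
built-in one.

## Risk rules

The published evidence provides shape categories and qualitative
comparisons but no validated scoring rule, so the engine's defaults are an
explicit reconstruction, declared in `RiskConfig` and echoed into every
profile:

- "comparable" means within ±20% of the reference value;
- indicators: glottic AP traversal (L1 vs 9.8 mm), glottic transverse
  mismatch (width vs 3.4 mm), cross-section traversal (2D area vs
  26.5 mm²), cricoid comparison (L1×width vs 7.4×6.8 mm²), ETT
  obstruction (L3 vs 4.0–4.5 mm), sharp-edge hazard (dihedral census),
  sharp-tip hazard (min curvature radius < 0.1 mm default), and an
  optional small-parts cylinder fit (dimensions config-only; the
  conservative rule `L2 <= diameter and L1 <= depth`);
- shape classes: `spherical_smooth` (psi >= 0.95, no sharp edges),
  `slim_sharp` (e >= 0.90 with any sharpness flag), `irregular_angular`
  (convexity < 0.90 or sharp edges), else `other`;
- tier: `high` when a sharpness indicator and an entry indicator (AP or
  cross-section traversal) are both triggered, `moderate` when exactly one
  group is, `low` otherwise. Worsening a hazard measurement can never
  lower the tier (property-tested).

Missing inputs mark indicators `not_evaluable`, never silently skipped;
aggregation with zero evaluable indicators is an error. Literature odds
ratios are attached as evidence text with citations, never multiplied into
a score.

## Report builder

The prompt is two messages: a system message assigning the expert role and
the instruction list (age/sex, dimensions/shape/sharpness, lodgment site,
complications, prevention, evidence-based reasoning, no overconfidence),
and a user message concatenating three labelled blocks (operator
description, measurement summary, normative table). Generation parameters
default to temperature 0.5 and 5000 max completion tokens; model names are
config strings with a primary and a fallback; top_p, penalties and seed
are intentionally left unset. Bundles serialize to canonical JSON and are
hashed (SHA-256) into every report's provenance. The offline narrative is
a pure template function of the risk profile — byte-identical for
identical inputs — and is also the fallback when every configured model
fails (the transport error and attempted models are recorded). The HTTP
client reads its API key from the environment at call time and never
stores or logs it. Every narrative carries a decision-support disclaimer.

## Synthetic fixtures

`make_mesh` generates watertight meshes with closed-form ground truth:
icospheres and scaled ellipsoids (inscribed, so volume/area converge from
below; per-subdivision tolerances are frozen from the measured chordal
deficit with headroom, and the ellipsoid area uses the Thomsen p=1.6075
approximation with its ≤1.07% bound folded into the tolerance), boxes
(exact), capsules (closed forms, segment-count tolerance), notched boxes
(a rectangular channel whose hull is the full box, so convexity is exact —
the default notch removes 32% of the cross-section, matching the worked
case's 0.68), and star prisms whose point ridges carry a closed-form sharp
dihedral equal to the planar apex angle. An optional seeded rigid motion
exercises invariance; every (kind, params, seed) triple regenerates
bit-identically.

`render_photo` rasterizes a dark shape (disk, square, stadium, simple
polygon) on a bright background with 4x supersampled anti-aliasing, a
yellow ruler band with anti-aliased dark ticks at an exact fractional
pixel spacing, and optional seeded salt-and-pepper noise. The shape centre
is offset by a fraction of a pixel so edges never align degenerately with
pixel centres. Ground-truth tolerances are per-field; polygons with acute
corners get looser area/perimeter/Feret tolerances (3.5–4%) because
segmentation smoothing truncates sharp corners — a real effect the
pipeline shares with any threshold-based method.

What the renders do **not** emulate: perspective distortion, uneven
lighting, shadows, sensor noise beyond salt-and-pepper, motion blur, or
3D-to-2D projection of an actual mesh. Passing tests therefore demonstrate
correctness of the measurement chain on ideal imagery at realistic scale
(~0.05 mm/px), not robustness to difficult photography.

## Problem sizes and numerical choices

Fixture suites use icosphere subdivisions 2–4 (~10²–10³ faces), 64-segment
capsules, and image canvases of ~640×480 px — sizes at which every
tolerance above has comfortable margin while the full test suite runs in
well under a minute for the geometry modules. Degenerate inputs raise
typed errors: rank-deficient vertex clouds (naming the rank), empty
meshes, truncated STL payloads (naming the byte count), empty
segmentations, sub-3-point contours, all-rejected curvature fits, and
aggregation without evaluable indicators.

## Known limitations

- The worked clinical case's raw mesh and photograph are not public; its
  mesh- and image-level values enter only as published constants driving
  the rule engine, and the derived-ratio and regression tests.
- 2D descriptors depend on the photographed orientation; only the 3D
  extents are orientation-free.
- The tier aggregation is a reconstruction, not a clinically validated
  score; it is deliberately transparent and configurable rather than
  predictive.
- Vertex-merge and watertightness handling do not repair meshes; holes
  are reported, not filled.
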