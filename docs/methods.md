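# Methods

This note documents the models behind `rastank`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic pipeline does
and does not capture about real recirculating-aquaculture (RAS) imagery.

## Schooling simulation

### Model

Fish are point agents in a cylindrical tank (floor at z = 0, invisible lid at
z = height, wall at the tank radius). Per step each fish receives:

1. **Boids steering** over neighbours within `perception_radius`:
   - *separation*: sum of `(p_i - p_j) / d^3` over neighbours with
     `d < min_separation` (inverse-square weighting, so the nearest intruder
     dominates), scaled by `separation_weight`;
   - *alignment*: `alignment_weight * (mean neighbour velocity - v_i)`;
   - *cohesion*: `cohesion_weight * (neighbour centroid - p_i)`.
   Each term and their sum are clamped to `max_accel` by rescaling.
2. **Boundary avoidance**: linear ramps from zero at a lookahead distance
   (default `max(wall_margin, 0.25 m)`) to a fixed strength (4 m/s²) at the
   boundary — inward at the wall, up at the floor, down at the lid — plus a
   barrier push along the outward normal of the nearest cuboid surface point,
   with linear falloff over `repulsion_range`. The field is continuous in
   position; a fish exactly on or inside the cuboid is pushed along the axis
   of least penetration.
3. **Vortex forcing**: tangential acceleration about the tank axis with
   magnitude `strength * exp(-|z - source_height| / decay_length)`; zero
   exactly on the axis, where no tangent exists.

Integration is explicit Euler: `v += dt * a`, speed clamped into
`[min_speed, max_speed]` by rescaling, `p += dt * v`, then a hard containment
pass that mirrors positions and reflects velocities at the wall, floor, lid,
and barrier faces. Containment is therefore exact at every step, and the
first-order convergence of the integrator is guarded by a dt-halving test.

### Defaults and rationale

| parameter | default | why |
|---|---|---|
| tank radius / height | 3.45 m / 4.0 m | a 150 m³ cylinder, the scale of a semi-commercial growout tank |
| wall margin | 0.2 m | fish stand-off from the physical wall |
| fish count | 200 | free parameter; stocking is usually quoted as kg/m³, not counts, so this is a rendering-density choice |
| perception radius | 1.2 m | a few body lengths for a ~35 cm trout |
| min separation | 0.3 m | just under one body length |
| separation / alignment / cohesion weights | 2.5 / 0.6 / 0.25 | separation-dominant mix that keeps the school collision-free while still polarised |
| max / min speed | 0.6 / 0.05 m/s | cruise speed of ~1–2 body lengths per second; a near-zero floor lets crowded fish stall instead of forcing contacts |
| max acceleration | 8 m/s² | burst manoeuvre scale; gives enough braking authority that two fish closing head-on at cruise speed stop well before half the separation radius |
| dt | 0.05 s | ~3 cm of travel per step at cruise speed |
| bottom vortex | +1 (counter-clockwise), 0.45 m/s², decay 20 m | dominant circulation driver; the long decay makes the forcing nearly depth-uniform, matching how round-tank circulation behaves through the water column |
| top vortex | −1 (clockwise), 0.02 m/s², decay 1 m | weak opposing swirl near the lid; kept small because a strong opposing vortex decelerates fish near the surface and makes them accumulate there (residence time scales inversely with speed) |
| barrier | cuboid at the wall in front of the camera, spanning the full water column | diverts fish horizontally around the camera zone at every depth; a partial-height cuboid pumps fish upward on every pass over its top face |

The steering weights, speeds and vortex pair were tuned against the package's
own invariant suite (containment, minimum pairwise distance ≥ half the
separation radius over 2000-step runs, a well-defined rotation direction, and
a vertically spread school), not against any external dataset.

**Initialization.** Positions are dart-throwing samples, uniform over the
swimmable cylinder, rejected inside the barrier or closer than
`min_separation` to an already placed fish — the school starts contact-free,
which an unconstrained uniform draw of 200 fish would not guarantee, and the
marginal distribution stays uniform. Headings are tangentially biased with
Gaussian jitter; speeds uniform in `[min_speed, max_speed]`. Everything is
driven by one `numpy` generator, so a seed fixes the trajectory bit-exactly.

## Rendering

**Camera.** Rectilinear pinhole; defaults follow a 140° HFOV 1920x1080
sensor. Focal length `fx = (width/2) / tan(hfov/2)`, square pixels, principal
point `(width/2 - 0.5, height/2 - 0.5)` so pixel (row j, col i) has centre at
projected coordinates (i, j); origin top-left, v grows downward. Depth is the
Euclidean camera-to-surface distance, not axial z. No lens-distortion model
is applied even at 140°: the rendering targets content, not radiometric
calibration, and distortion is listed under limitations.

**Geometry.** The procedural fish mesh is an ellipsoid body (salmonid
proportions, default 35 x 9 x 5 cm) with a flattened caudal fan, ~180
triangles. It is a deliberately simple stand-in — any `FishMesh` can be
injected. Each fish is posed by rotating the body axis to its velocity
direction (roll-free about world z) and translating to its position.

**Rasterization.** Per-triangle bounding-box scan with inclusive barycentric
inside tests, perspective-correct interpolation of the camera-space surface
point, z-buffering on camera z, nearest surface wins. Shading is flat,
two-sided diffuse from a single overhead direction (an area-lit indoor tank
has no strong shadows) with an ambient floor of 0.35. Triangles with any
vertex at or behind the near plane are skipped rather than clipped; fish that
close to the camera are not usable training content.

**Turbidity.** Beer–Lambert blend `out = T*rgb + (1-T)*background` with
`T = exp(-beta * depth)` and `T = 0` for background pixels, followed by a
depth-binned Gaussian blur with `sigma = blur_sigma_per_m * max(0, depth -
blur_start)` quantised into 8 sigma levels (background uses the farthest
level). The `low` (beta 0.18 m⁻¹) and `high` (beta 0.60 m⁻¹) presets are
qualitative: they are chosen to make distant fish respectively legible and
washed-out at tank scale, since no published scattering coefficients exist
for the conditions they emulate.

**Layered I/O.** Frames round-trip losslessly through NPZ containers with
arrays `rgb`, `depth`, `index` (the R,G,B / Z / ID channel semantics of
multi-channel EXR workflows). EXR itself is not bundled — requesting it
raises `UnsupportedFormatError` — because no OpenEXR backend ships with the
package's dependency set.

## Automated annotation

The instance-index layer is authoritative: all pixels carrying id k form
instance k, with no connected-component analysis, so a fish split into
disjoint pixel groups by occlusion still yields one (correct) box. The
representative depth is the **median** over the instance's pixels, which is
robust to boundary pixels catching the water background. Filtering applies
the pixel-count check first, then the depth check, with per-instance logged
exclusion reasons. Boxes are tight over the mask in COCO convention
(`x = min col`, `width = max col - min col + 1`); the record's `area` is the
true pixel count, not the box area; the centre is the 2-D mask centroid (a
3-D volume centroid would need the mesh, and the mask centroid is what a
detector's box centre estimates). Defaults `min_pixels=100`, `max_depth=3 m`
are repository defaults chosen for the default camera and presets; both are
mandatory arguments in the CLI precisely because they are scene-dependent.

COCO files carry `info`, `licenses`, a single category `fish` (id 1),
`images`, and `annotations` with float bboxes and `iscrowd=0`, written and
validated with the standard library's JSON tooling; reading checks the key
structure and reports the first missing key path.

## Dataset design

`mix_counts` turns a (total, virtual %, real %) spec into integer counts and
is strict by default: percentages must divide the total into whole images,
which all the standard 700-image designs do. `build_split` assigns
train/val/test by seeded shuffle with largest-remainder rounding and fills
validation and test exclusively with real images — the design's purpose is to
test sim-trained detectors on real imagery — failing loudly with the
shortfall when the real pool is too small. `build_manifest` composes both:
training size 700 at 70:20:10 implies 200 validation and 100 test images.

Augmentation is photometric only, so annotations carry over verbatim:
exposure gain in 1±0.25, brightness shift ±0.25 of full scale, saturation
scaled about Rec. 709 luma in 1±0.25, and Gaussian blur with sigma uniform in
[0, blur_range * max(H, W)] — the blur fraction has no canonical unit, so the
reference scale is explicit and configurable. "2X" augmentation produces two
variants per image; whether originals are retained is a caller policy
(`keep_original`, default true) since both conventions are in use.

## Metrics

Greedy confidence-ordered matching at IoU ≥ 0.5 (ties toward the lower
ground-truth index; equal confidences keep input order, making AP invariant
under permutation of tied detections). AP is the all-points
precision-envelope integral, the modern convention of the common evaluation
toolchains — not 11-point interpolation; users comparing against 11-point
numbers should expect small differences. Because the operating point behind
a single published F1 is rarely stated, `f1_sweep` exposes F1 at every
confidence cutoff and reports the maximum.

## What the synthetic data does not capture

- Fish appearance: one rigid procedural mesh, flat shading — no texture,
  undulation, size variation or per-fish colour differences. Detectors
  trained purely on these renders will overfit to simplified appearance;
  that is the domain gap the mixed-dataset design exists to measure.
- Optics: no fisheye distortion, refraction, caustics or sensor noise.
- Water: a single attenuation coefficient, no wavelength dependence or
  suspended-particle sprites.
- Behaviour: no feeding responses, wall-following individuality, or
  hydrodynamic interaction; collision handling is soft steering plus
  reflection, not rigid-body contact.

Passing the test suite therefore demonstrates internal correctness —
containment, oracle-equality of the rasterizer and annotator, exact dataset
arithmetic, metric definitions — not realism of the imagery.

## Problem sizes

The test and acceptance runs use deliberately modest scales chosen as
representative defaults: 50–200 fish, 500–2000 steps, 64x64 to 320x180
rasters, 10 seeds for Monte-Carlo invariants, 20 scenes for the turbidity
comparison. All are parameters; nothing in the implementation assumes these
values.
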