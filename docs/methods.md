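# Methods

## Problem and model

A single depth image observes only the near surface of an object; volume
estimation from it must reconstruct the self-occluded far side.  `depthvol`
implements the opposite-view completion approach: the observed depth map is
paired with the depth map an opposite-facing camera would see, the two views
are fused into one metric point cloud, and the enclosed volume is measured
by alpha-shape surface reconstruction.

The camera model is an ideal pinhole with intrinsics K = [[fx, 0, cx],
[0, fy, cy], [0, 0, 1]].  A pixel (u, v) with depth Z back-projects to
Z · K⁻¹ · [u, v, 1]ᵀ.  The world frame is fixed to the initial camera.  The
opposite camera is modelled as a 180° rotation about the initial camera's
vertical axis, Ry(180°) = diag(−1, 1, −1), plus a translation T, so an
opposite-view point p registers into the world as p_w = Ry(180°)⁻¹ (p − T).
For an object centred at distance d on the optical axis, T ≈ (0, 0, 2d).
Only T is ever estimated or refined; the rotation is fixed by construction
(conventions: right-handed, camera looks along +Z, image v-axis down).

## Synthetic study data

The generator replaces scanned household-object meshes with analytic
primitives whose volumes are closed-form: cube (edge 5.7 cm, 185.19 cm³),
sphere (r 3.65 cm, 203.69 cm³), cylinder (r 3 / h 5 cm, 141.37 cm³),
capsule (r 2.5 / l 6 cm, 183.26 cm³), plus an ellipsoid and a bent-capsule
("banana") whose Pappus volume π r² (R_bend·θ) + 4/3 π r³ is cross-checked
against a dense voxelization in the tests.  Meshes are built with trimesh
(the bent capsule by marching cubes on the arc distance field); at the
default resolution their discretization volume deficit is ≲ 0.2%.

Camera pose pairs are drawn uniformly from the training ranges: azimuth
0–360°, elevation (polar angle) 90–270°, camera distance 0.5–0.6 m,
centre shift ±0.1 m in both image-plane axes; the opposite camera sits on
the antipodal side (elevation + 180°, signed height −0.5 to −0.6 m read as
the mirrored position) with its own independent shift draw.  The opposite
orientation is exactly Ry(180°) relative to the initial camera, so every
sample carries an exact ground-truth translation.

Depth is rendered by a perspective-correct z-buffer triangle rasterizer
(first-surface depth, 0 where no surface) and stored, when written to disk,
as 16-bit PNG in millimetres.  Everything is reproducible from a seed.

What this emulates — and does not: the synthetic views are ideal pinhole
depth with no quantization (in memory), no multipath/occlusion artifacts,
no boundary mixed pixels and no background clutter, and the objects are
convex-ish solids on an empty background.  Passing tests therefore
demonstrate the geometric correctness and noise behaviour of the pipeline,
not robustness to real structured-light sensor pathology or segmentation
errors.

## View synthesis

The learning task maps the initial depth image to the opposite depth image
plus the inter-camera translation, with the cost
Σ_{u,v} (d̃ − d)² + λ‖t̃ − t‖², λ = 10⁻³ (raw pixel sum; a mean-per-pixel
toggle exists but is off by default).  Two variants are provided: a naive
convolutional encoder–decoder (four stride-2 stages to a latent vector,
nearest-neighbour-upsample decoder, softplus output so depths are
non-negative) and an inception variant that prepends two inception blocks
(parallel 3/5/7 kernels concatenated; the first strided) and adds a
translation head on the latent vector.  Exact channel counts and the latent
width are free parameters (defaults: 8 base channels, latent 128); the
implementation is a reconstruction of the architecture family, not a
replication.  Training is minibatch Adam (batch 16, lr 10⁻³), fully seeded
and single-threaded, with early stopping on a validation split — at the
reduced scale used in the tests (500 pairs) longer training overfits.

At that scale both variants converge toward the conditional-mean predictor
(the opposite view's in-frame position depends on an independent shift draw
and is inherently unpredictable), so the test suite asserts training
stability, validation-loss halving and a not-worse ordering of the
inception variant rather than any absolute loss value.

Because training at full scale is out of scope, the downstream stages are
exercised with an *oracle synthesizer*: the ground-truth opposite render
plus i.i.d. Gaussian depth noise (valid pixels only, clipped at zero) and
Gaussian translation noise.  Default study noise: depth SD 3 mm,
translation SD 20 mm per axis — the latter large enough that the ICP stage
is genuinely responsible for the final registration.

## Completion and translation refinement

Fusion pipeline: fill interior depth holes (bilateral-weighted; zeros
connected to the image border are background, not holes), bilaterally
smooth the valid region (per-pixel noise on the far surface otherwise
inflates the reconstructed envelope by roughly the noise amplitude), mask
the largest connected component, back-project both views, register the
opposite cloud through the Ry(180°) model, optionally refine the
translation, fuse, and remove statistical outliers (k = 20 neighbours,
threshold mean + 3 SD of the mean-kNN distance; 2 SD measurably trims the
legitimately sparse silhouette-rim samples and biases volumes low).

The translation refinement is the delicate part.  Point-to-point ICP
between the two *full* half-surface clouds has a strong wrong minimum that
collapses the far surface onto the near one, so the refinement matches the
back-projected silhouette *contours*: for exactly antipodal orientations
the two rims sample (nearly) the same 3-D curve, making contour-to-contour
ICP a full-overlap problem.  The stages are:

1. centroid alignment of the two contour clouds (capture range of several
   centimetres), then the translation-only ICP: nearest-neighbour
   correspondences, adaptive rejection max(5 × median spacing, 3 × median
   current distance), damped mean-residual steps with halving on cost
   increase — the cost history is non-increasing;
2. a second, quantile-trimmed phase (best 60% of pairs, floored at 6 mm)
   that locks onto genuinely shared rim segments when opposed centre
   shifts tilt the effective viewing directions and the silhouettes only
   partially correspond;
3. restoration of the *tangency gap* along the optical axis.  Contour
   matching drives the apparent rim gap to zero, but three measurable
   effects mean the true gap is positive: (a) sampling retreat — the
   outermost valid pixel sees a smooth limb of transverse curvature radius
   ρ about √(2·pitch·ρ) nearer the camera than the true tangent rim
   (~6 mm for fruit-sized objects at VGA); estimated per view by fitting
   the erosion-ring depth profile z(x) = c − m·x − b·√x (linear term for
   sharp edges, square-root term for curved limbs; ridge on b resolves
   their near-collinearity; effective ring distances 0.24 + 0.78·j pixels,
   calibrated once on analytic limb profiles) and extrapolating to the
   silhouette; (b) the perspective rim offset ρ · r_sil / Z between the
   tangent rims of the two views (r_sil = silhouette radius about its own
   centroid — the centre-shift component of the ray tilt averages out
   around the rim); (c) the measured depth drag of the bilateral smoothing
   at the contour, gated by the fitted limb-curvature weight since it only
   matters where the limb carries the volume.  Sharp-edged silhouettes get
   near-zero corrections by construction;
4. a one-sided free-space clamp: no fused point may sit measurably in
   front of a surface either camera observed (margin 3 mm, tolerance 1% of
   points); when the trimmed match still over-compresses (strongly opposed
   shifts on flat-sided objects), the registration is decompressed by
   bisection until consistent.

Residual registration error under the default noise is a few millimetres;
its volume impact is largest for spheres (~2% per mm of axial error).

## Volumetry

The alpha complex is built once per cloud from scipy's Delaunay
triangulation (tetrahedra with circumradius ≤ α are "in"), and the object
is treated as solid: excluded tetrahedra are flood-filled from the convex
hull, with the flood blocked by any triangle whose circumradius is ≤ α;
pockets never reached are enclosed cavities and count as solid.  The
volume is the sum of solid tetrahedron volumes (immune to the exactly
degenerate slivers that coplanar pixel-grid samples produce); the reported
boundary mesh is the outward-oriented solid/outside interface, with
winding repaired by propagation, and α → ∞ reproduces the convex hull.

The base alpha is 3 × the median nearest-neighbour spacing.  Two opposite
views necessarily leave an unsampled annular band at the silhouette rim
(the surface there is tangent to both viewing directions; centre shifting
widens it to ~1–3 cm at table-top scale), and no spacing-scale alpha can
bridge it, so `estimate_volume` walks a doubling alpha ladder and keeps
the first rung whose volume is stable under a further doubling (< 10%
change) *and* exceeds a quarter of the hull volume.  Below sealing the
"solid" is a thin shell one to two orders of magnitude smaller than the
hull, at sealing the volume jumps to the enclosed value, and past it it
creeps slowly toward the hull, so the first qualifying plateau marks the
sealed reconstruction.  The hull-fraction guard separates shells from
solids for any compact food-like shape; genuinely sheet-like objects
(a flat omelette, say) would need a different criterion — a documented
limitation.  Non-watertight boundaries yield a warned best-effort volume.

## Evaluation protocol and expected numbers

`evaluate` runs 15 trials per object (seeds base + trial), in two modes:
known extrinsics ("Vg") and noisy-oracle + ICP ("Vp"), reporting per-object
mean, SD and unsigned percent error against the analytic volume (objects
without one use the mean Vg as reference), and the mean error per mode.
At VGA resolution the known-extrinsics mean error across the four-primitive
suite is ≈ 1.5% (dominated by the unsampled rim band on smooth objects)
and the oracle+ICP accuracy ≈ 94–95%; a small number of trials with
strongly opposed centre shifts remain harder (partially shared silhouettes)
and dominate the residual error.  `scripts/acceptance.py` recomputes both
numbers from scratch.

Problem sizes used throughout (chosen to keep the full suite comfortably
reproducible on a laptop-class CPU): 480×640 evaluation renders, 120×160
unit-test renders, 64×64 training images, 500 training pairs, mesh
resolution level 2 (≈ 5k–8k triangles).

## Numerical choices and edge cases

- Invalid depth is exactly 0; negative or non-finite depths are rejected
  at construction.  Pixel centres at integer coordinates; projection
  rounds to nearest with ties away from zero and keeps the nearest point
  per pixel.
- ICP defaults: ≤ 100 iterations, 10⁻⁵ m RMS-change tolerance, step 0.5
  with halving; empty correspondence sets yield a not-converged result.
- Outlier removal passes clouds smaller than k+1 through with a warning.
- All randomness flows through seeded `numpy` generators; dataset builds
  are byte-reproducible.
- Depth PNG quantization is 1 mm; in-memory pipelines are float64
  (the training stack is float32 for speed).

## Known limitations

- The rim-band volume deficit is inherent to two opposite views; it is
  the main Vg error term for smooth objects (~1.5–3%).
- The tangency-gap corrections assume a locally convex limb; deep
  concavities at the silhouette would be mis-modelled.
- The alpha ladder's hull-fraction guard assumes compact objects.
- The view-synthesis models are test-scale reconstructions; no claim is
  made about full-scale (480×640, 20k pairs/object) training behaviour.
- Real-sensor effects (mixed pixels, multipath, holes from specularity)
  are out of scope of the generator; the hole-filling and smoothing
  stages exist for them but are validated only on synthetic defects.
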