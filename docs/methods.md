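# Methods

## Problem setting

The cochlea is a fluid-filled spiral of roughly 2.5 turns. Its two main
chambers — scala vestibuli (SV) and scala tympani (ST) — run in parallel,
separated by the cochlear partition (basilar membrane, organ of Corti,
scala media). Micro-CT stacks resolve the coiled lumina in many frames;
histology resolves the soft-tissue structures in a handful of sections.
`cochlea3d` reconstructs a 3D model by (i) estimating the spiral centerline
from labelled SV/ST point samples, and (ii) sweeping the 2D contours
annotated in one section along that centerline into per-structure surface
meshes. This note records the model, the parameters that matter, the
numerical choices, and what the synthetic phantom does and does not show.

## Synthetic phantom

Real specimen images are not redistributable, so every test and the
acceptance script run against a generated phantom with analytic ground
truth. The mid-curve is a tapering helix

    c(t) = center + r(t)(cos θ(t) u + sin θ(t) v) + z(t) a,   t ∈ [0, 1]

with θ sweeping `turns · 2π`, radius linear from `radius_base` to
`radius_apex`, and z the integral of a linearly tapering per-turn pitch.
Radius and pitch taper linearly in t because that is the simplest monotone,
analytically differentiable law. The two scala centerlines are mirrored
offsets of the mid-curve at ±`scala_separation/2` along the local radial
direction (pointing away from the helix axis), i.e. in the plane a
histology section would cut. Defaults: 2.5 turns, radius 4 → 1.5, pitch
1.5 → 1.0 per turn, separation 0.9, tube radius 0.4, all in abstract model
units (the real acquisition's absolute units are irrelevant to the
geometry and are reported inconsistently in the literature). A
minimum-distance check at generation time asserts the two tubes never
approach within one tube diameter of each other across turns.

Clouds sample each offset curve uniformly in t with isotropic Gaussian
jitter; the default study conditions are 4000 points per scala at jitter
σ = 0.25 × tube radius. Cross-sections are rasterized parametric shapes
(disks for the scala lumina, a small ellipse for the scala media, bands
for membranes) with additive Gaussian noise; the ground-truth contours are
the exact parametric boundaries. Image stacks are planar cuts of the two
solid tubes.

What the phantom does *not* emulate: X-ray physics, staining variation,
histology tearing and anisotropic deformation, intensity inhomogeneity,
and structures with genuinely fuzzy boundaries. Passing tests demonstrate
the geometry pipeline's correctness and its noise behaviour under the
stated conditions — not robustness to real histological artifacts.

## Hierarchical segmentation

Per slice: Gaussian smoothing + linear contrast stretch (monotone; a
constant image passes through), then a coarse-to-fine plan. Large lumina
with crisp boundaries are detected by a circle Hough transform on a Canny
edge map; the image is contrast-normalized first, which makes detections
exactly invariant to global intensity scaling. Accepted peaks are
non-overlapping disks, sorted by accumulator score (ties: smaller radius,
then lexicographic center). The working image is then cropped to the
detections (origin offset tracked so all contours return in global
coordinates), and smaller structures are segmented by a region-based
morphological Chan–Vese level set, initialized either from a configured
prior disk or by Otsu thresholding with previously claimed regions
excluded. Plans name their labels; optional per-label prior centers encode
anatomical location knowledge.

Consecutive slices are registered rigidly (rotation + translation, no
scaling — scaling is the projection module's job) by closed-form 2D
Procrustes on contours resampled to a fixed count by arc length.
Correspondence is by arc-length index; since independently traced contours
have arbitrary start points, the start is canonicalized to the vertex
farthest along the direction from the slice's joint centroid to the
contour centroid — a rigidly equivariant choice that stays defined for
near-circular contours away from the slice center.

## Mirrored-GMM centerline

The generative model is M *pairs* of isotropic Gaussian components laid
along an initial helix (user/config supplied, as the initial model is in
practice set manually), one pair member per scala, mirrored across the
helix at half the scala separation. Scala labels gate the E-step: SV
points see only SV components, ST points only ST components, with weights
renormalized within each group. Weights stay fixed and uniform.

The M-step preserves the initial geometry: first a single global affine
transform (12 parameters) of the *initial* means is fit by weighted least
squares to the responsibility-weighted barycenters; then each pair
receives one shared local affine correction, ridge-regularized toward the
identity with weight λ (default 1.0; the shared pair-level local is what
softly enforces the mirror symmetry). With two points per pair the local
problem is underdetermined and the ridge supplies the null-space prior.
λ → ∞ pins the locals so only the global affine acts. A candidate update
is accepted only if it does not increase the weighted squared distance to
the barycenters — a generalized-EM guard that makes the log-likelihood
trace provably non-decreasing. Starved pairs (total responsibility below
1e-12) are frozen in place with a warning, never deleted. EM is local, so
the means are first translated by the closed-form centroid offset between
model and data (exact initialization for a purely translated cloud). The
shared variance may optionally be re-estimated per iteration (off by
default — the default phantom fit is more accurate with the variance held
at its initial value, σ ≈ 0.8 × tube radius, wide enough to cover the
lumen but narrower than the component spacing).

Defaults that matter:

* `n_pairs` M = 64. Component spacing then approximates the tube
  diameter. Two error terms scale with spacing: the arc-chord bias of a
  component mean (the barycenter of a curved window lies inside the curve
  by ≈ R·θ²/24 per window angle θ) and the end shortening (below). At
  M = 64 the averaged-centerline RMSE on the default phantom is ≈ 0.05
  tube radii; at M = 32 it is ≈ 0.13.
* `init_variance` 0.1 (σ ≈ 0.32 ≈ 0.8 × tube radius).
* `max_iterations` 50–80, relative log-likelihood tolerance 1e-7.

**End extension.** The outermost components average one-sided
responsibility windows, so the fitted polylines stop roughly half a
component spacing short of the tube ends. Each end is re-localized from
the data: a local helical arc (planar circle plus linear out-of-plane
drift, least squares through the last 8 means) extends the end curve;
nearby points (within tube radius + 3σ of the curve — below the
inter-turn gap) get arc-length coordinates by nearest-point projection;
and the end position is the maximum-likelihood location of a smoothed
step, density ∝ Φ((T − s)/σ) with the known sampling σ. The appended end
vertex is finally re-centered laterally on the mean perpendicular offset
of the local points. The ML estimator is nearly efficient: its standard
deviation (~0.03–0.05 units under the default conditions) is close to the
Cramér–Rao bound for locating a Gaussian-smoothed edge at the phantom's
sampling density, so residual end error of ~0.1 tube radii is an
information limit of the data, not an implementation artifact.

**Resampling.** The pointwise average of the two (extended) scala
polylines is the cochlea centerline; averaging pair midpoints (rather
than separately smoothed scala splines) is a deliberate choice. A cubic
b-spline is fit through the polyline — interpolating when smoothing is 0;
the pipeline default smoothing budget is `n_vertices × (per-mean
position noise)² ≈ 0.01`, since an interpolating spline would chase the
component noise instead of the medial axis. Arc length is accumulated by
composite 8-point Gauss–Legendre quadrature of the spline speed; the N
stations (default 200, endpoints included) are placed by bisection on
cumulative length to 1e-9 of the total, giving gap uniformity well below
the 0.1 % contract. "Equal distant" is resolved as equal *arc length*,
not equal chord. Tangents are normalized spline derivatives.

## Frames, scaling, projection

The centerline tangent is the section-plane normal; the in-plane basis is
transported by rotation-minimizing frames (double-reflection method) from
a configurable reference direction (default: the helix axis), because
Frenet frames flip at low-curvature points whereas RMF twist is minimal.
Each triple is re-orthogonalized against the exact tangent to stop drift;
triads are right-handed to 1e-9.

Region areas are measured by the shoelace formula (self-intersection
rejected via a polygon-validity test). The scale profile uses the square
root of area ratios — a *length* scale must multiply coordinates — with
`s_max` the mean base ratio over the matched labels, `s_min` the apex
ratio, and linear interpolation in arc-length fraction in between. The
matched-region set defaults to the two scala lumina (present in both
modalities of the phantom).

A contour point (x, y) relative to the 2D anchor a maps to

    station_i + s_i ((x − a_x) n1_i + (y − a_y) n2_i)

an exact per-station similarity (pairwise distances scale by s_i to
1e-9). The anchor defaults to the centroid of the osseous-spiral-lamina
points nearest the annotation centroid (its modiolar edge) when present,
else the annotation bounding-box center; per-structure overrides are a
config knob. One annotated section is swept along all stations —
multi-section interpolation is out of scope.

In the end-to-end pipeline the two scala-lumen contours are swept along
their *own* fitted scala centerlines, each anchored at its own contour
centroid; other structures follow the averaged cochlea centerline. An RMF
twists relative to the anatomical radial direction by the integral of
torsion (~60° over the default phantom), so sweeping a scala as a fixed
in-plane offset of the central axis would displace it by a large fraction
of the scala separation; circular rings centered on the per-scala
centerline are rotation-invariant and land on the true lumen.

## Lofting and validation

Rings from the same contour share point ordering, so lofting joins them
index-to-index (a cyclic-shift-minimizing correspondence is available
behind a flag for externally supplied rings). Quads split along the
shorter diagonal (tie: the diagonal from the lower vertex index) to limit
slivers on tight turns. Caps are centroid fans; capped lofts of
non-self-intersecting stacks are watertight with Euler characteristic 2,
uncapped lofts have χ = 0 and two boundary loops, and V/F counts follow
V = RK (+2), F = 2(R−1)K (+2K). Counter-clockwise rings viewed against
the tangent give positive signed volume (divergence theorem). The
validator censuses edges exactly: non-manifold edges, same-direction
(flipped) interior edges, degenerate faces, boundary loops, Euler
characteristic, watertightness; it never mutates the mesh. Exports: OBJ
(own writer, named per-structure groups), binary little-endian PLY and
binary STL via trimesh. An exact point-to-surface distance (KD-tree
candidate faces + barycentric clamping) supports the geometric tests.

## Pipeline and reproducibility

The runner wires phantom generation (or real-input loading) → per-slice
hierarchical segmentation → rigid registration to the first slice → cloud
assembly → GMM fit → end extension and b-spline resampling → frames and
scale profile → sweeps → lofts → export. Every intermediate is
serialized; the manifest records the full effective config, per-stage
timings and file lists, registration transforms, the scale profile and
mesh-validation reports. A single global seed fans out per stage as
`(seed + crc32(stage_name)) mod 2³¹`, so any stage can be re-run in
isolation reproducibly; identical config + seed yields byte-identical
outputs (the manifest's wall-clock timings excepted). Stage failures
abort with the stage name and cause recorded in the manifest; completed
outputs are retained.

Default problem sizes — 4000 points per scala, 64 component pairs, 200
stations, 256² sections, 3 histology-like slices — are the package's
study conditions: large enough that the estimators operate in their
asymptotic regime, small enough that the full test suite and the
acceptance script each run in about a minute on one CPU.

## Known limitations

* Centerline end localization is information-limited (see above): under
  heavy sampling noise the reconstructed tube ends can be off by ~0.1
  tube radii, and this is seed-dependent.
* The mirrored pairing is enforced softly (shared local affine), not as a
  hard symmetry constraint; strongly asymmetric scala configurations are
  outside the model.
* Hough label assignment relies on configured location priors when
  several similar circles are present; there is no learned structure
  identification.
* Registration assumes rigid in-plane motion between adjacent sections;
  non-rigid histology deformation is not modelled.
* A single section is swept along the whole spiral with only a scalar
  linear scale profile; real cross-section shape change along the cochlea
  is not captured (multi-section interpolation is future work).
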