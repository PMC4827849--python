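# Methods

This note documents the models, numerical choices and open design decisions
behind each stage of the pipeline, and what the synthetic cohort does and
does not emulate.

## Synthetic cohort

The generator emulates the gross geometry of a hippocampus as a *canal
solid*: a circular-arc centerline (curvature `bend_curvature`, default
1/45 mm⁻¹) swept by a tapered radius profile
`r(s) = r_max sqrt(4 s (1 − s))` (default `r_max` 6 mm over a 36 mm
centerline), rasterized at 1 mm into a 64³ grid by testing each voxel
center against `min_s (|p − γ(s)|² − r(s)²) ≤ 0` on a 512-point arclength
grid. For a straight centerline this solid is exactly a prolate spheroid
with semi-axes `(sqrt(r_max² + L²/4), r_max, r_max)`, which the surface
tests use as a closed-form oracle.

Per-subject shape noise is a truncated random cosine series (5 terms) added
to the radius, scaled so its arclength standard deviation equals `noise_sd`
(default 0.25 mm) and tapered by the relative base profile so the ends stay
closed. Atrophy is a multiplicative radial shrink inside a Tukey window in
arclength: a flat core of width `extent_s/2` where the full shrink applies,
with raised-cosine flanks of width `extent_s/4` on each side. The flat core
exists so that "mean radial deficit inside the window" is a well-defined
recovery target equal to the implanted shrink; a fully tapered window would
dilute it by half. Dose 0/1/2 scales the shrink by 0/0.5/1. Subject seeds
derive from the master seed through `numpy` seed sequences, so cohorts are
bit-reproducible.

Not emulated: MRI intensities, segmentation errors, left/right asymmetry,
longitudinal within-subject correlation, and the digitations and C-shape of
a real hippocampus. Passing tests therefore demonstrate that the machinery
detects and localizes known radial effects on tube-like topology at
realistic mesh resolution — not that it reproduces any particular clinical
effect size.

## Surfaces and QC

Masks are pre-smoothed with a 1-voxel Gaussian before marching cubes at the
0.5 isosurface (staircase artifacts otherwise dominate curvature), then
smoothed 10 iterations of Taubin λ|μ (0.5 / −0.53) filtering, which is
shrink-resistant where plain Laplacian smoothing loses volume. Refinement
is by loop subdivision only, applied when a target vertex count asks for
more resolution; there is no decimation. Topology QC computes V − E + F,
boundary loops and manifoldness; only closed, manifold, genus-0,
single-component surfaces pass, automating the usual manual exclusion of
surfaces with handles. The 9-parameter affine (scale, then intrinsic x-y-z
Euler rotation, then translation) defaults to identity for synthetic data,
where no standard-space matrix exists.

## Conformal parameterization

The closed tube is opened by deleting the k-ring (default 2) of faces
around the two extremes of the first principal axis (ties broken by lowest
vertex index; the axis sign is fixed by its dominant coordinate so v = 0 is
the same anatomical end across similar subjects). On the resulting
cylinder, `v` is the harmonic potential of the cotangent Laplace equation
with Dirichlet data 0/1 on the boundary loops; `ω = dv` is exact. The
conjugate form `ω*` is the closed edge 1-form nearest (area-weighted least
squares, with per-face closedness imposed exactly through the KKT system)
to the 90°-rotated face gradient of the potential. Integrating `ω*` over a
BFS spanning tree gives `u`, single-valued modulo the period `U` (the loop
integral of `ω*` around a boundary loop); faces straddling the cut carry
per-face unwrapped u. The conformal factor is the vertex-ring ratio of 3-D
to planar area, and mean curvature uses the cotangent Laplace–Beltrami of
the embedding over Meyer-style mixed Voronoi areas (signed so a sphere of
radius r has H = +1/r).

On an analytic cylinder the construction is exact to solver precision; on
~5k-vertex synthetic tubes the median per-triangle angle distortion is
typically 0.5–1.1°. Occasionally one boundary sliver flips in the plane for
a particular hole size; the hole radii 1–3 are tried in turn and a subject
is excluded (with the reason in the manifest) only if all fail.

The feature image z-scores the conformal factor and mean curvature across
vertices before summing — the two carry incommensurate units (area ratio
vs mm⁻¹), so a raw sum would be dominated by whichever is numerically
larger — then linearly interpolates the sum onto a 128×64 raster (periodic
in u) and rescales to [0, 255].

## Fluid registration

Registration runs on the feature-image rectangle: u periodic, v with zero
normal displacement at the ends (boundary loops map to boundary loops).
Each subject's u-origin is a free gauge of the cylinder map, so an integer
circular cross-correlation shift in u pre-aligns the images before the
local model runs. The SSD body force drives the Navier–Cauchy operator
`μ∇²v + (λ+μ)∇(∇·v) = −f`, inverted spectrally per iteration: the v axis is
mirror-extended (even for the u component, odd for the v component) and the
2×2 Fourier symbol `μ|k|² I + (λ+μ) k kᵀ` inverted in closed form.
Defaults μ = 1, λ = 0; per-iteration motion is capped at 0.5 px, steps are
accepted only if the energy (SSD + consistency penalty) does not increase
and the incremental map does not fold (step halving otherwise), and the
moving image is regridded whenever the incremental Jacobian determinant
drops below 0.5 — together these keep the accumulated map diffeomorphic.

Inverse consistency alternates directions: each direction is re-estimated
warm-started from the inverse of the other with a quadratic penalty
(weight 2.0 by default) against drifting from it, and a final blend of each
field with the other's inverse cancels the remaining first-order
asymmetry (backed off if it would fold a map; skipped entirely at weight
0, which degenerates to two independent one-way registrations). Typical
inverse-consistency error on synthetic subject pairs is 0.1–0.5 px.
Correspondence transfer maps each template vertex's uv through the forward
field, locates the containing subject uv-triangle (periodic point location
via a centroid KD-tree with barycentric verification) and interpolates the
subject's 3-D coordinates barycentrically.

## Morphometry

With all subjects resampled on template connectivity and sharing the
template uv, the per-vertex 1-ring least-squares fits `T` (template) and
`S` (subject) map uv displacements to 3-D edge vectors; the correspondence
derivative in orthonormal tangent frames (u direction, orthonormalized v
direction, each surface using its own frame derived from the shared uv) is
`J = (E_sᵀ S)(E_tᵀ T)⁻¹`. This makes J exactly I for identical surfaces,
sI under uniform scaling, and invariant to rigid motion. The mTBM vector is
`(L11, √2 L12, L22)` of `L = ½ log(JᵀJ)`; the √2 weight makes the vector
2-norm equal `‖L‖_F`. Vertices with det J ≤ 0 (possible at the cut
boundaries) are masked, not imputed, and the mask is intersected across
subjects before inference.

The medial core is the area-weighted centroid of each of `n_levels`
(default 30 at this mesh resolution; empty bands raise) iso-v bands,
linearly interpolated between band centers; radial distance is the
Euclidean distance from a vertex to the core at its own v. Radial distance
is computed on post-affine (template-space) coordinates.

## Group inference

Σ is the pooled, Bessel-corrected covariance of the two groups, with a
ridge of `1e-8 · tr(Σ)/4` added for near-singular vertices. The permutation
test uses one shared schedule of label shuffles across all vertices — both
for speed and because the map-level null is incoherent otherwise — and the
add-one estimator `p = (1 + #{M_perm ≥ M_obs}) / (1 + n_perm)`, so p is
never 0. The map-level statistic is suprathreshold *surface area* in mm² on
the template (not vertex count). Its null is nested: each permutation's
vertex p-values are computed against the same shared null by ranking, which
costs one sort per vertex instead of n_perm² statistic evaluations.
Production default is 10,000 permutations; the test suite and acceptance
script use 500–1000, with sizes stated below. No covariate adjustment is
performed; selectors support stratification and pooling (e.g. dose {1,2} =
carriers) instead.

The CDF plots show the empirical distribution of vertex p-values against
the y = x null line and the Benjamini–Hochberg q = 0.05 reference line
y = x/0.05; they are descriptive, not a second correction.

## Simulation sizes and thresholds

- Conformality check: one ~4.8k-vertex tube; median angle distortion < 2°,
  1-form closedness residuals < 1e-8 (direct sparse solves).
- Geometry oracles: icosphere (2562 vertices, H within 5% of 1/r, in
  practice ~1e-5), analytic cylinder (radial distance within 2% of r).
- Registration: 128×64 rasters; synthetic 2-px warp recovered < 0.5 px RMS;
  min Jacobian > 0; inverse consistency < 0.5 px mean.
- Calibration: n = 20/20 Gaussian null, 200 Monte-Carlo reps, 500
  permutations, 16 vertices per rep (one designated vertex per rep gives
  independent trials for the vertex-level rate); rates must fall in the 95%
  binomial interval around 0.05, and permutation p must agree with the
  Hotelling T² → F p by two-sample KS at α = 0.01.
- Power/localization: 15% shrink, n = 25/25, 1000 permutations; corrected
  p ≤ 0.05 and Dice ≥ 0.5 between the p ≤ 0.05 region and the true window
  (where the window weight ≥ 0.5). The end-to-end recovered radial deficit
  is ~11–13% of the implanted 15% — registration smoothing dilutes the
  window edges — while the morphometry stage alone (analytically deformed
  surface, exact correspondence) recovers 15% ± 3%.
- Dose ordering: doses 0/1/2 at 0/7/14% shrink, n = 15 per group, 500
  permutations; the CDF deviation at p = 0.05 of the 14% contrast must
  exceed both 7% contrasts. The two 7% contrasts have equal effect size
  and are deliberately not ordered against each other.

## Known limitations

- The conjugate 1-form is the least-squares closed approximation of the
  Hodge star, not exactly co-closed; conformality error concentrates near
  the cut holes.
- The medial core is the iso-parameter center line, not a medial-axis
  transform; for strongly bent or branched shapes the two differ.
- Fluid registration matches a single scalar feature channel by SSD;
  images are min-max normalized per subject, so global contrast differences
  are absorbed but channel weighting is fixed.
- Map-level correction treats one surface at a time; analyses of paired
  left/right structures must either pool vertices before correction or
  correct per side.
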