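# Methods

This note records how `gingshape` computes what it computes, the choices
made where the design was genuinely open, and what the synthetic validation
does and does not demonstrate.

## Curvature estimation

**Model.** At each vertex the surface is represented locally as a Monge
patch z(u, v) over the vertex tangent plane and approximated by the full
six-parameter quadric z = a·u² + b·uv + c·v² + d·u + e·v + f, fitted by
ordinary least squares with the residual measured along the vertex normal.
The constant term is deliberately part of the model: the fitted patch need
not pass through the vertex, which is what lets the fit act as a noise
filter. Curvature is evaluated at (u, v) = (0, 0): the first fundamental
form is built from the fitted gradient (d, e), the second from
(2a, b; b, 2c)/√(1+d²+e²), and the principal curvatures are the
eigenvalues of the Weingarten map. The 2×2 generalized symmetric
eigenproblem II·y = k·I·y is solved in closed form through the Cholesky
factor of I, which guarantees real eigenvalues and I-orthogonal
eigenvectors; mapped through the surface basis X_u, X_v these become
Euclidean-orthogonal 3D principal directions.

**Tangent frame.** The vertex normal is the normalized area-weighted sum of
incident face cross products; the in-plane axes are derived
deterministically from the coordinate axis least aligned with the normal.
Curvature eigenvalues are invariant to the in-plane axis choice, which is
what the rigid-motion test exercises.

**Sign convention.** With outward normals, convex (bulging) surfaces are
positive: a sphere of radius r has k_min = k_max = +1/r, and a swollen
gingival margin carries a positive k_min tail. The quadric-level function
(`principal_from_quadric`) reports curvature of the graph itself (bending
toward the frame normal positive, so z = (u²+v²)/2 gives +1); the
mesh-level driver flips the sign because the frame normal points outward.
The shape index inherits the convention — a convex umbilic has SI = −1 —
and a single `orientation` flag flips it for pipelines using the opposite
convention.

**Neighbourhood.** The scale parameter is a *diameter*: the neighbourhood
of a vertex is the edge-connected component, containing the seed, of the
set of vertices within Euclidean distance diameter/2. Pure kd-tree balls
would borrow geometry across nearby but disconnected anatomy (an adjacent
tooth); the breadth-first restriction prevents that. Vertices whose ball
holds fewer than the six points a quadric needs fall back to expanding
topological rings and are flagged (`fallback`), as are rank-deficient
fits, which additionally receive a tiny ridge penalty so the field never
holds NaNs.

**Accuracy.** On analytic fixtures at 1–2 mm diameters the median absolute
error is ~1e-4/mm on a radius-10 sphere and ~2e-3/mm on a radius-5
cylinder. An unweighted least-squares quadric over a cap of chord radius c
on a sphere of radius r carries an irreducible truncation bias of order
c²/(4r³) (the quartic term of the sphere leaking into the quadratic
coefficient); on the torus tube of radius 2 mm at 1 mm diameter this bias
is ~7e-3, i.e. 1.6 % of the 0.5/mm tube curvature. Accuracy claims are
therefore stated as max(5e-3 absolute, 5 % relative) per fixture.

**Umbilics.** Exact ties k_min = k_max (within 1e-12 relative) get an
arbitrary orthonormal tangent pair as directions and an `umbilic` flag. On
estimated fields exact ties essentially never occur; SI at an exact
umbilic is defined by the continuity limit −sign(H) (0 at a flat point).
SI on a numerically flat surface is the shape of rounding noise — a
consequence of its scale invariance, not a defect — and is left as such.

## Six measures and their identities

MC = (k_max+k_min)/2, GC = k_max·k_min, SI = (2/π)·arctan((k_min+k_max)/
(k_min−k_max)), CU = √((k_max²+k_min²)/2). The test suite checks the
algebraic identities SI ≡ (2/π)·arctan(−H/√(H²−K)) and CU ≡ √(2H²−K) to
1e-9 on 10⁵ random pairs, plus SI ∈ [−1, 1], CU ≥ 0, H² ≥ K. Scaling
geometry and diameter together by s multiplies k_min, k_max, H, CU by 1/s
and K by 1/s² while leaving SI untouched; this exact law (the neighbour
sets are scale-invariant, so the fit scales algebraically) is asserted to
1e-6 relative.

## ROI construction

The margin and the mesial/distal line angles are *inputs* (CSV polylines);
detecting them is out of scope. The apical direction is one global unit
vector per scan — a deliberate simplification of the anatomy-driven
interactive choice; for the phantom it is −y.

* **Apical offset.** Each margin point marches apically along the surface
  in 0.1 mm steps (project direction to tangent plane, advance, re-project
  to the mesh) until 3 mm of on-surface path is accumulated. On a cylinder
  with an axial apical direction this reproduces the unrolled-plane
  geodesic to well under 2 %. Points hitting a mesh boundary are clamped
  and counted in a warning.
* **Band membership.** A vertex belongs to the band when it lies on the
  apical side of its closest margin point and the coronal side of its
  closest apical-boundary point, both inclusive — the margin line itself is
  kept inside the ROI on purpose; the GS percentile discounts it. No
  lateral clipping is applied beyond the curves' extent.
* **Central/interdental split.** Each line-angle curve defines a cutting
  plane containing the apical direction (least-variance direction of the
  curve after projecting out the apical axis). A curve running exactly
  parallel to the apical axis on a flat region leaves that plane
  underdetermined; the plane is then anchored with the mean surface normal
  along the curve. Per-tooth "inside both planes" scores label central
  regions; remaining band vertices go to the gap with the best score, so
  central ∪ interdental is an exact partition of the band.

Closest-point-on-mesh queries use an internal structure (kd-tree over
triangle centroids with a provably sufficient candidate radius plus exact
barycentric point–triangle tests).

## GS statistic

GS = the 95th percentile (linear interpolation between closest order
statistics — the mainstream numerical default; no rule is clinically
settled) of the *signed* measure values in an ROI, with a configurable
percentile for sensitivity analyses and a 20-vertex floor below which the
statistic is refused. Tables carry per-ROI descriptives (mean, sd, p5,
median, p95); `cohort_summary` aggregates GS across ROIs.

## Scan–rescan error

The two acquisitions are processed completely independently and joined on
(tooth, ROI kind, measure, diameter); the method error is the mean (or
median, as an option) absolute GS difference per group, reported alongside
the pooled cohort GS mean ± sd in signal-to-noise style bar charts. No
registration is used or needed.

## Synthetic data

**Analytic surfaces** (plane, sphere, cylinder, torus, saddle) come with
exact curvature callables and serve as oracles throughout the suite.

**Phantom.** A flattened dental arch as a height field: x mesio-distal, y
corono-apical, z outward. Ten teeth by default, 7 mm spacing with 2 mm
gaps, a scalloped margin (1 mm amplitude, cos² per tooth). Each tooth
carries a central margin-roll bulge and each gap a papilla bulge, built as
an axisymmetric two-circular-arc profile: a spherical cap core with a
tangent concave rounding back to the base. Inside the core the surface is
an exact sphere patch, so the central bulge (radius 3 mm, footprint 2 mm)
pins ground truth k_min = 1/3 per mm and the papilla (radius 5 mm,
footprint 1.5 mm) pins MC = 0.2 per mm; off-core the tangential curvature
is provably below the core value, so the 95th percentile lands on the
core. Default mesh resolution 0.15 mm, comparable to intraoral scanners.
Ground-truth zone labels use the band's declared closest-point semantics
for the margin side but an independent per-column arc-length integration of
the analytic height field for the apical boundary, so label agreement tests
the marching implementation rather than echoing it.

**Rescan simulation.** Gaussian displacement along vertex normals (default
sd 0.02 mm, first-order optical scanner noise), one boundary-pinned uniform
Laplacian pass, then vertex-clustering decimation of the midpoint-subdivided
mesh on a randomly offset grid at the original mean edge length — the
rescan has genuinely different connectivity, as real consecutive scans do.
Deterministic given the seed.

**What the phantom does not emulate:** curved arch geometry (it is
flattened), tooth surfaces and their specular scan artefacts, soft-tissue
texture, margin-detection error (curves are exact), and patient-level
anatomical variability. Passing phantom tests therefore validates the
geometry pipeline, not clinical performance; the clinical cohort statistics
of real scans are not reproducible here and are not claimed.

## Validation problem sizes

The standard study used by the tests and the acceptance script: 10-tooth
phantom (~20k vertices, ~14.5k per simulated acquisition after remeshing),
three diameters (0.5/1/2 mm), two acquisitions; analytic fixtures of
2.5k–13k vertices; a 10k-vertex dense sphere for the noise ladder. These
sizes keep a full run in the low minutes on one CPU while leaving every
neighbourhood scale well resolved.

## Known limitations

* The quadric truncation bias grows with (diameter/feature-radius)²; at
  2 mm diameters on sub-millimetre features the estimates are intentionally
  smoothed (that is the point of the scale parameter), so GS values at
  different diameters are not interchangeable.
* The band has no lateral clipping: margins whose curve ends mid-arch will
  pick up band vertices beyond the curve ends via endpoint projection.
* Colour-scale thresholds are configuration with no clinically validated
  defaults.
* Orientation of open scans trusts the stored winding (the centroid vote
  applies only to closed shells); inside-out exports need the explicit
  flip flag.
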