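# Methods

## Model and assumptions

The monolayer is modeled as a curved membrane: a two-dimensional surface
carrying a symmetric tangential stress tensor σ (force per unit length)
and no bending moments. For a closed pressurized cap attached to the
substrate along its contact line, mechanical equilibrium on the
free-standing part reads

    div_s σ = 0            (tangential, 2 equations)
    σ : b   = ΔP           (normal; b = second fundamental form)

with ΔP the luminal pressure. Because curvature supplies a third
equation, the three independent components of σ are determined by shape
and pressure alone — no constitutive law enters. The membrane assumption
is appropriate for thin, tense monolayers around pressurized lumens;
strongly columnar epithelia with large bending stiffness are outside the
model. When ΔP is not measurable the system is solved at unit pressure
and all tensions are relative ("up to a scaling factor"), which the
results object reports explicitly.

Sign conventions: the substrate plane is z = 0, the footprint centroid is
the origin, the lumen lies under the cap, and the outward normal has
positive z over the cap interior. Curvature is positive for a pressurized
cap bulging upward (a sphere of radius R has k = 1/R), so positive
pressure produces positive tension. Internally tensions are Pa·µm;
user-facing values are mN/m (1 mN/m = 1000 Pa·µm), pressures Pa, lengths
µm.

## Discretization

Stress components are piecewise linear at mesh vertices, expressed in
per-vertex orthonormal tangent frames. All three equilibrium equations
are contained in the single ambient statement div_s(Σ) + ΔP n = 0 for the
tangential 3×3 tensor Σ; its Galerkin residual against hat-function test
fields at interior vertices is evaluated per vertex along the local
(t1, t2, n) directions. On a polyhedral surface the normal balance is
encoded by the dihedral angles between faces, which avoids committing
the solver to any particular pointwise curvature estimate. Rows are
weighted by 1/sqrt(vertex area) so the residual norm is an L2 norm of a
force density. No boundary condition is imposed on σ at the contact line
(natural boundary condition): the boundary tension is an output used for
validation, never an input.

Test functions exist only at interior vertices, so the system has a
deficiency of order the number of boundary vertices; it is closed by a
Tikhonov penalty λ‖D σ‖², where D takes differences of the component
vectors across edges after parallel transport of the frames (minimal
rotation between vertex normals), divided by edge length and scaled by
the mean edge length. Two details matter:

- the component metric is the Frobenius metric (the shear component
  counts twice); with a plain 3-vector norm the penalty would depend on
  the arbitrary frame orientation and rigid rotations of the input would
  change the answer at the percent level.
- the mean-edge-length scaling makes the penalty a mesh-scale-normalized
  jump seminorm: its bias vanishes under refinement and the same λ is
  transferable across resolutions.

The normal-balance residual of a fitted field is additionally evaluated
pointwise against a second, independent discretization of b: per-vertex
quadric fits of the height function over two-ring neighborhoods in the
vertex-normal frame (first/second fundamental forms from the fitted
quadric, principal curvatures from the generalized eigenproblem II v =
k I v). This quadric-fit `CurvatureField` also provides all geometric
quantities (curvature anisotropy, near-flat masking); boundary vertices
have incomplete rings and are flagged as extrapolated.

## Choice of the penalty weight

The classical L-curve corner is undefined here: on clean analytic meshes
the problem is noiseless, the (log residual, log smoothness) curve has no
elbow, and corner-hunting collapses to near-zero penalties that amplify
the near-null modes of the equilibrium operator. (The clearest example is
a tube: on a cylinder the axial tension distribution around the
circumference is not constrained by local equilibrium at all — it is set
by the end caps — so under-penalized solutions fill those modes with
noise.) The default selection is therefore a physical criterion: sweep
log-spaced candidates (10⁻⁵…1, 11 values) and pick the weight minimizing

    score(λ) = normal-balance rms + relative roughness
             = rms[(σ:b − ΔP)/ΔP]  +  ‖D σ‖ / ‖σ‖_L2 .

The first term is computed against the quadric-fit b, which the solver
does not use, so it is an independent check that catches over-smoothing
(the field stops satisfying Young–Laplace pointwise); the second,
dimensionless term catches under-smoothing (noise-amplified modes that
the normal balance cannot see). On verification geometries this lands
each family in its accuracy optimum: spheres pick large λ (the true field
is uniform; smoothing is free), spheroidal caps with genuine tension
gradients pick λ ≈ 10⁻⁴–10⁻³, tube caps pick λ ≈ 3·10⁻². The L-curve
selector remains available (`fit(lam="lcurve")`), as does a fixed weight.

For fixed λ the solution is exactly linear in ΔP.

## Boundary traction and global force balance

Two read-outs of the contact-line tension σ·ν (ν = in-surface outward
conormal) are provided:

- *pointwise*: contract the vertex stress tensor with ν — simple, but at
  the boundary the field is the least-determined part of the solution and
  the smoothness penalty biases it (up to ~15% on square footprints);
- *weak-form flux* (default in `predict_boundary_traction`): evaluate the
  equilibrium residual against boundary test functions, the discrete
  analogue of FEM reaction forces. This is consistent with the divergence
  theorem and substantially more accurate.

Integrated force functionals are still affected by the penalty, so
`contact_line_force()` evaluates the flux on a minimally penalized
re-solve (smallest candidate weight): pointwise noise in that solution
cancels in the integral, and the vertical balance ∮σ_rz ds = ΔP·A then
holds to better than 1% on every verification family. The predicted
substrate traction is T_z = σ_rz / l_T with the transmission band width
l_T defaulting to 15.7 µm (about one cell diameter); `calibrate_l_T`
recovers it from paired tension/traction medians as
l_T = median(σ_rz)/median(T_z).

## Traction-grid observables

Traction grids are regular xy grids of (T_x, T_y, T_z) in Pa, tractions
exerted by cells on the substrate, T_z > 0 up. Pressure is measured as
−mean(T_z) over a scaled-down central footprint (linear scale 0.5 by
default, configurable; at least 25 grid points required) to avoid
boundary effects. Boundary profiles are medians of T_z in a band of
width `band_width` placed immediately *outside* the footprint outline —
that is where the adhered cells transmitting the suspended tension sit; a
band centered on the outline would mix in the luminal −ΔP signal.
Rectangles report one median per side over the central 50% of the side's
length, with short/long labels; ellipses report medians per polar-angle
bin after folding the four quadrants into β ∈ [0°, 90°] (β = 0 on the
major axis). Band points are attributed the parametric angle of their
nearest outline point; using the point's own angle would distort the
profile near the highly curved ends of eccentric ellipses. Empty bins
are NaN, never interpolated. Stress–strain binning uses equally spaced
areal-strain bins and drops bins with fewer than 3 points.

## Cell orientation

Cell outlines on the dome are projected to the tangent plane at the
centroid (nearest-vertex normal; centroids more than 2 µm off-surface are
rejected) and reduced to the second-area-moment ellipse, with the
convention R_i = 2·sqrt(eigenvalue/area) which is exact for ellipses.
α is the acute tangent-plane angle between the long axis and the local
σ_I direction; it is undefined (NaN, excluded from statistics) where the
stress is numerically isotropic or the cell circular. Region binning on
elliptical footprints uses the footprint polar angle of the projected
centroid (β ≤ θ_c from the major axis → major-axis region, ties to
major) and a height threshold (top if z ≥ fraction × dome height);
defaults are θ_c = 45° with 50% for aspect 2:3 and θ_c = 30° with 40%
for aspect 1:3.

Two resampling statistics: the uniform-null median test draws `n_rep`
(default 10⁴) samples of the observed size from Uniform(0°, 90°) and
returns the two-sided rank position of the observed median among the null
medians, p = 2·min(r, n_rep − r)/n_rep floored at 1/n_rep; the bootstrap
median CI is the percentile interval over `n_rep` (default 10⁴)
resamples with replacement.

## Synthetic data

The generators emulate the study conditions: spherical caps with
footprint diameters 25–200 µm; caps of ellipsoids of revolution
(circular footprint, meridian axis ratios such as 2:3 and 1:3) which are
the shapes with an exact axisymmetric membrane solution; ellipse-footprint
caps (scaled sphere caps, aspects 2:3 and 1:3); and rectangle-footprint
tube caps (aspects 1:1, 1:2, 1:4). Inflation is dome height over
footprint half-width; tube caps accept up to 1.0 (half-cylinder), caps of
revolution up to 1.2 (slightly past hemispherical). Meshes are built from
closed rings uniform in profile arc length (zipped into triangle strips,
apex fans for caps), so triangle quality stays good even where the
surface is steep; the reference edge length (default ≈ footprint
size/20–36, giving 1000–3000 vertices) is exposed.

Tube caps are z = arch(y)·taper(x): a circular-arc cross-section swept
along the long axis with a smooth cosine taper to zero over one
half-width at each end. The central cross-section is exactly the arc;
corners are smooth flat points, so the footprint keeps exact sharp
corners. Real dome end-caps have unknown shape; this construction is an
idealization and end regions are excluded from oracle comparisons.

The axisymmetric oracle evaluates, along a sampled meridian
(arc-length-parameterized splines), N_φ = ΔP·r₂/2 from the closed-form
axial balance and N_θ from N_φ/r₁ + N_θ/r₂ = ΔP; the identity is
satisfied by construction and the numerical content (r₁, r₂ from spline
derivatives) is verified against sphere and cylinder closed forms. The
tube oracle gives hoop ΔP·R_c and mean axial ΔP·A_cs/s_arc (pressure on
the lumen cross-section spread over the arc), reducing to ΔP·R_c/2 at
the half-cylinder limit.

Traction grids are painted as −ΔP inside the outline and σ_rz(s)/l_T on
the outer band of width l_T (nearest-boundary attribution), with
in-plane components from the horizontal boundary tension and i.i.d.
Gaussian noise (default 5 Pa in the verification loop — of the order of
the noise floor of soft-gel traction microscopy). This construction
balances the vertical force to O(κ·l_T) geometric corrections (exact on
straight rectangle sides). Synthetic cells draw area-uniform centroids,
axial von-Mises orientations of concentration κ about a supplied
direction field (κ = 0 uniform), and elliptical outlines in the local
tangent plane (default semi-axes 8×5 µm ± 15%). Point clouds sample xz/yz
section curves spaced 7.5 µm (typical annotated-slice spacing) with
optional Gaussian jitter. All generators are deterministic under a fixed
seed.

What the generators do *not* emulate: spatially correlated segmentation
error, monolayer thickness (the fitted surface is a single sheet; the
half-thickness radius offset is a user parameter, default 0), apicobasal
tension asymmetry, cell-scale stress heterogeneity, and time dynamics.
Passing the verification suite therefore demonstrates correctness of the
mechanics and of the pipeline plumbing under controlled noise, not
robustness to every artifact of real confocal data.

## Surface fitting

`fit_smooth_surface` represents the dome as a height graph z(x, y) over
the footprint: a thin-plate smoothing spline (scipy RBF, roughness weight
exposed as `smoothness`) fitted to the point cloud with the contact line
pinned to the footprint outline at z = 0, evaluated on a ring
triangulation of the footprint. The graph representation is adequate up
to roughly hemispherical inflation; overhanging shapes are out of scope
for the fitter (synthetic meshes handle them). Preconditions: ≥ 50
points, cloud above the substrate (2 µm allowance), xy-projection inside
the outline within a 10% margin. The spherical-cap fit is the algebraic
least-squares sphere; ε_a = (h/R_b)² with h = c_z + R.

## Numerical choices and tolerances

- boundary vertices must satisfy |z| < 0.5 µm (below optical z
  resolution); degenerate triangles (area ≤ 1e-12) are dropped.
- near-flat handling: vertices with both |k| < 1e-4 µm⁻¹ get zero weight
  in the normal-balance row; if more than half the surface area is flat
  the inference is rejected as ill-posed.
- interior masks for oracle comparisons exclude a boundary margin of
  0.25 × the lateral scale sqrt(area/π) (≈ one to two cell diameters),
  where the natural-boundary-condition layer lives. Verification
  tolerances: spheres within 2% pointwise; caps of revolution within 5%
  at the 95th percentile (normalized by the local oracle σ_I — the
  hardest case, a 1:3 spheroid near its feasibility limit, has isolated
  mask-rim points at 5–6%); tube interiors within 5%.
- principal decomposition is the closed-form 2×2 eigensolve; isotropy is
  flagged when the eigenvalue gap is below 1e-9 of the trace (exact
  constructed fields only — numerically inferred fields on spheres carry
  percent-level anisotropy noise and keep their directions).
- region-bin ties go to the lower bin (major axis); cells straddling
  region boundaries are assigned by centroid only.
- sparse solves use a direct factorization of the normal equations; the
  candidate sweep re-uses the assembled operators.
- problem sizes in the test and verification suite (meshes of one to
  three thousand vertices, 3 rectangle and 6 ellipse validation cases,
  500 null datasets × 250 replicates for the median test, 200 rounds ×
  400 replicates for bootstrap coverage) are chosen to resolve the
  quantities being checked on a single CPU; production analyses can
  raise them freely.

## Known limitations

- Bending moments and apicobasal tension asymmetry are neglected by
  construction; the method quantifies membrane tension only.
- The boundary layer (within ~one cell diameter of the contact line) is
  regularization-dominated pointwise; use the flux read-out and
  integrated quantities there.
- Stress on near-flat regions is filled by the smoothness prior, not
  measured; the normal balance carries no information where curvature
  vanishes, and on cylinders the axial component is constrained only
  globally (through the end caps).
- The surface fitter assumes a height graph; strongly overhanging domes
  require a different parameterization.
- Ellipse-footprint caps have no closed-form membrane solution; they are
  verified indirectly (force balance, symmetry, the traction loop)
  rather than against an analytic oracle.
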