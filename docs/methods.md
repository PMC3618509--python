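# Methods

This note records the science and the numerical choices behind `surfray`:
what each stage computes, the parameters that matter, what the synthetic
fixtures do and do not emulate, and the known limitations.

## Surfaces as ray oracles

Every surface kind implements one contract: given a ray, return the sorted
crossings with outward (material-to-solvent) normals.  The builders differ
only in how they realize it.

### SES / VdW / SAS

The solvent-excluded surface is assembled from the regular triangulation
(RT) of the probe-inflated balls `(cᵢ, Rᵢ + r_p)`.  The RT is computed as
the lower convex hull of the 4-D lift `(c, ‖c‖² − w)` with Qhull; points
absent from the lower hull are power-hidden (their ball is covered) and
contribute nothing.  From the RT:

* every exposed atom emits a convex sphere patch of radius `Rᵢ`;
* every RT edge whose inflated spheres intersect in a circle with at least
  one unblocked arc emits a saddle torus (center and axis on the edge
  line, major radius = circle radius, minor radius = `r_p`).  Blocked
  angular intervals are computed exactly per neighbouring ball and merged;
* every RT triangle whose two trisector points (tangent probe positions)
  clear all inflated balls emits a concave probe patch per valid position.

**Patch clipping.**  Let Ω be the free-probe region (centers clearing
every inflated ball).  A candidate point `p` with realizing probe center
`q` (the radially tangent probe for convex patches, the circle projection
for tori, the patch center for concave patches) is on the SES iff `q` is
free and `p` is at least `r_p` away from every other part of Ω.  The
second condition is tested per stratum of Ω's boundary: its faces (the
radial foot of `p` on a nearby inflated sphere is itself a free probe),
its edges (distance to the stored free arcs), its vertices (distance to
the other trisector probes), plus Ω's interior (`p` itself clears every
inflated ball).  This is exactly the boundary-of-the-union-of-probe-balls
membership test, so self-intersections of saddles and concave patches in
crowded geometry — deep pockets, internal cavities, the fullerene interior
— are clipped correctly without case analysis.  Simpler per-patch trims
(contact wedges, contact spherical triangles) were tried first and fail
precisely there: a concave patch legitimately extends beyond its contact
triangle wherever the adjacent probe arc is blocked.

VdW is the SES with `r_p = 0` (the strata collapse to plain
union-of-balls membership); SAS is the VdW of the inflated radii.

Tolerances: probe-clearance clash tolerance 10⁻⁷ Å; strata cut
`r_p − 10⁻⁹`; seam points shared by adjacent patches are reported by both
and collapsed by the caster's coincident-hit filter (10⁻⁹ in `t`).

### Skin

For weighted points `(cᵢ, wᵢ = Rᵢ²)` and shrink `s`, the skin is the
boundary of the union of all convex-combination balls shrunk by `s`.
Minimizing the shrunken-ball deficit per RT simplex σ gives, inside σ's
mixed cell, the quadric

    ‖(x − z)_N‖² / s  −  ‖(x − z)_E‖² / (1 − s)  =  −w_z

with `z, w_z` the orthocenter and squared orthoradius of σ, `E` the
simplex direction space and `N` its complement; the body is the `f ≤ 0`
side.  Specializations: vertices give spheres of radius `√s·Rᵢ`;
tetrahedra give *void bubbles* — spheres of squared radius `(1−s)·w_z`
around the orthocenter with the material outside — exactly when the
orthosphere is real; edges and triangles give hyperboloids of revolution.
The same derivation fixes the mixed cell as `(1−s)·σ ⊕ s·ν(σ)` with
`ν(σ)` the dual power-diagram face: this pairing (and not its mirror) is
the one that reproduces the two anchors `s = 1 →` union of balls and
vertex-patch radius `√s·Rᵢ`, and it is validated against a
definition-based membership oracle in the tests.  Because cells and dual
faces are convex, the cell clip is a pure conjunction of half-space trims,
assembled from the barycentric map `p(x) = z + P_E(x−z)/(1−s)` and the
power map `q(x) = z + P_N(x−z)/s`.

`s = 1` is clamped internally to `1 − 10⁻⁷` so the non-vertex cells stay
well-defined; the surface then matches the union of balls to that
tolerance.  Bounding boxes of boundary-simplex cells (unbounded dual
faces) fall back to the union-of-balls box — conservative, never too
small.

### Gaussian

Field `Σᵢ exp(B(‖x−cᵢ‖²/Rᵢ² − 1))`, `B < 0`, accumulated atom-wise with a
6 Å cutoff, iso-value 1.  With this kernel the isolated-atom isosurface is
exactly the VdW sphere, which anchors the tests.  Ray crossings bracket
sign changes of the trilinear interpolant at `h/8` steps and bisect to
10⁻⁹; exact-zero samples count as inside so that a surface passing exactly
through grid vertices is still crossed.  The trilinear interpolant biases
the crossing outward by `O(h² f''/f')`; at `B = −2.5`, `R = 1`, `h = 0.25`
this is ≈ +1.4 % in radius (≈ +2.8 % in area), shrinking quadratically
with `h`.  Defaults `B = −2.5`, cutoff 6 Å, iso 1.

### Imported meshes

OFF / ascii PLY / MSMS pairs are manifold-checked on load (every edge in
exactly two triangles; offending edges listed).  Ray/triangle tests are
barycentric (Möller–Trumbore); hits within 10⁻¹⁰ of a shared edge or
vertex are assigned to exactly one owning triangle (lowest incident face
index) so a crossing through an edge is counted once.  Zero-area faces are
treated as misses and counted for diagnostics.

## Geometry kernels

Ray/sphere and ray/quadric reduce to quadratics; tangencies (discriminant
within 10⁻¹² of zero, scaled) are discarded — grazing contact must not
change parity.  Ray/torus builds the quartic of the implicit form and
isolates its roots with a Sturm sequence: the chain is constructed in
closed form for the (generic, square-free) quartic case with
bisection-plus-safeguarded-Newton refinement to 10⁻¹⁰, and falls back to a
generic Sturm chain with square-free deflation and derivative-based
multiplicity classification when the fast chain degenerates.  Even-
multiplicity roots (tangencies) and spindle-sheet roots (points of the
inner self-intersection sheet, recognized by the distance-to-circle test)
are dropped.  All kernels are validated against dense sign-change scans
and the eigenvalue companion-matrix solver, and are rigid-motion invariant
to 10⁻⁹.

## Grid, rays, parity

The cubic grid spans `(largest bbox side)·100/perfil` per axis, centered
on the solute, with `h = 1/scale` exactly and odd vertex counts (even cube
counts) — the finite-difference convention of Poisson–Boltzmann solvers.
Grid rays run through cube centers (statuses at centers and at the face
centers orthogonal to the axis, plus inside intervals); edge rays run
along the vertex lattice lines (vertex statuses and the analytic crossings
stored per grid edge).  Statuses seen from all three axes are combined by
majority; disagreements are counted.

Parity protocol: odd crossing counts are recast with a fresh uniform
transverse jitter of `0.01·h` (seeded), up to 5 times; an exhausted ray
copies the classification of the last completed ray in its casting plane
(scan order) and is flagged.  Per-axis 2-D acceleration grids (cell
`2h`) hold patch ids by bounding-box projection; SES torus boxes are
tightened to the free probe arcs ± `r_p`, which is what makes dense cages
affordable.  A vectorized slab test prunes the per-ray candidate list
before any quartic is solved.

## Volumes, cavities, triangulation

Volume per axis is `h² Σ` interval lengths — a midpoint quadrature of the
chord field.  Its error is `O(h^{3/2})` with an alignment-dependent
constant: bodies centered exactly on the lattice symmetry point (every
single-atom fixture, by construction of the grid) sit at the worst case
(≈ +2.6 % for `R = 1` at `h = 0.25`, measured against the closed-form
midpoint sum), while generic alignments are several times better.  The
estimator and grid placement are kept as specified; the residual bias is a
property of the discretization, not of the implementation.  Cross-axis
agreement reflects quadrature fluctuation and needs a body resolved by a
few tens of cells: the 8 Å hollow-shell fixture shows < 0.1 % spread at
scale 3, while a 2 Å two-atom system at the same scale fluctuates by
1–2 % in any orientation.

Cavities are 6-connected components of outside-status cube centers not
touching the grid boundary; filling toggles below-threshold cavities
(default 11.49 ų = a 1.4 Å water sphere) to inside and repairs the
1-cell halo — faces between two inside cubes become inside, vertices with
eight inside neighbours become inside, edge hits with two inside endpoints
are dropped, mixed edges keep the hit nearest the surviving outside
vertex — so the subsequent triangulation sees a consistent field.  A full
re-cast remains available for verification.

Marching cubes uses tables derived at import time: the cut edges of each
of the 256 configurations are paired around the faces (on an ambiguous
face the two cut edges sharing an inside corner pair up, so diagonal
inside corners are never connected — a symmetric rule that cannot produce
cracks between neighbours), chained into cycles, fanned, and oriented
outward via the Newell normal against the inside corners.  The analytic
variant places vertices at the stored edge crossings (several crossings on
one edge: the one nearest the outside endpoint; a mixed edge without a
crossing falls back to the midpoint and is counted); the bisecting variant
infers vertex statuses from the eight surrounding cube centers (majority,
ties outside) and uses midpoints throughout.  Laplacian smoothing (default
off; `λ = 0.5`, 1 iteration when on) trades the on-surface property for
triangle quality and shrinks area monotonically.

An inscribed triangulation underestimates a convex surface's area by the
chordal deficit ≈ 0.24·(h/R)² (−1.4 % for `R = 1` at `h = 0.25`, −6 % at
`h = 0.5`); a reference marching-cubes implementation with vertices
projected onto the exact sphere shows the same deficit, so this is the
floor of any grid-consistent mesh at that resolution, not a defect of the
vertex placement.

The incident-ray estimator divides by `max(|cos θ|, 0.1)`; the clamp value
is our choice.  It is strongly orientation-sensitive (15–30 % spread over
rotations on the two-atom fixture), the three-axis average roughly halves
that, and the triangulated area is orientation-insensitive to < 0.1 % —
the expected ordering.

## Grid coloring and projection

Cavity policies `keep-cavities` / `fill-below` / `fill-all` are applied to
the status grid before export.  Boundary points are cube centers whose six
face centers carry mixed media.  Projection onto the surface uses closed
forms for spheres, tori (circle projection) and triangles (barycentric
clamp) and a damped tangential foot-point iteration for quadrics; if the
closed-form foot violates the patch clip, a parametric sample of the valid
region is refined by shrinking coordinate search, which reaches the same
feet as enumerating the trim-boundary curves explicitly.  An
auxiliary 3-D cell grid (default cell `2h`) is searched in expanding
Chebyshev shells, stopping only when the remaining rings provably cannot
hold a nearer patch — the accelerated nearest point equals the brute-force
one exactly.

## Fixtures: what they do and do not emulate

The generators produce analytic shapes with self-computed ground truth:
sphere and sphere pairs (SES truth by 10⁵-node surface-of-revolution
quadrature), collinear chains (degenerate lifted hulls, rescued by the
perturbation machinery), the C60 cage (60 co-spherical atoms at cage
radius 3.55 Å, carbon radius 1.9 Å — the co-sphericity stress test; the
interior void for a 1.4 Å probe is the ball of radius 1.65 Å), watertight
Fibonacci-lattice shells (void volume by seeded Monte-Carlo membership;
watertightness pre-checked by neighbour spacing and radial pinhole
probes), random clusters, and torus/box meshes.  Torus mesh radii default
to 1.85/0.55 Å: deliberately incommensurate with the usual grid spacings,
because a mesh whose extremal vertex rings coincide with lattice planes
creates measure-zero tangent-ray degeneracies that imported geometry
(unlike atoms) cannot be perturbation-cured of.

What passing these fixtures shows: watertight classification, exact-parity
robustness under slivers and co-sphericity, correct topology and cavity
bookkeeping, and quantitative agreement with closed-form truths at the
stated resolutions.  What it does not show: behaviour on real proteins
(radius heterogeneity, tens of thousands of atoms, deep tunnel topology),
performance at production scales, or charge/dielectric physics, which are
all outside this package's scope.

## Known limitations

* Double precision with symbolic-perturbation retries replaces exact
  arithmetic; configurations degenerate beyond the 10⁻⁴ Å jitter raise
  after the configured retries instead of being resolved exactly.
* The SES strata predicate is exact up to the 10⁻⁷ Å clash tolerance;
  features thinner than that may classify either way (and are then caught,
  if at all, by the parity protocol).
* Ray casting is single-threaded by design here; the per-ray independence
  that permits parallel scheduling is untouched.
* The Gaussian surface inherits the trilinear crossing bias above;
  measuring it against analytic truth requires scales ≳ 8 for sub-percent
  area accuracy.
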