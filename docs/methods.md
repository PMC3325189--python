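# Methods

## The question the package answers

Branching biological structures — neuronal dendrites and axons, the
skeletons of branching corals such as *Madracis*, arteries, bronchi — are
spatial trees. A striking, convergent property of their bifurcations is
flatness: the apex of a typical bifurcation lies (nearly) on the plane
through the three points it connects to. `planarbif` measures this property,
compares it to what pure chance would produce, and tests whether a given
tree could still have its wiring cost reduced by flattening a bifurcation.

## Geometry

A reconstruction is a rooted tree embedded in R³. After reducing the
sampled polylines to their topological skeleton (root, branch points,
terminal tips; degree-2 samples collapsed into chains), each degree-3
internal node yields a **bifurcation**: apex `A` plus parent point `P` and
daughter points `D1`, `D2`. Nodes with more than two children
(multifurcations) are counted and skipped, never decomposed.

**Cone angle.** Normalise the three branch vectors to unit length, so their
tips lie on the unit sphere centred at the apex. The circle through the
three tips has circumradius `rho = abc / (4K)` (side lengths `a, b, c`,
triangle area `K`), and the aperture of the right circular cone through all
three directions is `theta = 2 * arcsin(rho)`. A flat bifurcation has
`theta = 180°`. Two numerical guards: the `arcsin` argument is clamped to
[0, 1] (near-flat triples can exceed 1 by float error), and triples with
`K < 1e-12` after normalisation are flagged degenerate and excluded from
statistics. An equivalent construction — the axis onto which the three unit
directions project equally, with `theta = 2 * arccos` of the common
projection — is kept in the test suite as an independent oracle; the two
agree to 1e-9 degrees over 10⁴ random bifurcations.

Note a float64 limitation: near `rho = 1` the derivative of `arcsin`
diverges, so machine-epsilon error in `rho` becomes ~1e-6–1e-4 degrees of
cone angle. Exactly-planar constructions are therefore asserted through the
apex-to-plane distance (machine-exact) rather than through a 1e-9-degree
cone-angle tolerance.

**Endpoint modes.** Neighbour points are either the adjacent reduced nodes
(`reduced_node`, the default: branch points or terminals) or the original
sample points nearest the apex along each incident chain (`first_segment`),
which is insensitive to branch curvature between branch points. A single
adjacent sample is used, not an average.

**Bifurcation plane and fold angles.** The bifurcation plane passes through
`P`, `D1`, `D2` only — the apex is excluded, since the apex lies on it iff
the bifurcation is planar. (The cone angle uses apex + 3 neighbours; the
plane uses the 3 neighbours; the two definitions are never conflated.) Two
bifurcations are *consecutive* when a daughter point of one is the apex of
the other. The angle between consecutive plane normals is folded into
[0°, 90°] via `arccos(|n1·n2|)` because normal signs are arbitrary.

## The random-bifurcation null

With the apex at the centre of a unit sphere and the three directions
i.i.d. uniform on its surface, the cone angle has density

    p(theta) = (3/4) sin³(theta/2),      theta in [0, pi],

CDF `1 − (3/2)cos(theta/2) + (1/2)cos³(theta/2)`. Sketch: for a fixed cone
axis the base-circle plane offset `h = cos(theta/2)` has density
proportional to `1 − h²` (the three points must sit on the circle, whose
circumference grows like `sin(theta/2)`, and integration over axes leaves
the plane-offset density); the change of variables to `theta` gives the
sine-cubed law. The density increases monotonically to a maximum at 180°:
even random bifurcations lean flat. The tail above 160° is
`(3/2)cos 80° − (1/2)cos³ 80° ≈ 0.2579` (26%), which is the yardstick for
biological planarity fractions (57–88% in published reconstructions).

The law is certified, not assumed: a seeded Monte-Carlo sampler (uniform
directions via normalised Gaussians) at n = 10⁵ passes a one-sample
Kolmogorov–Smirnov test against the closed form at alpha = 0.01, and the
n = 10⁶ tail lands within half a percentage point of 26%.

A variant samples 4 free i.i.d. points (Gaussian or uniform-ball) and
treats the first as apex. Because the shared apex correlates the three
directions, this law is *not* the sine-cubed law — its 160° tail is ~0.10
for Gaussian clouds. The sampler is provided for exploratory comparison
only, and no test asserts equality of the two laws.

## Wiring cost and the planarity audit

Wiring cost is `sum over edges e_ij of f_ij(d(x_i, x_j))` with each `f`
continuous, strictly increasing and symmetric in its indices. The registry
ships identity, `power:k` and `affine:a,b` models; strict monotonicity and
continuity are property-tested.

If an apex is off its bifurcation plane, its orthogonal projection onto the
plane shortens all three incident edges simultaneously — each original edge
is the hypotenuse of a right triangle whose leg is the projected edge — so
the total cost strictly decreases under *every* strictly increasing cost
model. `flatten_bifurcation` performs the projection and reports per-edge
deltas; `audit_planarity` applies it tree-wide and returns "not optimal"
iff some *deformable* bifurcation (one whose projected apex lies in the
apex's allowed region; all of space when no region oracle is supplied) is
off-plane beyond tolerance. Planarity tolerance is scale-aware: cone angle
within 1e-6° of 180° **or** apex-to-plane distance below 1e-9 × mean edge
length, so micrometre- and centimetre-scale reconstructions are treated
alike.

The audit and the flatten operator act on degree-3 vertices of the original
graph with their direct neighbours, because the cost is a sum over actual
graph edges and moving an apex only changes its three incident segments;
the descriptive statistics use reduced-tree endpoints. On synthetic trees
(one segment per branch) the two coincide.

`iterate_flatten` sweeps the projection over all apexes root-to-leaves;
the cost sequence is non-increasing. This is a local improvement pass with
no convergence-to-global claim — constructing optimal Steiner topologies is
NP-hard and out of scope.

**Fermat benchmark.** `fermat_point` minimises the summed distance from a
free junction to three terminals by Weiszfeld fixed-point iteration
(stopping at step < 1e-10 by default), with the vertex-capture case (some
terminal angle ≥ 120°, detected via `|u1 + u2| ≤ 1`) resolved analytically
first. Interior junctions reproduce the classical 120° angles to 1e-6; the
observation that real trees are planar but *not* 120°-angled is exactly
what separates general wiring-cost optimality from the Euclidean Steiner
special case.

## Synthetic data

`generate_planar_tree` grows a full binary tree (depth = number of
bifurcation levels, so `2^depth − 1` bifurcations and `2^depth − 2`
consecutive plane pairs). At each apex the two daughter directions lie in
the bifurcation plane on either side of the incoming direction, so apex,
parent point and daughters are coplanar by construction. Each child plane
contains the shared branch direction and is rotated about it by an azimuth:
independent uniform on [0°, 360°) by default, or fixed. Because parent and
child planes share a line, a uniform azimuth induces an exactly uniform
fold angle on [0°, 90°] after folding — the property the analysis looks
for in bias-free environments — while a fixed azimuth produces a point
mass, the detectable alternative.

Defaults (chosen once, as fixtures rather than estimates of any organism):
daughter deviation angles uniform on [20°, 70°], which spreads pairwise
branch angles broadly over roughly (40°, 160°) so that planarity
(universal) is distinguishable from Steiner 120° angles (not observed);
branch lengths log-normal with median 1 and sigma_log 0.3 (positive,
right-skewed like neurite segment lengths). `perturb_off_plane` displaces
each apex along its (unperturbed) plane normal by N(0, sigma), creating
the non-planar regime the audit must flag; sigma = 0 is the identity.

What the generator does **not** emulate: branch tapering and radii, tissue
boundaries, tortuous (curved) branches, correlated daughter angles,
multifurcations, reconstruction noise in terminal positions. Passing tests
therefore demonstrate correctness of the measurement and audit machinery,
not biological realism of any particular angle distribution.

## Statistics

Window fractions use closed windows: planarity = fraction of cone angles in
[160°, 180°], Steiner fraction = branch angles in [110°, 130°]. One-sample
KS tests compare cone angles to the analytic null and fold angles to
U(0°, 90°). Histogram divergence is Jensen–Shannon with base-2 logarithms
(range [0, 1] bits); the log base is recorded in report metadata. The
z-plane grouping splits bifurcations by the folded angle between their
plane normal and the z-axis (default split 45°, symmetric and
assumption-light) and reports per-group cone-angle histograms, between-group
JS and two-sample KS, and each group's JS against the null — a screen for
slice-compression artifacts, which inflate planarity anisotropically.
p-values are reported raw, with no multiple-testing correction. Bifurcations
are pooled across trees of a group; per-tree breakdowns are always emitted
alongside. Default histogram bin width is 10°.

## Problem sizes and determinism

All generators and samplers take explicit seeds and are reproducible;
distinct seeds give distinct draws. The standard verification sizes are
10⁶ Monte-Carlo bifurcations for the tail check, 10⁵ for the KS
certification, 10⁴ random bifurcations for the projection-improvement and
oracle-equivalence properties, 100 seeded replicates (~250 plane pairs
each) for the uniform-fold recovery, and 20 seeds × 3 noise levels for the
end-to-end monotonicity check; together they run in well under a minute on
one core.

## Known limitations

- The audit tests a *necessary* condition for optimality; a tree can pass
  (all deformable bifurcations planar) and still be far from optimal in
  topology or in-plane geometry.
- Cone angles near 180° carry ~1e-4-degree float noise (arcsin
  amplification); comparisons at tighter tolerance must use apex-to-plane
  distances.
- The edge-list reader is a generic carrier for non-SWC skeletons; it
  assumes one connected rooted tree per file.
- Only the edge-sum form of the wiring cost is implemented; path-based
  costs (linear combinations of root-to-terminal path costs) are noted in
  the literature as reducible to the same planarity argument but are not
  exposed here.
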