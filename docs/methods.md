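# Methods

## Model

Sample sites live in a planar map space with x = longitude and
y = latitude (equirectangular). A *linear geographic axis* is a line at
compass bearing θ (0° = due north, 90° = due east); it orders sites by
their scalar projection p_i = x_i sin θ + y_i cos θ. An axis and its
reverse induce the same biological ordering — gradients are undirected
— so bearings are taken mod 180° and every angular quantity has period
180°. No great-circle geometry is used anywhere: gradients are
line-of-sight structures in the projected map plane, and planar
coordinates keep the sweep algebra exact.

A georeferenced tree is rooted and may be multifurcating; each leaf
resolves to a site (several leaves may share one site — many sequences
per location is the common case). Drawing the leaves and the ordered
sites on two parallel lines and connecting each leaf to its site, the
*crossing number* of a layout equals the number of strict inversions
between the leaf-order-induced sequence of site positions and the site
order. Pairs of leaves on the same site never cross (their connectors
share an endpoint) and contribute zero.

## Optimal layout

The tree topology constrains attainable leaf orders: the children of
each internal node may be permuted independently, nothing else.
Crossings decompose exactly over internal nodes: for a node with
children subtrees 1..d, the number of crossings contributed by leaf
pairs whose lowest common ancestor is that node depends only on the
chosen child permutation, through the cost matrix

    C(i, j) = #{ (a in subtree i, b in subtree j) : pos(a) > pos(b) }.

Minimizing Σ_{i before j} C(i, j) over permutations is a linear
ordering problem, solved exactly per node:

* d ≤ 15: subset dynamic programming over the 2^d prefix sets,
  O(2^d · d) states/transitions, reconstructed forward so the
  lexicographically smallest optimal permutation is returned.
* d > 15: depth-first branch-and-bound in lexicographic order with
  lower bound Σ_{i<j unplaced} min(C(i,j), C(j,i)) and an incumbent
  seeded by a net-outflow greedy order refined by insertion local
  search. The incumbent only tightens pruning; the search still visits
  and records the lexicographically smallest optimum (prefixes are
  pruned only when the bound strictly exceeds the incumbent, so an
  optimal prefix is never discarded).

The global minimum crossing number is the sum of per-node minima;
`optimal_layout` also reports the realized leaf order and per-node
child permutations, and the test suite verifies the decomposition by
recounting inversions of the realized order. A brute-force enumerator
over all child-permutation combinations (refusing instances beyond
10^6 layouts) serves as the independent oracle. Inversion counting uses
a Fenwick tree, O(n log m); a quadratic pairwise counter is kept as a
reference implementation for tests.

All tie-breaking is deterministic (lexicographic), so results are
byte-for-byte reproducible.

## Linear axes analysis (the sweep)

The site ordering changes only at *critical angles*, where the segment
joining some site pair is perpendicular to the axis: for the pair
(i, j) this is θ = atan2(−Δy, Δx) mod 180°. The sweep therefore:

1. computes one event per distinct critical angle (pairs of coincident
   sites generate none; parallel segments and collinear triples merge
   into one event; angles closer than 1e-9° are merged to absorb
   floating-point slope collisions, with wrap-around merging at
   180° → 0°);
2. partitions [0°, 180°) into half-open intervals [e_k, e_{k+1})
   bounded by the events (plus the interval starting at 0° when 0° is
   not itself an event);
3. on each interval, computes the site ordering and the optimal layout
   once — the ordering is constant within the interval.

Every attainable ordering is evaluated, so the profile is exact for
*every* axis angle, not sampled. The layout is recomputed fully per
interval; with O(N²) intervals and a fast layout core this costs a few
seconds even for 50 sites × 200 leaves, so incremental crossing updates
across events were deliberately left out in favor of simplicity and
exactness.

### Degenerate configurations

Ties are handled symbolically, never by numeric nudging. At an angle
where two sites project equally, the ordering used is the one holding
*just after* an infinitesimal clockwise rotation; since
d p_i / dθ = x_i cos θ − y_i sin θ, the projection derivative is the
secondary sort key. Sites tied in both value and derivative are
coincident; they form permanent tie groups, ordered internally by site
id, and leaves attached to them never cross each other. Because
intervals are half-open [e_k, e_{k+1}) and a direct evaluation at any
angle applies the same just-after rule, a direct evaluation at an event
angle agrees exactly with the interval that starts there — the property
the dense-grid oracle tests exercise.

Numerically, "exactly equal projection" means a gap below
max(1, |coords|) · 1e-9 between adjacent sorted projections. Genuinely
distinct projections at evaluation angles sit many orders of magnitude
above this; projections that tie mathematically land within ~1e-16 of
each other. The synthetic null datasets place coordinates on a dyadic
grid (multiples of 2^-20) so that injected collinearity and parallelism
are exact in binary floating point rather than approximate.

## Permutation test

Under the null hypothesis of no geographic structuring, the
leaf-to-site assignment is exchangeable. Each permutation uniformly
shuffles the assignment (tree shape fixed), the optimal layout is
recomputed, and

    p = #{ c_perm ≤ c_obs } / m

with ties counted in the numerator and no continuity correction, so
p = 0 is attainable. A `conservative` flag switches to (b+1)/(m+1),
which is arithmetically identical to counting the unpermuted tree as
one more draw from its own null. Seeds are mandatory in the CLI and
default to 42 in the library; a fixed seed fixes the null distribution
byte-for-byte (NumPy PCG64 generators throughout).

The critical-value line for a sweep profile (the largest crossing count
c with #{null < c}/m ≤ α) is computed from a single null distribution
at a reference bearing of 90°. Justification: when all sites are
distinct, any fixed site ordering is a relabeling of any other, so the
null distribution of optimal crossings under uniform relabeling does
not depend on which ordering is used — one null serves every interval.
Co-located sites break this argument; when tie groups exist a warning
is emitted.

### Calibration conditions

The calibration experiment (p-value uniformity by Kolmogorov–Smirnov at
the 1% level; type-I error at α = 0.05 within [0.03, 0.07]) uses 500
replicates × 200 permutations on null datasets of 15 sites and 20
leaves with random binary topology. The instance size matters for a
principled reason: the crossing number is discrete, and the plain
proportion p-value is uniform only up to the probability mass at the
observed value. Tiny instances (≈10 leaves) concentrate the null on a
handful of values and make the p-value visibly conservative in lumps;
at 20 leaves over 15 sites the null spans enough distinct values that
the discretization bias is far below the KS detection threshold. The
suite's calibration instances reflect a realistically sized small
survey, not a limiting case.

## Supporting statistics

* **Regression** — ordinary least squares via `scipy.stats.linregress`;
  two-sided p from the slope's t statistic with n−2 df; requires n ≥ 3
  and non-constant x.
* **Mantel** — Pearson correlation of upper-triangle entries;
  significance by simultaneous row/column permutation of the second
  matrix; one-sided ("greater") by default, two-sided compares |r|.
  The same plain-proportion p-value convention (and `conservative`
  flag) as the permutation test. Constant matrices are rejected.
* **Bray–Curtis** — BC(u,v) = 1 − 2 Σ_k min(u_k, v_k) / (Σu + Σv) via
  `scipy.spatial.distance.pdist`; all-zero rows are rejected.
* **UPGMA** — size-weighted average-linkage agglomeration implemented
  in-package so that tie-breaking is deterministic: among equal merge
  distances the lexicographically smallest pair of cluster labels (a
  cluster is labelled by its smallest member) merges first. Node
  heights are half the merge distance; branch lengths are height
  differences, so cophenetic distances reproduce ultrametric inputs
  exactly. Cross-checked against SciPy average linkage in tests.
* **Alpha diversity** — with p_i = n_i / N over taxa with n_i > 0:
  richness S, Shannon H = −Σ p_i ln p_i (natural log by default; a
  log-base option is provided, and Pielou's J = H / ln S is
  base-invariant), Berger–Parker dominance d = max_i p_i (reported as
  dominance, not its reciprocal). Zero-abundance taxa are dropped
  before computation; J is undefined (missing) for S = 1.
* **O/E scores** — the expected values E are consumed from a
  user-supplied table (e.g. the output of a RIVPACS-style reference
  model); fitting such a model is out of scope. Both the raw ratio O/E
  and the capped ratio min(O/E, 1) are always reported (capping is the
  display convention for impairment screening, where only O/E < 1 is
  diagnostic), together with a `below_threshold` flag at a user-set
  threshold (default 1.0). Nonpositive or missing expected values are
  errors; indices undefined for a sample (Pielou at S = 1) are skipped
  rather than invented.

## Synthetic data

`make_planted_gradient` places site k at unit arc position k along the
planted bearing, adds N(0, scatter) jitter strictly perpendicular to
the axis (so the ordering along the planted axis is preserved by
construction while other bearings degrade), rescales coordinates to
stay inside valid latitude/longitude ranges, and builds a caterpillar
tree whose leaf order matches the site order. A caterpillar's
consistent leaf orders are unique up to mirror image, making the
planted signal unambiguous; the `mirrored` variant reverses the leaf
order, whose as-given layout at the planted angle shows the maximal
C(n,2) crossings. `make_null_dataset` draws dyadic-grid coordinates in
the unit square, a random topology (binary, star, or multifurcating
with degrees 2–4), and a uniform leaf-to-site assignment, with optional
exact degeneracy injection (coincident sites, shared longitudes,
collinear triples).

What the generators do **not** emulate: realistic coalescent or
birth–death tree shapes, spatial autocorrelation of abundances,
distance decay, or sampling noise in coordinates. Passing tests
therefore demonstrate algorithmic exactness and statistical calibration
under the stated null and planted models — not robustness to every
property of field data.

## Problem sizes and limitations

The default suite uses instances of up to 8 leaves for
oracle-equivalence checks (where exhaustive enumeration is feasible),
100 random sweeps with injected degeneracies against a 1° dense grid,
and one 50-site × 200-leaf multifurcating sweep (1225 events) as a
scale check; the whole suite and the acceptance script each run in a
few minutes on one CPU. Known limitations:

* The per-node solve is exponential in node degree in the worst case;
  degrees beyond ~25 with adversarial cost structure may be slow
  (exactness is never sacrificed — there is no heuristic fallback).
* The critical-value invariance argument fails under co-located sites
  (warned at run time).
* p = 0 from the proportion rule should be read as "< 1/m", and the
  `conservative` flag is recommended when p-values feed multiple-testing
  corrections.
* Coordinates are treated as planar; near the poles or across the
  antimeridian the projection geometry distorts and axis bearings lose
  their cartographic meaning.
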