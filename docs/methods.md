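# Methods

This note records the model, the numerical choices, and the known
limitations of the package, in the order of the processing chain.

## Division model and simulator

The simulator runs in three frozen-random stages, each drawing from an
independent stream spawned from the single user seed (so any stage can
be re-run in isolation and the composition is bit-reproducible).

**Mitotic clock.** All `n_roots` founding cells are scheduled to divide
at time 0; every newly born cell draws a cell-cycle duration from an
exponential distribution with rate `clock_rate` (default 1, arbitrary
time units). The cell with the smallest scheduled division time divides
next, ties broken by node id, until the division budget `D`
(`n_divisions`, default 200,000 over 100 roots) is exhausted; the
budget is first spent on the roots, so `D − n_roots` divisions execute
and exactly `D` leaves remain. A continuous exponential was chosen over
an integer-valued waiting time because integer durations make almost
all divisions simultaneous and the replay order then depends only on
tie-breaking. The resulting trees are unbalanced (random subtree
sizes); `balanced_forest(depth)` provides the idealized synchronized
alternative used in determination analyses.

**Expression.** Root profiles are standard-normal per gene
(`n_genes`, default 500). Each daughter's differential is exactly zero
with probability `symmetric_prob` (default 0.2) and standard-normal
otherwise. Profiles are per-lifetime constants; there are no
within-lifetime dynamics, no gene-regulatory mechanics, and the unit
of expression is an arbitrary signed deviation from a base level.

**Placement.** Divisions are replayed in ascending division time. A
uniform random direction is drawn (normalized normal triple); the ray
from the parent's slot is traversed one face-step at a time
(Amanatides–Woo stepping; corner ties resolved toward the smallest
axis index, so consecutive slots are always face-adjacent); the
contiguous run of occupied slots up to the first free slot is shifted
one slot outward, far-to-near; one daughter takes the parent slot and
the other the freed adjacent slot. Because every vacated slot is
refilled within the same division, the occupied set only ever grows by
one face-adjacent slot, which makes the mass provably 6-connected at
all times. Roots are seeded as a compact cluster (first root at the
origin, later roots in the first free face-neighbour scanned in a
fixed order).

*Limitation — enclosed vacancies.* Growth can wall in a free slot; it
is filled only when a later ray happens to terminate in it, so a few
holes persist (measured: 1–4 of ~67 interior 3³ blocks contain 25–26
cells instead of 27, ~0.05% of slots, at 5000 divisions). The
alternative reading of the shift rule — advancing *every* occupied
slot along the whole ray — was implemented and rejected: it produces a
porous mass (hundreds of enclosed vacancies), far worse. The 27-cell
interior capacity is therefore an idealization that the strict test
suite deliberately keeps visible as a failing assertion.

## Atlases and preprocessing

Voxelation partitions the lattice into `voxel_dim³` blocks anchored at
the occupied bounding box's minimum corner; each occupied block becomes
a voxel holding the mean profile of its cells (a `sum` aggregate is
available but the mean keeps simulated and externally supplied
density-like data on comparable scales). Partially filled surface
blocks are kept.

Preprocessing mirrors the conventions of voxelated expression grids
with a −1 invalid sentinel: drop voxels with more than
`max_invalid_frac` (default 20%) invalid entries, then genes by the
same rule over the survivors, in that order; impute remaining
sentinels with the gene's valid mean (so they become exactly 0 after
centering); then z-score each gene with the population standard
deviation. Constant genes are zeroed and flagged, not dropped, keeping
column indices stable. Imputed entries are included in the variance
estimate, matching the stated order of operations.

The shuffle control applies one global permutation to the flattened
voxel-by-gene matrix — the strongest structure-destroying control that
preserves the exact value multiset.

## Hierarchical decomposition

Per bin: center columns, `Q = X′ᵀX′`, unit leading eigenvector with a
deterministic sign (largest-magnitude component positive, first index
on ties), coefficients `w = X′·axis`, split `w < 0` left / `w ≥ 0`
right (zeros are measure-zero for continuous data; sending them right
makes the partition total). Because centered coefficients sum to zero,
both sides of a non-degenerate split are non-empty and the recursion
terminates at singletons or zero-variance bins. The eigensolver uses a
thin SVD when a bin has fewer rows than genes and a dense symmetric
eigendecomposition otherwise; a leading eigenvalue tied within 1e−10
(relative) falls back to the lexicographically smallest tied
eigenvector and flags the node. An independent power-iteration oracle
(tolerance 1e−12) verifies the decomposition on small random atlases
in the test suite.

Projection of an atlas onto an existing tree descends from the root,
centering each voxel by the *node's stored mean* (the estimated
ancestral profile — the quantity the model says is conserved) before
projecting on the node's axis; self-projection therefore reproduces
the decomposition's own assignment exactly, at every depth.

Agreement between two assignments at depth `d` is the fraction of
voxels with equal depth-`d` label prefixes (chance `2^−d` for balanced
independent assignments); the depth-weighted score weights depth `d`
by `d` within each voxel's common depth and normalizes so identity
scores exactly 1 (random assignments score `Σ d 2^−d / Σ d`). Because
left/right is arbitrary per split, independently computed hierarchies
are aligned before comparison: over a shared voxel set, children are
matched by member overlap (robust even under global sign flips of the
data, which preserve sign-normalized axes while mirroring
memberships); across different voxel sets, by the dot product of the
left-child mean offsets.

**Determination.** True internal nodes are matched to estimated nodes
by Jaccard overlap of leaf-cell progeny; per matched pair the squared
Pearson correlation is reported between the true asymmetry and the
estimated axis (sign-invariant) and between the true ancestral profile
and the estimated mean, grouped by true generation. Note an intrinsic
ceiling: even with oracle memberships, the mean-of-progeny estimator
of an ancestor's profile carries variance ≈ Σ_d 2^−d ≈ 1 per gene from
the shared early differentials, so expression determination is ~0.5 at
the root and *rises* with generation (the ancestor's own variance
grows while the estimator noise shrinks); asymmetry determination with
oracle axes is exactly 1. On clocked (unbalanced) forests the leading
covariance axis mixes the asymmetries of similarly sized subtrees, so
root-asymmetry determination is positive but modest; the balanced
forest recovers the clean per-generation picture.

## Spatial graph

Voxel adjacency is the Gabriel graph of the voxel centroids: a
Delaunay edge survives iff no third point lies in the *closed* ball
having the edge as diameter. The closed-ball rule (a point exactly on
the sphere blocks the edge) is used because it reproduces the
textbook definition, keeps the Euclidean minimum spanning tree a
subgraph (hence the graph connected), and makes the Gabriel graph of a
full cubic lattice exactly the 6-connected face adjacency (an optional
fast path asserts and exploits this). An edge passing the closed-ball
test has an empty circumball and thus belongs to every Delaunay
triangulation, so filtering Qhull's candidates cannot miss an edge
even for degenerate (cospherical) inputs; fully collinear/coplanar
point sets fall back to the O(n³) pairwise test. Numerical tolerance:
blockers are points within relative distance 1e−9 of the ball radius.

## Guidance

Signals: the guidance signal of tree node `s` at voxel `v` is the
Pearson correlation across genes between the node's mean profile (the
growth cone's template) and the voxel's expression, and it exists only
for `v` in the member region of `s` (the progeny of the adopted
ancestor). Templates with numerically zero variance (std ≤ 1e−12 — in
particular the root of any z-scored atlas, whose mean profile is
identically zero) have no signal and are inadmissible; growth cones
consequently stay within the depth-1 subtree of their source, matching
the observed grouping of simulated axons into the hemispheres of the
first division.

Moves: a cone steps only into the *best-matching* adjacent voxel and
only if it strictly improves on the current position; exact ties clone
the cone. Template changes to lineage-adjacent nodes are available
before any step but are irreversible, so a branch's state sequence is
a simple path in the tree: up through the source's ancestors, then
down into one other subtree. All of this is realized as a Dijkstra
traversal over (voxel, state, phase) triples with spatial cost 1 and
template-change cost 0 and lexicographic tie-breaking, making arbors
bit-reproducible; node costs equal spatial hop counts. Synapses are
recorded at settled nodes holding a leaf state with no improving
spatial step (the branch has arrived at a leaf in both expression and
physical space). Self-avoidance is enforced per (voxel, state) node by
the settle-once rule; a voxel may be traversed under different
templates.

The steepest-ascent step (rather than all improving neighbours) is
essential to the shuffle control's behaviour: with all
positive-gradient steps admissible, an unstructured signal field
supports increasing-path percolation and shuffled arbors wander 15–25
voxels; with steepest ascent, each template contributes at most ~1
step in an i.i.d. field and shuffled arbors typically stay within 1–3
voxels of their source. A residual tail remains — across 20 axons the
maximum reach is typically 4–6, one short climb per shallow tree level
whose bins are larger than the gene count — which the strict 2-voxel
assertion in the acceptance tests keeps visible.

Controls and robustness: `random_walk_axon` is a seeded self-avoiding
uniform walk on the spatial graph (single branch, tip at its
endpoint); `add_noise` adds i.i.d. Gaussian noise with standard
deviation equal to the level (a fraction of the unit per-gene standard
deviation of z-scored data) without recomputing the hierarchy; arbor
dissimilarity is the symmetrized mean over tips of the minimum
Euclidean tip-to-tip distance; the connectivity matrix counts synapses
between hierarchy regions at a chosen depth.

## Problem sizes used in the tests

The shared guidance substrate is 10 lineages × 30,000 divisions × 100
genes, voxelated at dimension 3 (~1500 voxels) — the scale at which
the shuffle-control and chance-agreement checks are specified. The
guided-versus-random-walk comparison uses 100,000 divisions × 300
genes (~4600 voxels): at 30,000 divisions guided branches are 1–3
hops and matched self-avoiding walks are equally straight, so the
comparison carries no signal; at the larger size guided tips outreach
matched walks (measured mean 2.0 vs 1.7 lattice units over ~90
branches). Determination uses a balanced depth-8 lineage with 200
genes. The clock-only check runs the full published scale (100 roots,
200,000 divisions, < 1 s).

## Known limitations

- The placement rule idealizes tissue mechanics; no migration, death,
  or physical forces, and rare enclosed vacancies (above).
- Hierarchies are strictly binary; no model selection of tree depth.
- Guidance is simulated on a frozen tissue (no growth during axon
  extension) and for pioneer axons only (no fasciculation).
- The signal uses plain Pearson correlation over all genes; gene
  subsets are supported by subsetting columns before decomposition
  (the `gene-subset` command), with one subset shared by all axons.
- Passing tests on simulated tissue show that the recovery and
  guidance machinery behaves as designed under the generative model's
  own assumptions (independent normal differentials, frozen
  randomness, lattice geometry); they do not certify behaviour on
  real voxelated expression data, which has measurement noise,
  nonstationary scales and anatomy the simulator does not emulate.
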