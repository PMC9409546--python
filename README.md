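# mitomap

Tools for studying how a mitotic lineage can wire a brain: simulate
clocked cell divisions that imprint a hierarchical gene-expression
address space onto a growing cell mass, recover that hierarchy from
voxelated expression by recursive covariance decomposition, and grow
branching axons whose growth cones navigate the recovered hierarchy by
correlation-gradient climbing.

The package is aimed at computational and systems neuroscientists who
want to experiment with lineage-induced spatial expression structure
and lineage-guided axon growth, either on fully synthetic tissue (the
bundled simulator) or on any voxel-by-gene expression grid supplied as
a tab-separated table (`x y z gene...`, one voxel per row, −1 marking
invalid measurements — the conventions of voxelated in-situ
hybridization atlases).

## The model

**Division model.** Each cell `i` lives once and carries an expression
profile `c_i` over `N` genes. At mitosis a parent `c` produces two
daughters with `c_l = c + δ_l` and `c_r = c + δ_r`, where each
differential `δ` is either exactly zero (a symmetric division,
probability 0.2 by default) or a standard-normal vector. The division
asymmetry `Δ = c_l − c_r = δ_l − δ_r` propagates into both progenies
and remains detectable in the leaf population. Cell-cycle durations are
exponential (rate `clock_rate`), and the cell with the earliest
scheduled division divides next until a budget of `D` divisions is
spent. Daughters are placed on an unbounded integer lattice by shifting
the contiguous run of occupied slots along a random ray one step
outward, so the mass grows one face-adjacent slot per division.

**Hierarchy recovery.** Voxelating the mass (mean expression of the
cells in each `d³` block) and z-scoring each gene gives a
voxel-by-gene matrix `X`. The decomposition centers the columns of a
bin's submatrix, forms `Q = X′ᵀX′`, takes the unit leading eigenvector
(the estimated division asymmetry of that bin's founding mitosis),
projects the rows onto it, and splits by coefficient sign; recursion
down to singleton bins yields an estimated lineage tree whose node
means `ĉ` estimate ancestral expression profiles.

**Guidance.** A growth cone at a voxel holds a tree node as its search
template; its signal at a voxel is the Pearson correlation between the
template's mean profile and the voxel's expression, defined only
inside the template's member region. The cone steps into the
best-matching adjacent voxel when that improves its current match
(cloning on exact ties), and may irreversibly re-tune to a
lineage-adjacent template, so each branch anti-differentiates up from
its source leaf and re-differentiates down another subtree. Branches
complete (synapse) where they hold a leaf template they cannot improve
on. The whole arbor is computed as a deterministic Dijkstra traversal
of the voxel-by-state product graph (spatial steps cost 1, template
changes 0).

Controls: a global permutation of all expression entries (destroys
spatial and covariance structure while preserving the value multiset)
and self-avoiding random-walk axons of matched length.

## Worked example

```python
import mitomap as m

params = m.SimParams(n_roots=4, n_divisions=2000, n_genes=40, seed=3)
forest, expr, asym, grid = m.simulate_tissue(params)

atlas = m.voxelate(grid, expr, 3)                 # 3x3x3-cell voxels
norm = m.normalize(m.filter_invalid(atlas)[0])    # per-gene z-scores
tree = m.decompose(norm)                          # estimated lineage tree
graph = m.gabriel_graph(atlas.coords.astype(float))
sg = m.build_state_graph(tree, norm, graph)
arbor = m.grow_axon(sg, 0)                        # axon from voxel 0

print(forest.leaves.size)        # 2000  (one leaf per division budget unit)
print(norm.n_voxels)             # 144   (occupied 3^3 blocks)
print(len(tree.nodes))           # 287   (binary tree over 144 voxels)
print(graph.n_edges)             # 329   (Gabriel adjacency, connected)
print(len(arbor.synapses))       # 6     (completed branches)
print(m.spread_profile(tree, atlas.coords.astype(float)).head(3))
#  depth  median     q1     q3  n_regions
#      0   1.000  1.000  1.000          1
#      1   0.902  0.899  0.906          2
#      2   0.849  0.832  0.855          4
```

The spread profile shows the decomposition's regions contracting in
physical space as depth increases — the signature of the lineage
hierarchy being simultaneously embedded in expression space and brain
space — even though voxel positions never enter the decomposition. The
`arbor` records every (voxel, state) position its growth cones
reached; `m.path_metrics(arbor)` tabulates per-branch path length
versus straight-line source-tip distance, and
`m.connectivity_matrix(arbors, tree, depth)` aggregates synapse counts
between hierarchy regions.

A command-line interface mirrors the library
(`mitomap simulate-tissue | preprocess | shuffle | decompose | project |
spread | agreement | gene-subset | build-graph | grow-axons |
random-walk | noise-sweep | connectivity | run`); `mitomap run
--config cfg --out-dir out` executes the whole pipeline and writes a
manifest with content hashes that are identical across reruns of the
same configuration.

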