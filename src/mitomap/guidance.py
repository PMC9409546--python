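"""Growth-cone guidance through the voxel-by-lineage-state product graph.

A growth cone occupies a (voxel, state) node: a spatial location plus a
receptor configuration corresponding to one node of the estimated
lineage tree. Its guidance signal at a voxel is the Pearson correlation
(across genes) between the state's mean profile — the estimated
ancestral expression the cone is searching for — and the voxel's
expression. A state's signal exists only within the progeny of the
adopted ancestor, i.e. the state's own member voxels, which confines
each template's search to its familial region.

Growth follows four rules, mirroring a cone that climbs its tuned
gradient and re-tunes only at decision points:

* A cone moves into the best-matching adjacent voxel when that
  improves on its current position (steepest ascent); exact ties clone
  the cone into all tied directions.
* Before any step a cone may instead change template to a
  lineage-adjacent state whose signal is defined at its position;
  branches explore every such option.
* Template changes are irreversible, so the state sequence of any
  branch is a simple path in the tree: up from the source leaf through
  its ancestors, then down into one other subtree (anti-differentiate,
  then re-differentiate).
* A branch completes when it holds a leaf state it cannot improve on;
  a synapse is recorded there.

The arbor is the set of (voxel, state) nodes reached by this process,
computed as a Dijkstra traversal with spatial steps costing 1 and
template changes 0, so a node's cost is its spatial hop distance along
the arbor. Deterministic tie-breaking makes arbors bit-reproducible.

The mean profile of the root bin of a z-scored atlas is identically
zero, so the root state has no defined signal and is inadmissible;
cones consequently remain within the depth-1 subtree (hemisphere) of
their source.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import ExpressionAtlas
from .hierarchy import HierarchyTree
from .spatial import SpatialGraph

__all__ = [
    "StateGraph",
    "Arbor",
    "build_state_graph",
    "signal",
    "grow_axon",
    "random_walk_axon",
    "add_noise",
    "path_metrics",
    "arbor_dissimilarity",
    "connectivity_matrix",
    "write_swc",
]

#: state id used for the stateless random-walk control
WALK_STATE = -1

#: traversal phases: ASCENDING while still on the source leaf's ancestor
#: chain (may anti-differentiate further), DESCENDING once the branch has
#: committed to another subtree (may only re-differentiate)
ASCENDING, DESCENDING = 0, 1

#: templates with standard deviation at or below this are numerically
#: zero (e.g. the exact-zero root mean of a z-scored atlas) and carry no
#: signal
TEMPLATE_TOL = 1e-12


def _row_zscores(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row z-scores across genes; rows with zero variance are flagged
    invalid (their signal is undefined)."""
    mean = X.mean(axis=1, keepdims=True)
    std = X.std(axis=1, keepdims=True)
    valid = std[:, 0] > 0
    Z = np.zeros_like(X)
    np.divide(X - mean, std, out=Z, where=std > 0)
    return Z, valid


class StateGraph:
    """Signal tables and admissible moves over (voxel, state) pairs.

    ``state_id`` indexes ``tree.nodes``. Per state the signal is stored
    for its admissible domain (the state's member voxels with
    non-constant expression); states with a zero-variance template (the
    root of any z-scored atlas, degenerate bins) have no signal at all.
    """

    def __init__(
        self, tree: HierarchyTree, atlas: ExpressionAtlas, sgraph: SpatialGraph
    ):
        if atlas.n_voxels != tree.n_voxels or atlas.n_voxels != sgraph.n_nodes:
            raise ValueError("tree, atlas and spatial graph cover different voxel sets")
        self.tree = tree
        self.atlas = atlas
        self.sgraph = sgraph

        Z, row_valid = _row_zscores(atlas.X)
        g = atlas.n_genes
        self.signals: dict = {}
        for node in tree.nodes:
            profile = node.mean
            pstd = profile.std()
            if pstd <= TEMPLATE_TOL:
                continue
            zp = (profile - profile.mean()) / pstd
            domain = node.members[row_valid[node.members]]
            vals = Z[domain] @ zp / g
            self.signals[node.node_id] = dict(
                zip((int(v) for v in domain), vals.tolist())
            )

        self.leaf_of_voxel = tree.leaf_of_voxel()

    def signal(self, state: int, voxel: int) -> float | None:
        """Signal value, or None where undefined/inadmissible."""
        table = self.signals.get(state)
        if table is None:
            return None
        return table.get(voxel)

    def has_node(self, voxel: int, state: int) -> bool:
        return self.signal(state, voxel) is not None

    def steepest_moves(self, voxel: int, state: int) -> list:
        """Voxels an improving steepest-ascent step may enter: the
        adjacent voxel(s) with the highest defined signal, admitted only
        if strictly better than the current voxel's; ties return all."""
        sig = self.signal(state, voxel)
        if sig is None:
            return []
        table = self.signals[state]
        best = None
        best_targets: list = []
        for u in self.sgraph.adjacency[voxel]:
            s_u = table.get(u)
            if s_u is None or s_u <= sig:
                continue
            if best is None or s_u > best:
                best, best_targets = s_u, [u]
            elif s_u == best:
                best_targets.append(u)
        return best_targets

    def template_transitions(
        self, voxel: int, state: int, forbidden_child: int | None = None
    ) -> tuple:
        """(parent_state_or_None, list_of_child_states) adoptable at the
        voxel: lineage-adjacent states whose signal is defined there,
        excluding ``forbidden_child`` (the state a branch on the
        ancestor chain ascended from)."""
        node = self.tree.nodes[state]
        parent = node.parent if node.parent >= 0 and self.has_node(
            voxel, node.parent
        ) else None
        children = [
            c
            for c in (node.left, node.right)
            if c >= 0 and c != forbidden_child and self.has_node(voxel, c)
        ]
        return parent, children


def build_state_graph(
    tree: HierarchyTree, atlas: ExpressionAtlas, sgraph: SpatialGraph
) -> StateGraph:
    """Construct the voxel-by-state signal/move structure."""
    return StateGraph(tree, atlas, sgraph)


def signal(
    tree: HierarchyTree, atlas: ExpressionAtlas, state: int, voxel: int
) -> float | None:
    """Guidance signal of one state at one voxel (None if undefined).

    Pearson correlation across genes between the state's mean profile
    and the voxel's expression; defined only for member voxels of the
    state (the progeny of the adopted ancestor).
    """
    node = tree.nodes[state]
    if int(voxel) not in set(int(v) for v in node.members):
        return None
    profile = node.mean
    x = atlas.X[voxel]
    if profile.std() <= TEMPLATE_TOL or x.std() == 0:
        return None
    return float(np.corrcoef(profile, x)[0, 1])


@dataclass
class Arbor:
    """Branching trajectory of one axon through (voxel, state) space."""

    source_voxel: int
    source_state: int
    #: settled (voxel, state) -> accumulated spatial-hop cost
    nodes: dict
    #: (voxel, state) -> parent (voxel, state); source maps to None
    parents: dict
    #: (voxel, state) nodes where synapses were recorded
    synapses: list
    coords: np.ndarray = field(repr=False, default=None)

    @property
    def voxels(self) -> set:
        return {v for v, _s in self.nodes}

    @property
    def tip_coords(self) -> np.ndarray:
        return self.coords[[v for v, _s in self.synapses]]

    @property
    def max_cost(self) -> float:
        return max(self.nodes.values())

    def branch_to(self, node) -> list:
        """Chain of (voxel, state) nodes from the source to ``node``."""
        chain = []
        while node is not None:
            chain.append(node)
            node = self.parents[node]
        return chain[::-1]


def grow_axon(sg: StateGraph, source_voxel: int) -> Arbor:
    """Grow one axon from a source voxel (see module docstring for the
    traversal rules).

    Internally a Dijkstra over (voxel, state, phase) triples: phase
    ASCENDING while the branch is still on the source leaf's ancestor
    chain, DESCENDING after it commits to another subtree. Spatial
    steps cost 1, template changes 0; ties break on
    (cost, voxel, state, phase), so arbors are bit-reproducible.
    Synapses are recorded at settled nodes holding a leaf state with no
    improving spatial step.
    """
    source_state = sg.leaf_of_voxel.get(source_voxel)
    if source_state is None:
        raise ValueError(f"voxel {source_voxel} not covered by the hierarchy")
    if not sg.has_node(source_voxel, source_state):
        raise ValueError(
            f"source ({source_voxel}, state {source_state}) has no defined signal"
        )

    tree = sg.tree
    # child on the source's ancestor chain, per ancestor: the state an
    # ascending branch came from, which it may not re-enter
    chain_child: dict = {}
    s = source_state
    while tree.nodes[s].parent >= 0:
        chain_child[tree.nodes[s].parent] = s
        s = tree.nodes[s].parent

    start = (source_voxel, source_state, ASCENDING)
    dist: dict = {}
    best = {start: 0.0}
    parents: dict = {start: None}
    heap = [(0.0,) + start]
    while heap:
        cost, v, s, ph = heapq.heappop(heap)
        node = (v, s, ph)
        if node in dist:
            continue
        dist[node] = cost

        succ = [((u, s, ph), 1.0) for u in sg.steepest_moves(v, s)]
        forbidden = chain_child.get(s) if ph == ASCENDING else None
        parent_state, children = sg.template_transitions(v, s, forbidden)
        succ += [((v, c, DESCENDING), 0.0) for c in children]
        if ph == ASCENDING and parent_state is not None:
            succ.append(((v, parent_state, ASCENDING), 0.0))
        for node2, w in succ:
            if node2 in dist:
                continue
            new = cost + w
            if new < best.get(node2, np.inf):
                best[node2] = new
                parents[node2] = node
                heapq.heappush(heap, (new,) + node2)

    # fold phases out: a (voxel, state) pair is reachable in exactly one
    # phase (descending subtrees are disjoint from the ancestor chain)
    nodes = {}
    par = {}
    synapses = []
    for (v, s, ph), c in dist.items():
        nodes[(v, s)] = c
        p = parents[(v, s, ph)]
        par[(v, s)] = None if p is None else (p[0], p[1])
        if tree.nodes[s].is_leaf and not sg.steepest_moves(v, s):
            synapses.append((v, s))
    synapses.sort()
    return Arbor(
        source_voxel=source_voxel,
        source_state=source_state,
        nodes=nodes,
        parents=par,
        synapses=synapses,
        coords=np.asarray(sg.sgraph.coords, dtype=np.float64),
    )


def random_walk_axon(
    sgraph: SpatialGraph, source: int, total_steps: int, seed: int
) -> Arbor:
    """Self-avoiding uniform random walk control on the spatial graph.

    No states and no branching: the walk takes ``total_steps`` uniform
    random steps to unvisited neighbours (fewer if trapped); its single
    tip is the final voxel.
    """
    if total_steps < 0:
        raise ValueError("total_steps must be >= 0")
    rng = np.random.default_rng(seed)
    visited = {source}
    chain = [source]
    current = source
    for _ in range(total_steps):
        options = [u for u in sgraph.adjacency[current] if u not in visited]
        if not options:
            break
        current = int(options[rng.integers(len(options))])
        visited.add(current)
        chain.append(current)
    nodes = {(v, WALK_STATE): float(i) for i, v in enumerate(chain)}
    parents = {
        (v, WALK_STATE): ((chain[i - 1], WALK_STATE) if i else None)
        for i, v in enumerate(chain)
    }
    return Arbor(
        source_voxel=source,
        source_state=WALK_STATE,
        nodes=nodes,
        parents=parents,
        synapses=[(chain[-1], WALK_STATE)],
        coords=np.asarray(sgraph.coords, dtype=np.float64),
    )


def add_noise(atlas: ExpressionAtlas, level: float, seed: int) -> ExpressionAtlas:
    """Add zero-mean Gaussian noise with standard deviation ``level``
    (a fraction of the unit per-gene standard deviation of z-scored
    data) to every entry. Callers testing guidance robustness
    deliberately do NOT recompute the hierarchy afterwards."""
    if level < 0:
        raise ValueError("noise level must be >= 0")
    rng = np.random.default_rng(seed)
    X = atlas.X + (rng.standard_normal(atlas.X.shape) * level if level > 0 else 0.0)
    return ExpressionAtlas(
        coords=atlas.coords,
        genes=list(atlas.genes),
        X=X,
        stage=atlas.stage,
        cell_members=atlas.cell_members,
        constant_genes=list(atlas.constant_genes),
    )


def path_metrics(arbor: Arbor) -> pd.DataFrame:
    """Per-branch path length and straight-line source-tip distance.

    The path length sums Euclidean inter-centroid segment lengths along
    the branch (template changes contribute zero length); the straight
    distance is Euclidean from source to tip. Path length >= straight
    distance for every branch by the triangle inequality.
    """
    if not arbor.nodes:
        raise ValueError("empty arbor")
    coords = arbor.coords
    src = coords[arbor.source_voxel]
    tips = arbor.synapses if arbor.synapses else [max(arbor.nodes, key=arbor.nodes.get)]
    rows = []
    for tip in tips:
        chain = arbor.branch_to(tip)
        length = 0.0
        for (v1, _), (v2, _) in zip(chain, chain[1:]):
            if v1 != v2:
                length += float(np.linalg.norm(coords[v2] - coords[v1]))
        straight = float(np.linalg.norm(coords[tip[0]] - src))
        rows.append(
            {"tip_voxel": tip[0], "path_length": length, "straight_distance": straight}
        )
    return pd.DataFrame(rows)


def arbor_dissimilarity(a: Arbor, b: Arbor) -> float:
    """Symmetrized mean over tips of the minimum Euclidean distance to
    the other arbor's tips."""
    ta, tb = a.tip_coords, b.tip_coords
    if ta.shape[0] == 0 or tb.shape[0] == 0:
        raise ValueError("both arbors must have at least one tip")
    d = np.linalg.norm(ta[:, None, :] - tb[None, :, :], axis=2)
    return 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())


def connectivity_matrix(
    arbors: list, tree: HierarchyTree, region_depth: int
) -> pd.DataFrame:
    """Synapse counts between hierarchy regions at ``region_depth``.

    Rows index the source voxel's region, columns the arrival region of
    each synapse; the matrix is square over all regions present at that
    depth and its total equals the total synapse count.
    """
    region_of = tree.assignment(max_depth=region_depth)
    labels = sorted(set(region_of.values()))
    index = {lab: i for i, lab in enumerate(labels)}
    M = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for arbor in arbors:
        try:
            src = region_of[arbor.source_voxel]
        except KeyError:
            raise ValueError(f"source voxel {arbor.source_voxel} has no region")
        for (v, _s) in arbor.synapses:
            if v not in region_of:
                raise ValueError(f"arrival voxel {v} has no region")
            M[index[src], index[region_of[v]]] += 1
    return pd.DataFrame(M, index=labels, columns=labels)


def write_swc(arbor: Arbor, path) -> None:
    """SWC morphology export: soma sample (type 1) at the source voxel
    centroid, axon samples (type 2) along the arbor, radius 0.5."""
    children: dict = {}
    root = None
    for node, parent in arbor.parents.items():
        if parent is None:
            root = node
        else:
            children.setdefault(parent, []).append(node)
    order = []
    stack = [root]
    while stack:
        node = stack.pop()
        order.append(node)
        for child in sorted(children.get(node, []), reverse=True):
            stack.append(child)
    sample_id = {node: i + 1 for i, node in enumerate(order)}
    coords = arbor.coords
    with open(path, "w") as fh:
        fh.write("# SWC export: soma = source voxel, type 2 = axon\n")
        for node in order:
            sid = sample_id[node]
            parent = arbor.parents[node]
            pid = -1 if parent is None else sample_id[parent]
            stype = 1 if parent is None else 2
            x, y, z = coords[node[0]]
            fh.write(f"{sid} {stype} {x:.3f} {y:.3f} {z:.3f} 0.5 {pid}\n")
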