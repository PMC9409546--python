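"""Simulation of mitotic lineages growing a cell mass on an integer lattice.

The model has three stages, run in sequence on one seeded random stream
per stage:

1. A mitotic clock builds the branched division history: every cell draws
   an exponential cell-cycle duration at birth, and the cell with the
   smallest scheduled division time divides next, until a fixed budget of
   divisions is spent.
2. Gene expression is inherited: a daughter's profile is its parent's
   profile plus a differential vector ``delta`` that is either exactly
   zero (a symmetric division) or a fresh standard-normal draw per gene.
3. Cells are placed on an unbounded 3D integer lattice: at each division
   a random direction is drawn, the contiguous run of occupied slots
   along that ray is shifted one slot outward to free the slot next to
   the parent, and the two daughters take the parent slot and the freed
   slot.

All randomness is derived from a single integer seed, so a given
parameter set reproduces bit-identical forests, expression tables and
grids.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimParams",
    "MitoticForest",
    "ExpressionTable",
    "TrueAsymmetryTable",
    "CellGrid",
    "balanced_forest",
    "run_mitotic_clock",
    "assign_expression",
    "place_cells",
    "simulate_tissue",
]

# Stage indices for deriving independent per-stage random streams from
# the single user-facing seed.
_STAGE_CLOCK, _STAGE_EXPR, _STAGE_PLACE = 0, 1, 2

# Fixed scan order for lattice face neighbours (+x, -x, +y, -y, +z, -z).
FACE_NEIGHBORS = (
    (1, 0, 0),
    (-1, 0, 0),
    (0, 1, 0),
    (0, -1, 0),
    (0, 0, 1),
    (0, 0, -1),
)


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Independent, reproducible generator for one simulation stage."""
    children = np.random.SeedSequence(seed).spawn(3)
    return np.random.default_rng(children[stage])


@dataclass(frozen=True)
class SimParams:
    """Parameters of one tissue simulation.

    Parameters
    ----------
    n_roots
        Number of independent lineage roots (the initial cell pool).
    n_divisions
        Total division budget ``D``; the budget is first spent on the
        roots themselves, so the executed division count is
        ``n_divisions - n_roots`` and the final leaf count equals
        ``n_divisions``.
    n_genes
        Genes per expression profile.
    symmetric_prob
        Probability that a daughter's differential vector is exactly
        zero (a symmetric division).
    clock_rate
        Rate of the exponential cell-cycle-duration distribution.
    seed
        Integer seed for all three simulation stages.
    """

    n_roots: int = 100
    n_divisions: int = 200_000
    n_genes: int = 500
    symmetric_prob: float = 0.2
    clock_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_roots < 1:
            raise ValueError("n_roots must be >= 1")
        if self.n_divisions < self.n_roots:
            raise ValueError(
                "n_divisions must be >= n_roots "
                "(the division budget is spent on the roots first)"
            )
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0.0 <= self.symmetric_prob <= 1.0:
            raise ValueError("symmetric_prob must lie in [0, 1]")
        if self.clock_rate <= 0:
            raise ValueError("clock_rate must be > 0")


@dataclass
class MitoticForest:
    """Branched division history of one simulation.

    Nodes are cell lifetimes, numbered in creation order: roots first
    (ids ``0..n_roots-1``), then daughters in pairs in execution order.
    ``parent`` is -1 for roots; ``left``/``right`` are -1 for leaves.
    ``division_time`` of a leaf is its scheduled (never executed)
    division time; daughters' ``birth_time`` equals their parent's
    ``division_time``.
    """

    n_roots: int
    parent: np.ndarray
    left: np.ndarray
    right: np.ndarray
    birth_time: np.ndarray
    division_time: np.ndarray
    root_id: np.ndarray
    #: internal node ids in the order their divisions were executed
    division_order: np.ndarray = field(repr=False, default=None)

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def leaves(self) -> np.ndarray:
        return np.flatnonzero(self.left < 0)

    @property
    def internal_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.left >= 0)

    def generations(self) -> np.ndarray:
        """Per-node generation (number of divisions since the root; root = 0)."""
        gen = np.zeros(self.n_nodes, dtype=np.int64)
        # creation order guarantees parents precede children
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                gen[i] = gen[p] + 1
        return gen

    def leaf_descendants(self, node: int) -> np.ndarray:
        """Leaf ids descending from ``node`` (the node itself if a leaf)."""
        out = []
        stack = [int(node)]
        while stack:
            i = stack.pop()
            if self.left[i] < 0:
                out.append(i)
            else:
                stack.append(int(self.left[i]))
                stack.append(int(self.right[i]))
        return np.array(sorted(out), dtype=np.int64)

    # ---------------------------------------------------------------- IO

    def to_edge_table(self):
        """Flat edge list: child, parent, birth_time, division_time."""
        import pandas as pd

        return pd.DataFrame(
            {
                "child": np.arange(self.n_nodes),
                "parent": self.parent,
                "birth_time": self.birth_time,
                "division_time": self.division_time,
            }
        )

    def to_newick(self) -> str:
        """Newick export (one tree per root, ';'-separated), with node ids
        as labels and branch lengths equal to lifetime durations."""
        parts = []
        for r in range(self.n_roots):
            parts.append(self._newick_node(r) + ";")
        return "\n".join(parts)

    def _newick_node(self, i: int) -> str:
        length = self.division_time[i] - self.birth_time[i]
        if self.left[i] < 0:
            return f"n{i}:{length:.6g}"
        l = self._newick_node(int(self.left[i]))
        r = self._newick_node(int(self.right[i]))
        return f"({l},{r})n{i}:{length:.6g}"

    def validate(self) -> None:
        internal = self.internal_nodes
        if not np.all((self.left[internal] >= 0) & (self.right[internal] >= 0)):
            raise AssertionError("internal node without two daughters")
        for i in internal:
            for d in (self.left[i], self.right[i]):
                if self.parent[d] != i:
                    raise AssertionError("parent/daughter mismatch")
                if self.birth_time[d] != self.division_time[i]:
                    raise AssertionError("daughter birth != parent division")


@dataclass
class ExpressionTable:
    """Per-node expression vectors and per-node differential vectors.

    ``X[i]`` is the expression profile of node ``i`` (signed deviations
    from a base level); ``delta[i]`` its differential relative to its
    parent (zero for roots, whose profile is the frozen root draw).
    """

    X: np.ndarray
    delta: np.ndarray

    def leaf_matrix(self, forest: MitoticForest) -> np.ndarray:
        return self.X[forest.leaves]


@dataclass
class TrueAsymmetryTable:
    """Ground-truth division asymmetries.

    ``node_ids[k]`` is an internal node and ``delta_sib[k]`` the
    difference between its two daughters' expression vectors
    (left minus right).
    """

    node_ids: np.ndarray
    delta_sib: np.ndarray

    def lookup(self, node: int) -> np.ndarray:
        idx = np.searchsorted(self.node_ids, node)
        if idx >= len(self.node_ids) or self.node_ids[idx] != node:
            raise KeyError(f"node {node} is not an internal node")
        return self.delta_sib[idx]


@dataclass
class CellGrid:
    """Bijective mapping between leaf cells and occupied lattice slots."""

    cell_at: dict
    slot_of: dict

    @property
    def n_cells(self) -> int:
        return len(self.slot_of)

    def cells_and_coords(self):
        """Leaf ids (sorted) and their integer coordinates, aligned."""
        cells = np.array(sorted(self.slot_of), dtype=np.int64)
        coords = np.array([self.slot_of[int(c)] for c in cells], dtype=np.int64)
        return cells, coords

    def to_table(self, root_id: np.ndarray | None = None):
        import pandas as pd

        cells, coords = self.cells_and_coords()
        data = {
            "cell_id": cells,
            "i": coords[:, 0],
            "j": coords[:, 1],
            "k": coords[:, 2],
        }
        if root_id is not None:
            data["root_id"] = root_id[cells]
        return pd.DataFrame(data)


# ------------------------------------------------------------------ stages


def balanced_forest(depth: int) -> MitoticForest:
    """Idealized fully balanced single-root division history.

    Every cell divides exactly once per unit time for ``depth``
    generations, leaving ``2**depth`` synchronized leaves. Useful for
    determination analyses where the clocked (unbalanced) forest's
    variable subtree sizes confound per-generation statistics.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    n_internal = 2**depth - 1
    n = 2 ** (depth + 1) - 1
    parent = np.full(n, -1, dtype=np.int64)
    left = np.full(n, -1, dtype=np.int64)
    right = np.full(n, -1, dtype=np.int64)
    for i in range(n_internal):
        left[i], right[i] = 2 * i + 1, 2 * i + 2
        parent[2 * i + 1] = parent[2 * i + 2] = i
    gen = np.zeros(n, dtype=np.int64)
    for i in range(1, n):
        gen[i] = gen[parent[i]] + 1
    return MitoticForest(
        n_roots=1,
        parent=parent,
        left=left,
        right=right,
        birth_time=gen.astype(float),
        division_time=gen.astype(float) + 1.0,
        root_id=np.zeros(n, dtype=np.int64),
        division_order=np.arange(n_internal),
    )


def run_mitotic_clock(params: SimParams) -> MitoticForest:
    """Build the division history by always dividing the cell with the
    minimum scheduled division time.

    Roots are scheduled at time 0; every newly born cell draws an
    exponential cycle duration at rate ``clock_rate``. Exactly
    ``n_divisions - n_roots`` divisions are executed, leaving
    ``n_divisions`` leaves. Ties in scheduled time are broken by node id.
    """
    rng = _stage_rng(params.seed, _STAGE_CLOCK)
    n_div = params.n_divisions - params.n_roots
    n_nodes = params.n_roots + 2 * n_div

    parent = np.full(n_nodes, -1, dtype=np.int64)
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    birth = np.zeros(n_nodes, dtype=np.float64)
    division = np.zeros(n_nodes, dtype=np.float64)
    root_id = np.zeros(n_nodes, dtype=np.int64)
    order = np.empty(n_div, dtype=np.int64)

    scale = 1.0 / params.clock_rate
    heap = [(0.0, r) for r in range(params.n_roots)]
    root_id[: params.n_roots] = np.arange(params.n_roots)
    heapq.heapify(heap)

    # cycle durations drawn in blocks: one stream, far fewer generator calls
    block = 1 << 16
    durations = rng.exponential(scale, size=min(2 * n_div, block))
    ptr = 0

    push = heapq.heappush
    nxt = params.n_roots
    for k in range(n_div):
        t, c = heapq.heappop(heap)
        order[k] = c
        rid = root_id[c]
        for child in (nxt, nxt + 1):
            if ptr == len(durations):
                durations = rng.exponential(scale, size=block)
                ptr = 0
            d = t + durations[ptr]
            ptr += 1
            parent[child] = c
            birth[child] = t
            division[child] = d
            root_id[child] = rid
            push(heap, (d, child))
        left[c], right[c] = nxt, nxt + 1
        nxt += 2

    return MitoticForest(
        n_roots=params.n_roots,
        parent=parent,
        left=left,
        right=right,
        birth_time=birth,
        division_time=division,
        root_id=root_id,
        division_order=order,
    )


def assign_expression(
    forest: MitoticForest, params: SimParams
) -> tuple[ExpressionTable, TrueAsymmetryTable]:
    """Assign inherited-plus-perturbed expression profiles to every node.

    Root profiles are standard-normal per gene. Each non-root node's
    differential is the zero vector with probability ``symmetric_prob``,
    otherwise a standard-normal vector; its profile is its parent's plus
    the differential. The whole table is a deterministic function of the
    seed (a frozen random stream).
    """
    rng = _stage_rng(params.seed, _STAGE_EXPR)
    n, g = forest.n_nodes, params.n_genes

    delta = np.zeros((n, g), dtype=np.float64)
    X = np.empty((n, g), dtype=np.float64)
    X[: forest.n_roots] = rng.standard_normal((forest.n_roots, g))

    nonroot = np.arange(forest.n_roots, n)
    symmetric = rng.random(nonroot.size) < params.symmetric_prob
    asym_ids = nonroot[~symmetric]
    delta[asym_ids] = rng.standard_normal((asym_ids.size, g))

    # creation order guarantees parents precede children
    for i in nonroot:
        X[i] = X[forest.parent[i]] + delta[i]

    internal = forest.internal_nodes
    sib = delta[forest.left[internal]] - delta[forest.right[internal]]
    return ExpressionTable(X=X, delta=delta), TrueAsymmetryTable(
        node_ids=internal, delta_sib=sib
    )


def _ray_voxels(origin: tuple, direction: np.ndarray):
    """Yield the lattice slots a ray visits, one face-step at a time.

    Amanatides & Woo traversal starting at (but not yielding) ``origin``;
    ties when the ray crosses a slot corner are broken toward the
    lexicographically smallest axis, so consecutive slots are always
    face-adjacent.
    """
    pos = list(origin)
    step = [0, 0, 0]
    t_max = [np.inf, np.inf, np.inf]
    t_delta = [np.inf, np.inf, np.inf]
    for a in range(3):
        d = direction[a]
        if d > 0:
            step[a] = 1
            t_max[a] = 0.5 / d
            t_delta[a] = 1.0 / d
        elif d < 0:
            step[a] = -1
            t_max[a] = -0.5 / d
            t_delta[a] = -1.0 / d
    while True:
        a = min(range(3), key=lambda i: (t_max[i], i))
        pos[a] += step[a]
        t_max[a] += t_delta[a]
        yield tuple(pos)


def place_cells(forest: MitoticForest, params: SimParams) -> CellGrid:
    """Place the leaf cells on the lattice by replaying divisions in time.

    Roots seed a compact contiguous cluster (first root at the origin,
    each later root in the first free face-neighbour slot of an earlier
    placement). Each division draws a uniform direction on the unit
    sphere; the contiguous run of occupied slots along the ray from the
    parent is shifted one slot outward (far-to-near), then one daughter
    takes the parent slot and the other the freed adjacent slot. Every
    vacated slot is refilled in the same division, so the occupied set
    grows by exactly one face-adjacent slot per division and the mass
    stays 6-connected.
    """
    rng = _stage_rng(params.seed, _STAGE_PLACE)

    cell_at: dict = {}
    slot_of: dict = {}

    def put(cell: int, slot: tuple) -> None:
        cell_at[slot] = cell
        slot_of[cell] = slot

    # --- seed roots in a contiguous cluster
    placed_order = []
    put(0, (0, 0, 0))
    placed_order.append((0, 0, 0))
    for r in range(1, forest.n_roots):
        target = None
        for slot in placed_order:
            for d in FACE_NEIGHBORS:
                cand = (slot[0] + d[0], slot[1] + d[1], slot[2] + d[2])
                if cand not in cell_at:
                    target = cand
                    break
            if target is not None:
                break
        put(r, target)
        placed_order.append(target)

    # --- replay divisions in ascending division-time order
    for c in forest.division_order:
        c = int(c)
        p = slot_of.pop(c)
        del cell_at[p]

        direction = rng.standard_normal(3)
        norm = np.linalg.norm(direction)
        while norm == 0.0:  # essentially impossible, but stay well-defined
            direction = rng.standard_normal(3)
            norm = np.linalg.norm(direction)
        direction /= norm

        run = []
        free_slot = None
        for slot in _ray_voxels(p, direction):
            if slot in cell_at:
                run.append(slot)
            else:
                free_slot = slot
                break
        # shift the run outward, far-to-near
        for src, dst in zip(reversed(run), reversed(run[1:] + [free_slot])):
            moved = cell_at.pop(src)
            put(moved, dst)
        adjacent = run[0] if run else free_slot

        put(int(forest.left[c]), adjacent)
        put(int(forest.right[c]), p)

    return CellGrid(cell_at=cell_at, slot_of=slot_of)


def simulate_tissue(
    params: SimParams,
) -> tuple[MitoticForest, ExpressionTable, TrueAsymmetryTable, CellGrid]:
    """Run all three stages; deterministic (bit-identical) given the seed."""
    forest = run_mitotic_clock(params)
    expr, asym = assign_expression(forest, params)
    grid = place_cells(forest, params)
    return forest, expr, asym, grid
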