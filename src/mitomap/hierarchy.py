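"""Recursive covariance decomposition of expression atlases.

The estimated lineage tree is recovered by recursive bisection: for the
voxels of a bin, center the expression columns, form the gene-by-gene
covariance ``Q = X'^T X'``, take the unit leading eigenvector (the bin's
estimated division asymmetry), project the centered rows onto it, and
split by coefficient sign (negative coefficients go left, the rest
right). Recursion stops at singleton bins or bins with zero variance.

Because the centered coefficients sum to zero and are not all zero for a
non-degenerate bin, both sides of every split are non-empty, so the
recursion always terminates.

The module also provides the downstream metrics on hierarchies:
projection of new atlases onto an existing tree, per-depth spatial
spread, bin agreement between assignments (plain and depth-weighted),
axis correlations, and determination of the reconstruction against
simulated ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import ExpressionAtlas

__all__ = [
    "HierarchyNode",
    "HierarchyTree",
    "ZeroVarianceError",
    "principal_axis",
    "decompose",
    "project",
    "spread_profile",
    "agreement_at_depth",
    "depth_weighted_agreement",
    "axis_correlation",
    "harmonized_relabel",
    "reconstruction_determination",
]

#: eigenvalue-multiplicity tolerance below which the leading axis is
#: considered degenerate (split proceeds on the lexicographically
#: smallest of the tied eigenvectors, and the node is flagged)
DEGENERATE_EIG_TOL = 1e-10


class ZeroVarianceError(ValueError):
    """All rows identical: the bin carries no signal to split on."""


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector sign: largest-magnitude component positive
    (first index on ties)."""
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def principal_axis(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leading axis of variance of the member-by-gene matrix ``X``.

    Columns are centered by their empirical means; the axis is the unit
    leading eigenvector of ``Q = X'^T X'`` with deterministic sign, and
    the coefficients are the centered rows projected onto the axis.

    Raises
    ------
    ZeroVarianceError
        If all rows are identical (the caller should treat the bin as a
        degenerate leaf).
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("principal_axis requires a 2D matrix with >= 2 rows")
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ZeroVarianceError("all rows identical; zero-variance bin")

    n, g = Xc.shape
    if n < g:
        # thin SVD is cheaper and equivalent: right singular vectors of X'
        # are the eigenvectors of Q
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        vals = s**2
        vecs = vt
        order = np.arange(len(vals))  # already descending
    else:
        Q = Xc.T @ Xc
        w, V = np.linalg.eigh(Q)
        order = np.argsort(w)[::-1]
        vals = w[order]
        vecs = V[:, order].T

    top = vecs[0]
    if len(vals) > 1 and abs(vals[0] - vals[1]) <= DEGENERATE_EIG_TOL * max(
        vals[0], 1.0
    ):
        # tie in the leading eigenvalue: pick the lexicographically
        # smallest of the (sign-fixed) tied eigenvectors for determinism
        tied = [
            _fix_sign(vecs[i])
            for i in range(len(vals))
            if abs(vals[0] - vals[i]) <= DEGENERATE_EIG_TOL * max(vals[0], 1.0)
        ]
        top = min(tied, key=lambda v: tuple(v))
    axis = _fix_sign(top / np.linalg.norm(top))
    w = Xc @ axis
    return axis, w


@dataclass
class HierarchyNode:
    node_id: int
    parent: int  # -1 for root
    depth: int
    path: str  # string over {L, R}; '' for root
    members: np.ndarray  # voxel row indices
    mean: np.ndarray  # mean profile over member voxels
    axis: np.ndarray | None = None  # None for leaves / degenerate bins
    left: int = -1
    right: int = -1
    degenerate: bool = False  # zero-variance non-singleton bin
    tied_axis: bool = False  # leading eigenvalue was degenerate

    @property
    def is_leaf(self) -> bool:
        return self.left < 0


@dataclass
class HierarchyTree:
    """Binary tree of nested voxel bins over one atlas."""

    nodes: list
    n_voxels: int
    n_genes: int
    genes: list = field(default_factory=list)

    @property
    def root(self) -> HierarchyNode:
        return self.nodes[0]

    def children(self, node_id: int) -> tuple[int, int]:
        n = self.nodes[node_id]
        return n.left, n.right

    def node_at_path(self, path: str) -> HierarchyNode:
        n = self.root
        for ch in path:
            nid = n.left if ch == "L" else n.right
            if nid < 0:
                raise KeyError(f"path {path!r} runs past a leaf")
            n = self.nodes[nid]
        return n

    def nodes_at_depth(self, depth: int) -> list:
        return [n for n in self.nodes if n.depth == depth]

    def max_depth(self) -> int:
        return max(n.depth for n in self.nodes)

    def leaf_of_voxel(self) -> dict:
        """Map voxel row index -> leaf node id."""
        out = {}
        for n in self.nodes:
            if n.is_leaf:
                for v in n.members:
                    out[int(v)] = n.node_id
        return out

    def assignment(self, max_depth: int | None = None) -> dict:
        """Per-voxel path label implied by the decomposition itself."""
        out = {}
        for n in self.nodes:
            if n.is_leaf:
                label = n.path if max_depth is None else n.path[:max_depth]
                for v in n.members:
                    out[int(v)] = label
        return out

    # ------------------------------------------------------------- IO

    def to_json(self, path) -> None:
        recs = [
            {
                "node_id": n.node_id,
                "parent": n.parent,
                "depth": n.depth,
                "path": n.path,
                "members": n.members.tolist(),
                "mean": n.mean.tolist(),
                "axis": None if n.axis is None else n.axis.tolist(),
                "left": n.left,
                "right": n.right,
                "degenerate": n.degenerate,
            }
            for n in self.nodes
        ]
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_voxels": self.n_voxels,
                    "n_genes": self.n_genes,
                    "genes": self.genes,
                    "nodes": recs,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "HierarchyTree":
        with open(path) as fh:
            d = json.load(fh)
        nodes = [
            HierarchyNode(
                node_id=r["node_id"],
                parent=r["parent"],
                depth=r["depth"],
                path=r["path"],
                members=np.array(r["members"], dtype=np.int64),
                mean=np.array(r["mean"], dtype=np.float64),
                axis=None if r["axis"] is None else np.array(r["axis"]),
                left=r["left"],
                right=r["right"],
                degenerate=r["degenerate"],
            )
            for r in d["nodes"]
        ]
        return cls(
            nodes=nodes,
            n_voxels=d["n_voxels"],
            n_genes=d["n_genes"],
            genes=d.get("genes", []),
        )

    def to_newick(self) -> str:
        """Topology export with path labels as node names."""

        def rec(nid: int) -> str:
            n = self.nodes[nid]
            name = n.path if n.path else "root"
            if n.is_leaf:
                return name
            return f"({rec(n.left)},{rec(n.right)}){name}"

        return rec(0) + ";"


def decompose(atlas: ExpressionAtlas, max_depth: int | None = None) -> HierarchyTree:
    """Recursively bisect the atlas voxels into an estimated lineage tree.

    Splits stop at singleton bins, zero-variance (degenerate) bins, or
    at ``max_depth`` if given.
    """
    if atlas.n_voxels < 1:
        raise ValueError("empty atlas")
    nodes: list[HierarchyNode] = []
    # stack of (parent_id, depth, path, member indices); explicit stack
    # keeps deep unbalanced trees out of the recursion limit
    all_members = np.arange(atlas.n_voxels, dtype=np.int64)
    stack = [(-1, 0, "", all_members)]
    while stack:
        parent_id, depth, path, members = stack.pop()
        nid = len(nodes)
        node = HierarchyNode(
            node_id=nid,
            parent=parent_id,
            depth=depth,
            path=path,
            members=members,
            mean=atlas.X[members].mean(axis=0),
        )
        nodes.append(node)
        if parent_id >= 0:
            p = nodes[parent_id]
            if path[-1] == "L":
                p.left = nid
            else:
                p.right = nid
        if members.size < 2 or (max_depth is not None and depth >= max_depth):
            continue
        try:
            axis, w = principal_axis(atlas.X[members])
        except ZeroVarianceError:
            node.degenerate = True
            continue
        node.axis = axis
        left = members[w < 0]
        right = members[w >= 0]
        # push right first so the left child is created first (preorder)
        stack.append((nid, depth + 1, path + "R", right))
        stack.append((nid, depth + 1, path + "L", left))
    return HierarchyTree(
        nodes=nodes,
        n_voxels=atlas.n_voxels,
        n_genes=atlas.n_genes,
        genes=list(atlas.genes),
    )


def project(
    tree: HierarchyTree, atlas: ExpressionAtlas, max_depth: int | None = None
) -> dict:
    """Assign every atlas voxel a path label by descending the tree.

    At each node the voxel's expression is centered by the node's stored
    mean profile (the estimated ancestor expression) and projected onto
    the node's axis; negative coefficients descend left, the rest right.
    Descent stops at a leaf or at ``max_depth``.
    """
    if list(atlas.genes) != list(tree.genes):
        raise ValueError("gene lists of tree and atlas do not match")
    labels = {}
    # vectorized recursive descent: route index sets down the tree together
    stack = [(0, np.arange(atlas.n_voxels, dtype=np.int64))]
    while stack:
        nid, idx = stack.pop()
        node = tree.nodes[nid]
        if idx.size == 0:
            continue
        stop = node.is_leaf or node.axis is None or (
            max_depth is not None and node.depth >= max_depth
        )
        if stop:
            for v in idx:
                labels[int(v)] = node.path
            continue
        w = (atlas.X[idx] - node.mean) @ node.axis
        stack.append((node.left, idx[w < 0]))
        stack.append((node.right, idx[w >= 0]))
    return labels


def spread_profile(tree: HierarchyTree, coords: np.ndarray) -> pd.DataFrame:
    """Per-depth median and quartiles of normalized spatial spread.

    A region's spread is the mean Euclidean distance of its member voxel
    coordinates to their centroid, normalized by the root's spread.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.shape[0] < tree.n_voxels:
        raise ValueError("every member voxel needs a coordinate")

    def spread(members: np.ndarray) -> float:
        pts = coords[members]
        centroid = pts.mean(axis=0)
        return float(np.linalg.norm(pts - centroid, axis=1).mean())

    root_spread = spread(tree.root.members)
    rows = []
    for depth in range(tree.max_depth() + 1):
        vals = [spread(n.members) / root_spread for n in tree.nodes_at_depth(depth)]
        if not vals:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {"depth": depth, "median": med, "q1": q1, "q3": q3, "n_regions": len(vals)}
        )
    return pd.DataFrame(rows)


def _check_same_voxels(a: dict, b: dict) -> list:
    if set(a) != set(b):
        raise ValueError("assignments cover different voxel sets")
    return sorted(a)


def agreement_at_depth(a: dict, b: dict, depth: int) -> float:
    """Fraction of voxels whose depth-``depth`` path prefixes coincide.

    The chance reference for independent assignments is ``2**-depth``.
    """
    voxels = _check_same_voxels(a, b)
    hits = sum(1 for v in voxels if a[v][:depth] == b[v][:depth])
    return hits / len(voxels)


def depth_weighted_agreement(a: dict, b: dict) -> float:
    """Agreement score in [0, 1] that rewards deep matching prefixes.

    Per voxel, depth ``d`` contributes weight ``d`` when the two depth-d
    prefixes agree (a mismatch at a shallow depth forfeits all deeper
    depths, since prefixes then differ); the normalizer makes identical
    assignments score exactly 1. Random assignments score about
    ``sum(d * 2**-d) / sum(d)``.
    """
    voxels = _check_same_voxels(a, b)
    num = 0.0
    den = 0.0
    for v in voxels:
        la, lb = a[v], b[v]
        D = min(len(la), len(lb))
        for d in range(1, D + 1):
            den += d
            if la[:d] == lb[:d]:
                num += d
    return num / den if den else 1.0


def axis_correlation(
    trees: list, pairs: list, gene_indices: list | None = None
) -> np.ndarray:
    """Pearson correlation matrix between axis vectors of named nodes.

    ``pairs`` is a list of ``(tree_index, path)`` references; entry
    (i, j) is the correlation between the axes of the i-th and j-th
    referenced node. ``gene_indices`` optionally gives, per tree, the
    indices embedding that tree's gene list into a common gene space
    (needed when trees were built on gene subsets).
    """
    axes = []
    n_genes_common = None
    for t_idx, path in pairs:
        tree = trees[t_idx]
        node = tree.node_at_path(path)
        if node.axis is None:
            raise ValueError(f"node at path {path!r} has no axis")
        if gene_indices is None:
            vec = node.axis
            if n_genes_common is None:
                n_genes_common = len(vec)
            elif len(vec) != n_genes_common:
                raise ValueError("axis lengths (gene lists) do not match")
        else:
            idx = gene_indices[t_idx]
            if n_genes_common is None:
                n_genes_common = int(np.max([np.max(i) for i in gene_indices])) + 1
            vec = np.zeros(n_genes_common)
            vec[idx] = node.axis
        axes.append(vec)
    return np.corrcoef(np.array(axes))


def harmonized_relabel(
    reference: HierarchyTree,
    other: HierarchyTree,
    other_gene_indices: np.ndarray | None = None,
):
    """Build a label translator aligning ``other``'s arbitrary L/R choices
    to ``reference``'s.

    Left/right at each split is arbitrary, so before comparing two
    independently computed hierarchies the axes of corresponding nodes
    are sign-aligned: descending matched paths from the root, if the dot
    product of the two nodes' axes is negative, ``other``'s L/R labels
    are swapped at that node. ``other_gene_indices`` maps ``other``'s
    gene axis entries into the reference gene space when ``other`` was
    built on a gene subset. Returns a callable mapping an ``other``
    path label to the reference frame.
    """
    same_voxels = reference.n_voxels == other.n_voxels

    def overlap(tree_a, node_a, tree_b, node_b):
        return len(
            set(node_a.members.tolist()) & set(node_b.members.tolist())
        )

    def child_offset(tree, node, side):
        child = tree.nodes[node.left if side == "L" else node.right]
        return child.mean - node.mean

    flip_at: dict = {}
    stack = [("", "")]  # (reference path, other ORIGINAL path)
    while stack:
        rp, op = stack.pop()
        try:
            rn = reference.node_at_path(rp)
            on = other.node_at_path(op)
        except KeyError:
            continue
        if rn.axis is None or on.axis is None:
            continue
        if same_voxels:
            # hierarchies over one voxel set: match children by member
            # overlap (robust even under global data negation, which
            # preserves sign-normalized axes while swapping memberships)
            rl, rr = reference.nodes[rn.left], reference.nodes[rn.right]
            ol, orr = other.nodes[on.left], other.nodes[on.right]
            straight = overlap(reference, rl, other, ol) + overlap(
                reference, rr, other, orr
            )
            crossed = overlap(reference, rl, other, orr) + overlap(
                reference, rr, other, ol
            )
            flip = crossed > straight
        else:
            # different voxel sets (e.g. another developmental stage):
            # align by the geometry of the split in gene space
            r_off = child_offset(reference, rn, "L")
            o_off = child_offset(other, on, "L")
            if other_gene_indices is not None:
                r_off = r_off[other_gene_indices]
            flip = bool(np.dot(r_off, o_off) < 0)
        flip_at[op] = flip
        for ch in "LR":
            o_child = op + ch
            r_child = rp + (("R" if ch == "L" else "L") if flip else ch)
            stack.append((r_child, o_child))

    def translate(label: str) -> str:
        out = []
        prefix = ""
        for ch in label:
            flip = flip_at.get(prefix, False)
            out.append(("R" if ch == "L" else "L") if flip else ch)
            prefix += ch
        return "".join(out)

    return translate


def reconstruction_determination(
    forest,
    expr,
    asym,
    tree: HierarchyTree,
    voxel_members: list,
    max_generation: int = 6,
    max_tree_depth: int | None = None,
) -> pd.DataFrame:
    """Determination (squared Pearson correlation) of the reconstruction
    against simulated ground truth, per true-tree generation.

    Every true internal node up to ``max_generation`` is matched to the
    estimated hierarchy node with maximal Jaccard overlap of leaf-cell
    progeny (estimated nodes own the cells of their member voxels).
    For each matched pair the squared correlation is computed between
    the true division asymmetry and the estimated axis (sign-invariant)
    and between the true ancestor expression and the estimated mean
    profile. Unmatched true nodes (no overlapping estimated node with a
    defined axis) are counted, not silently dropped.
    """
    if max_tree_depth is None:
        max_tree_depth = max_generation + 2

    leaves = forest.leaves
    leaf_index = {int(c): i for i, c in enumerate(leaves)}
    n_leaves = leaves.size

    est_nodes = [
        n for n in tree.nodes if n.depth <= max_tree_depth and n.axis is not None
    ]
    est_mask = np.zeros((len(est_nodes), n_leaves), dtype=bool)
    for k, n in enumerate(est_nodes):
        for v in n.members:
            for c in voxel_members[int(v)]:
                est_mask[k, leaf_index[int(c)]] = True
    est_sizes = est_mask.sum(axis=1)

    generations = forest.generations()
    rows = []
    for node in forest.internal_nodes:
        g = int(generations[node])
        if g > max_generation:
            continue
        true_set = np.zeros(n_leaves, dtype=bool)
        for c in forest.leaf_descendants(int(node)):
            true_set[leaf_index[int(c)]] = True
        inter = est_mask.astype(np.int64) @ true_set.astype(np.int64)
        union = est_sizes + true_set.sum() - inter
        jac = inter / np.maximum(union, 1)
        if jac.max() <= 0:
            rows.append(
                {"generation": g, "r2_asym": np.nan, "r2_expr": np.nan, "matched": False}
            )
            continue
        best = est_nodes[int(np.argmax(jac))]
        d_true = asym.lookup(int(node))
        c_true = expr.X[int(node)]
        r_a = np.corrcoef(d_true, best.axis)[0, 1]
        r_e = np.corrcoef(c_true, best.mean)[0, 1]
        rows.append(
            {
                "generation": g,
                "r2_asym": float(r_a**2),
                "r2_expr": float(r_e**2),
                "matched": True,
            }
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby("generation")
        .agg(
            r2_asym=("r2_asym", "mean"),
            r2_expr=("r2_expr", "mean"),
            n_nodes=("generation", "size"),
            n_unmatched=("matched", lambda m: int((~m).sum())),
        )
        .reset_index()
    )
    return out
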