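"""Gabriel-graph adjacency over voxel centroids.

The spatial graph used for growth-cone movement keeps a Delaunay edge
(u, v) only if the ball having uv as diameter contains no third point.
The test uses the closed ball: a point on or inside the diametral sphere
blocks the edge. With the closed rule the Gabriel graph of a full cubic
lattice is exactly the 6-connected face adjacency (a face diagonal's
diametral sphere passes through the two right-angle lattice neighbours,
which therefore block it), and the Euclidean minimum spanning tree is
always a subgraph, so the graph is connected whenever the input is one
point set. Such an empty closed ball also witnesses that the edge
belongs to every Delaunay triangulation, so filtering Delaunay
candidates cannot miss a Gabriel edge even for degenerate (cospherical)
inputs; fully collinear or coplanar point sets, which Qhull rejects,
fall back to the brute-force pairwise test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial import Delaunay, QhullError, cKDTree

__all__ = ["SpatialGraph", "gabriel_graph", "gabriel_edges_bruteforce"]

#: relative tolerance for the closed-ball blocking test
_BALL_RTOL = 1e-9


@dataclass
class SpatialGraph:
    """Undirected simple graph over points with 3D coordinates."""

    coords: np.ndarray  # (n, 3) float
    edges: set  # of sorted (u, v) tuples
    adjacency: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.adjacency:
            adj = {i: [] for i in range(self.n_nodes)}
            for u, v in self.edges:
                adj[u].append(v)
                adj[v].append(u)
            self.adjacency = {u: sorted(vs) for u, vs in adj.items()}

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def _csgraph(self):
        if not self.edges:
            return coo_matrix((self.n_nodes, self.n_nodes))
        e = np.array(sorted(self.edges))
        data = np.ones(len(e))
        return coo_matrix(
            (np.r_[data, data], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
            shape=(self.n_nodes, self.n_nodes),
        )

    def is_connected(self) -> bool:
        if self.n_nodes <= 1:
            return True
        return connected_components(self._csgraph(), directed=False)[0] == 1

    def hop_distances(self, source: int) -> np.ndarray:
        """Unweighted graph distances (in voxels) from ``source``."""
        d = shortest_path(self._csgraph(), unweighted=True, indices=source)
        return d

    def write_edge_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("u\tv\n")
            for u, v in sorted(self.edges):
                fh.write(f"{u}\t{v}\n")


def _check_duplicates(coords: np.ndarray) -> None:
    _, inverse, counts = np.unique(
        coords, axis=0, return_inverse=True, return_counts=True
    )
    if np.any(counts > 1):
        dup_groups = np.flatnonzero(counts > 1)
        ids = [np.flatnonzero(inverse == gidx).tolist() for gidx in dup_groups]
        raise ValueError(f"duplicate coordinates for point ids {ids}")


def gabriel_edges_bruteforce(coords: np.ndarray) -> set:
    """O(n^3) reference Gabriel test over all point pairs (closed ball)."""
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    edges = set()
    for u in range(n):
        for v in range(u + 1, n):
            mid = 0.5 * (coords[u] + coords[v])
            r2 = np.sum((coords[u] - mid) ** 2)
            d2 = np.sum((coords - mid) ** 2, axis=1)
            d2[[u, v]] = np.inf
            if np.min(d2) > r2 * (1.0 + _BALL_RTOL):
                edges.add((u, v))
    return edges


def gabriel_graph(coords: np.ndarray, assume_lattice: bool = False) -> SpatialGraph:
    """Build the Gabriel graph of a 3D point set.

    ``assume_lattice=True`` is a fast path for exact integer-lattice
    centroids: it returns the 6-connected face adjacency directly, which
    equals the Gabriel graph on such point sets.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (n, 3)")
    n = coords.shape[0]
    if n < 1:
        raise ValueError("at least one point required")
    _check_duplicates(coords)

    if assume_lattice:
        icoords = coords.astype(np.int64)
        if not np.allclose(coords, icoords):
            raise ValueError("assume_lattice requires integer coordinates")
        index = {tuple(c): i for i, c in enumerate(icoords)}
        edges = set()
        for i, c in enumerate(icoords):
            for d in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
                j = index.get((c[0] + d[0], c[1] + d[1], c[2] + d[2]))
                if j is not None:
                    edges.add((min(i, j), max(i, j)))
        return SpatialGraph(coords=coords, edges=edges)

    if n == 1:
        return SpatialGraph(coords=coords, edges=set())
    if n <= 4:
        return SpatialGraph(coords=coords, edges=gabriel_edges_bruteforce(coords))

    try:
        tri = Delaunay(coords)
    except QhullError:
        # collinear / coplanar input: no 3D triangulation exists
        return SpatialGraph(coords=coords, edges=gabriel_edges_bruteforce(coords))

    candidates = set()
    for simplex in tri.simplices:
        for a in range(4):
            for b in range(a + 1, 4):
                u, v = int(simplex[a]), int(simplex[b])
                candidates.add((min(u, v), max(u, v)))

    tree = cKDTree(coords)
    edges = set()
    for u, v in candidates:
        mid = 0.5 * (coords[u] + coords[v])
        r = 0.5 * np.linalg.norm(coords[u] - coords[v])
        blockers = tree.query_ball_point(mid, r * (1.0 + _BALL_RTOL))
        if all(b in (u, v) for b in blockers):
            edges.add((u, v))
    return SpatialGraph(coords=coords, edges=edges)
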