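"""Deterministic toy inputs used throughout the test suite and docs."""

from __future__ import annotations

import numpy as np

from .atlas import ExpressionAtlas
from .lineage_sim import SimParams, assign_expression, balanced_forest, place_cells

__all__ = ["make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = (
    "two_voxel_atlas",
    "lattice_27",
    "two_cluster_points",
    "balanced_depth4",
)


def _two_voxel_atlas() -> ExpressionAtlas:
    return ExpressionAtlas(
        coords=np.array([[0, 0, 0], [1, 0, 0]]),
        genes=["g0001", "g0002", "g0003"],
        X=np.array([[1.0, -1.0, 0.5], [-1.0, 1.0, -0.5]]),
        stage="normalized",
    )


def _lattice_27() -> np.ndarray:
    """Coordinates of a fully occupied 3x3x3 cell block (one interior
    voxel under a voxel_dim=3 voxelation)."""
    g = np.arange(3)
    return np.array(np.meshgrid(g, g, g, indexing="ij")).reshape(3, -1).T


def _two_cluster_points() -> np.ndarray:
    """Two compact point clusters separated by a wide void; a plain
    Delaunay triangulation bridges the void with hull edges, the Gabriel
    filter must not."""
    rng = np.random.default_rng(7)
    a = rng.uniform(0, 3, size=(12, 3))
    b = rng.uniform(0, 3, size=(12, 3)) + np.array([20.0, 0.0, 0.0])
    return np.vstack([a, b])


def _balanced_depth4():
    """Fully balanced 16-leaf lineage with its ground-truth expression
    and asymmetry tables and cell placements."""
    params = SimParams(
        n_roots=1, n_divisions=16, n_genes=30, symmetric_prob=0.0, seed=11
    )
    forest = balanced_forest(4)
    expr, asym = assign_expression(forest, params)
    grid = place_cells(forest, params)
    return forest, expr, asym, grid


def make_fixture(name: str):
    """Return one of the bundled deterministic fixtures by name."""
    makers = {
        "two_voxel_atlas": _two_voxel_atlas,
        "lattice_27": _lattice_27,
        "two_cluster_points": _two_cluster_points,
        "balanced_depth4": _balanced_depth4,
    }
    try:
        return makers[name]()
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}") from None
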