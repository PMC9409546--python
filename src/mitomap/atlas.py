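"""Voxel-by-gene expression atlases: construction, preprocessing, controls.

An :class:`ExpressionAtlas` holds a voxel coordinate table (integer
triples), a gene name list and a dense voxel-by-gene matrix. Atlases come
from two sources: voxelation of a simulated cell grid, or an external
tab-separated table in the same conventions (``x y z gene...`` header,
one voxel per row, sentinel value -1 for invalid measurements).

Preprocessing follows the order: drop voxels with too many invalid
entries, then drop genes with too many invalid entries across the
surviving voxels, then impute remaining sentinels with the gene mean,
then z-score each gene across voxels (population standard deviation).
Imputed entries therefore become exactly 0 after centering. The shuffle
control applies one global permutation to the flattened voxel-by-gene
matrix, preserving the value multiset while destroying all spatial and
gene structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lineage_sim import CellGrid, ExpressionTable

__all__ = [
    "ExpressionAtlas",
    "PreprocessReport",
    "SENTINEL",
    "voxelate",
    "filter_invalid",
    "normalize",
    "shuffle_control",
    "read_atlas",
    "write_atlas",
]

SENTINEL = -1.0


@dataclass
class ExpressionAtlas:
    """Voxel coordinates, gene names and the expression matrix.

    ``stage`` tracks provenance: raw | filtered | normalized | shuffled.
    ``cell_members`` (present only for voxelated simulations) maps each
    voxel row to the array of leaf-cell ids it aggregates.
    """

    coords: np.ndarray  # (n_voxels, 3) int
    genes: list
    X: np.ndarray  # (n_voxels, n_genes) float
    stage: str = "raw"
    cell_members: list | None = field(default=None, repr=False)
    constant_genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64)
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_voxels, 3)")
        if self.X.shape != (self.coords.shape[0], len(self.genes)):
            raise ValueError("X must be (n_voxels, n_genes)")
        uniq = {tuple(c) for c in self.coords}
        if len(uniq) != self.coords.shape[0]:
            raise ValueError("duplicate voxel coordinates")

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class PreprocessReport:
    """Counts removed by filtering and per-gene imputation counts."""

    voxels_in: int
    genes_in: int
    voxels_removed: int
    genes_removed: int
    imputed_per_gene: dict

    def to_dict(self) -> dict:
        return {
            "voxels_in": self.voxels_in,
            "genes_in": self.genes_in,
            "voxels_removed": self.voxels_removed,
            "genes_removed": self.genes_removed,
            "voxels_retained": self.voxels_in - self.voxels_removed,
            "genes_retained": self.genes_in - self.genes_removed,
            "imputed_per_gene": self.imputed_per_gene,
        }


def voxelate(
    grid: CellGrid,
    expr: ExpressionTable,
    voxel_dim: int,
    aggregate: str = "mean",
) -> ExpressionAtlas:
    """Partition the occupied lattice into ``voxel_dim``-cubed blocks and
    aggregate cell expression per block.

    Blocks are anchored at the minimum corner of the occupied bounding
    box; every block containing at least one cell becomes a voxel whose
    coordinate is the block index. Partially filled boundary blocks are
    kept. Aggregation is the mean by default (``aggregate='sum'`` is
    available for density-style totals).
    """
    if voxel_dim < 1:
        raise ValueError("voxel_dim must be >= 1")
    if aggregate not in ("mean", "sum"):
        raise ValueError("aggregate must be 'mean' or 'sum'")
    cells, coords = grid.cells_and_coords()
    if cells.size == 0:
        raise ValueError("empty grid")

    blocks = (coords - coords.min(axis=0)) // voxel_dim
    uniq, inverse = np.unique(blocks, axis=0, return_inverse=True)
    n_vox = uniq.shape[0]
    g = expr.X.shape[1]

    sums = np.zeros((n_vox, g), dtype=np.float64)
    np.add.at(sums, inverse, expr.X[cells])
    counts = np.bincount(inverse, minlength=n_vox).astype(np.float64)
    Xv = sums if aggregate == "sum" else sums / counts[:, None]

    members = [cells[inverse == v] for v in range(n_vox)]
    genes = [f"g{j + 1:04d}" for j in range(g)]
    return ExpressionAtlas(
        coords=uniq, genes=genes, X=Xv, stage="raw", cell_members=members
    )


def filter_invalid(
    atlas: ExpressionAtlas, max_invalid_frac: float = 0.2
) -> tuple[ExpressionAtlas, PreprocessReport]:
    """Drop voxels then genes whose sentinel fraction exceeds the
    threshold (in that order), then impute remaining sentinels with the
    gene's mean over valid entries."""
    invalid = atlas.X == SENTINEL
    vox_frac = invalid.mean(axis=1)
    keep_vox = vox_frac <= max_invalid_frac
    if not keep_vox.any():
        raise ValueError("all voxels removed by the invalid-fraction filter")

    invalid = invalid[keep_vox]
    gene_frac = invalid.mean(axis=0)
    keep_gene = gene_frac <= max_invalid_frac
    if not keep_gene.any():
        raise ValueError("all genes removed by the invalid-fraction filter")

    X = atlas.X[np.ix_(keep_vox, keep_gene)].copy()
    invalid = invalid[:, keep_gene]
    genes = [g for g, k in zip(atlas.genes, keep_gene) if k]

    imputed = {}
    for j in range(X.shape[1]):
        bad = invalid[:, j]
        if bad.any():
            X[bad, j] = X[~bad, j].mean()
            imputed[genes[j]] = int(bad.sum())

    members = None
    if atlas.cell_members is not None:
        members = [m for m, k in zip(atlas.cell_members, keep_vox) if k]
    out = ExpressionAtlas(
        coords=atlas.coords[keep_vox],
        genes=genes,
        X=X,
        stage="filtered",
        cell_members=members,
    )
    report = PreprocessReport(
        voxels_in=atlas.n_voxels,
        genes_in=atlas.n_genes,
        voxels_removed=int((~keep_vox).sum()),
        genes_removed=int((~keep_gene).sum()),
        imputed_per_gene=imputed,
    )
    return out, report


def normalize(atlas: ExpressionAtlas) -> ExpressionAtlas:
    """Z-score each gene across voxels (population standard deviation).

    Constant gene columns are set to all zeros and recorded in
    ``constant_genes`` rather than dropped, keeping gene indices stable.
    """
    if np.any(atlas.X == SENTINEL):
        raise ValueError("sentinels remain; run filter_invalid first")
    mean = atlas.X.mean(axis=0)
    std = atlas.X.std(axis=0)  # population
    constant = std == 0.0
    std_safe = np.where(constant, 1.0, std)
    X = (atlas.X - mean) / std_safe
    X[:, constant] = 0.0
    return ExpressionAtlas(
        coords=atlas.coords,
        genes=list(atlas.genes),
        X=X,
        stage="normalized",
        cell_members=atlas.cell_members,
        constant_genes=[g for g, c in zip(atlas.genes, constant) if c],
    )


def shuffle_control(atlas: ExpressionAtlas, seed: int) -> ExpressionAtlas:
    """Global permutation of all matrix entries over the flattened
    voxel-by-gene array; coordinates untouched, multiset preserved."""
    rng = np.random.default_rng(seed)
    flat = atlas.X.ravel().copy()
    rng.shuffle(flat)
    return ExpressionAtlas(
        coords=atlas.coords,
        genes=list(atlas.genes),
        X=flat.reshape(atlas.X.shape),
        stage="shuffled",
        cell_members=atlas.cell_members,
        constant_genes=list(atlas.constant_genes),
    )


# ---------------------------------------------------------------------- IO


def write_atlas(atlas: ExpressionAtlas, path) -> None:
    """Tab-separated table with header ``x y z gene...``, one voxel per row."""
    df = pd.DataFrame(atlas.coords, columns=["x", "y", "z"])
    for j, g in enumerate(atlas.genes):
        df[g] = atlas.X[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_atlas(path, stage: str = "raw") -> ExpressionAtlas:
    """Parse an atlas TSV; malformed input raises with the offending line."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["x", "y", "z"]:
            raise ValueError(
                f"{path}: line 1: header must start with 'x\\ty\\tz', got {header[:3]}"
            )
        genes = header[3:]
        if not genes:
            raise ValueError(f"{path}: line 1: no gene columns in header")
        coords, rows, seen = [], [], {}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            try:
                c = tuple(int(v) for v in fields[:3])
                vals = [float(v) for v in fields[3:]]
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if c in seen:
                raise ValueError(
                    f"{path}: line {lineno}: duplicate coordinate {c} "
                    f"(first seen on line {seen[c]})"
                )
            seen[c] = lineno
            coords.append(c)
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no voxel rows")
    return ExpressionAtlas(
        coords=np.array(coords, dtype=np.int64),
        genes=genes,
        X=np.array(rows, dtype=np.float64),
        stage=stage,
    )
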