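"""End-to-end orchestration: simulate -> voxelate -> decompose -> graph ->
guide -> report, with a content-hashed manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import atlas as atlas_mod
from . import guidance, hierarchy, spatial
from .lineage_sim import SimParams, simulate_tissue

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Flat, file-serializable configuration of one full run."""

    n_roots: int = 4
    n_divisions: int = 2000
    n_genes: int = 50
    symmetric_prob: float = 0.2
    clock_rate: float = 1.0
    seed: int = 0
    voxel_dim: int = 3
    max_invalid_frac: float = 0.2
    decompose_max_depth: int = 0  # 0 = unlimited
    n_axons: int = 5
    region_depth: int = 3
    noise_levels: str = ""  # comma-separated, e.g. "0,0.5,1.0"
    out_dir: str = "mitomap_run"

    def sim_params(self) -> SimParams:
        return SimParams(
            n_roots=self.n_roots,
            n_divisions=self.n_divisions,
            n_genes=self.n_genes,
            symmetric_prob=self.symmetric_prob,
            clock_rate=self.clock_rate,
            seed=self.seed,
        )

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in asdict(self).items():
                fh.write(f"{k}={v}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in cls.__dataclass_fields__.values()}
        casts = {"int": int, "float": float, "str": str}
        for lineno, line in enumerate(open(path), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected key=value")
            k, v = line.split("=", 1)
            k = k.strip()
            if k not in types:
                raise ValueError(f"{path}: line {lineno}: unknown key {k!r}")
            kwargs[k] = casts[types[k]](v.strip())
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, log=None) -> dict:
    """Run the full pipeline and return a manifest of output artifacts.

    The manifest lists every produced file with a SHA-256 content hash;
    identical configurations produce identical hashes. On a stage
    failure a ``PipelineError`` naming the stage is raised and a
    ``FAILED`` marker file recording the stage is left next to any
    partial outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    log = log or (lambda msg: None)
    stage = "setup"

    def run_stage(name, fn):
        nonlocal stage
        stage = name
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            (out / "FAILED").write_text(f"stage={name}\nerror={exc}\n")
            raise PipelineError(name, exc) from exc
        log(f"stage={name} wall_s={time.perf_counter() - t0:.2f}")
        return result

    def emit(path: Path):
        files.append(path)

    # --- simulate
    forest, expr, asym, grid = run_stage(
        "lineage_sim", lambda: simulate_tissue(config.sim_params())
    )
    p = out / "forest_edges.tsv"
    forest.to_edge_table().to_csv(p, sep="\t", index=False)
    emit(p)
    p = out / "forest.nwk"
    p.write_text(forest.to_newick() + "\n")
    emit(p)
    p = out / "cells.tsv"
    grid.to_table(root_id=forest.root_id).to_csv(p, sep="\t", index=False)
    emit(p)

    # --- voxelate + preprocess
    def stage_atlas():
        raw = atlas_mod.voxelate(grid, expr, config.voxel_dim)
        filt, report = atlas_mod.filter_invalid(raw, config.max_invalid_frac)
        return atlas_mod.normalize(filt), report

    atl, report = run_stage("atlas", stage_atlas)
    p = out / "atlas.tsv"
    atlas_mod.write_atlas(atl, p)
    emit(p)
    p = out / "preprocess_report.json"
    p.write_text(json.dumps(report.to_dict(), indent=2))
    emit(p)

    # --- decompose
    max_depth = config.decompose_max_depth or None
    tree = run_stage("hierarchy", lambda: hierarchy.decompose(atl, max_depth))
    p = out / "hierarchy.json"
    tree.to_json(p)
    emit(p)
    p = out / "hierarchy.nwk"
    p.write_text(tree.to_newick() + "\n")
    emit(p)

    # --- spatial + state graph
    sgraph = run_stage(
        "spatial_graph", lambda: spatial.gabriel_graph(atl.coords.astype(float))
    )
    p = out / "spatial_edges.tsv"
    sgraph.write_edge_tsv(p)
    emit(p)
    sg = run_stage("state_graph", lambda: guidance.build_state_graph(tree, atl, sgraph))

    # --- axons
    def stage_axons():
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 99]))
        sources = rng.choice(atl.n_voxels, size=min(config.n_axons, atl.n_voxels),
                             replace=False)
        return [guidance.grow_axon(sg, int(v)) for v in np.sort(sources)]

    arbors = run_stage("guidance", stage_axons)
    for i, arbor in enumerate(arbors):
        p = out / f"axon_{i:03d}.swc"
        guidance.write_swc(arbor, p)
        emit(p)

    # --- metrics + connectivity
    def stage_metrics():
        spread = hierarchy.spread_profile(tree, atl.coords.astype(float))
        self_assign = tree.assignment()
        proj = hierarchy.project(tree, atl)
        metrics = {
            "n_voxels": atl.n_voxels,
            "n_axons": len(arbors),
            "spread_profile": spread.to_dict(orient="records"),
            "self_projection_agreement_depth3": hierarchy.agreement_at_depth(
                self_assign, proj, 3
            ),
            "path_metrics": [
                guidance.path_metrics(a).to_dict(orient="records") for a in arbors
            ],
            "max_source_distance_per_axon": [a.max_cost for a in arbors],
        }
        levels = [float(x) for x in config.noise_levels.split(",") if x.strip()]
        if levels:
            dissims = {}
            base = arbors[0]
            for lv in levels:
                noisy = guidance.add_noise(atl, lv, seed=config.seed + 1)
                sg_n = guidance.build_state_graph(tree, noisy, sgraph)
                a_n = guidance.grow_axon(sg_n, base.source_voxel)
                dissims[str(lv)] = guidance.arbor_dissimilarity(base, a_n)
            metrics["noise_dissimilarity"] = dissims
        return metrics

    metrics = run_stage("metrics", stage_metrics)
    p = out / "metrics.json"
    p.write_text(json.dumps(metrics, indent=2))
    emit(p)

    conn = run_stage(
        "connectivity",
        lambda: guidance.connectivity_matrix(arbors, tree, config.region_depth),
    )
    p = out / "connectivity.csv"
    conn.to_csv(p)
    emit(p)

    manifest = {
        "config": asdict(config),
        "files": {f.name: _sha256(f) for f in sorted(files)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    marker = out / "FAILED"
    if marker.exists():
        marker.unlink()
    return manifest
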