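import numpy as np
import pytest

import mitomap as m


@pytest.fixture(scope="session")
def small_sim():
    """A small but non-trivial simulated tissue shared across the suite."""
    params = m.SimParams(n_roots=4, n_divisions=1500, n_genes=40, seed=11)
    forest, expr, asym, grid = m.simulate_tissue(params)
    return params, forest, expr, asym, grid


@pytest.fixture(scope="session")
def small_atlas(small_sim):
    _, _forest, expr, _asym, grid = small_sim
    raw = m.voxelate(grid, expr, 3)
    filt, _report = m.filter_invalid(raw)
    return m.normalize(filt)


@pytest.fixture(scope="session")
def small_tree(small_atlas):
    return m.decompose(small_atlas)


@pytest.fixture(scope="session")
def small_sgraph(small_atlas):
    return m.gabriel_graph(small_atlas.coords.astype(float))


@pytest.fixture(scope="session")
def small_stategraph(small_tree, small_atlas, small_sgraph):
    return m.build_state_graph(small_tree, small_atlas, small_sgraph)


@pytest.fixture(scope="session")
def small_arbors(small_stategraph, small_atlas):
    rng = np.random.default_rng(17)
    sources = np.sort(rng.choice(small_atlas.n_voxels, size=8, replace=False))
    return [m.grow_axon(small_stategraph, int(v)) for v in sources]
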