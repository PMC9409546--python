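"""Tests for the recursive covariance decomposition and its metrics.

The decomposition itself is checked against an independent brute-force
oracle (explicit covariance matrix + power iteration) on small random
atlases, and the metric operations against closed forms and Monte Carlo.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mitomap as m
from mitomap.atlas import ExpressionAtlas
from mitomap.hierarchy import ZeroVarianceError, principal_axis


# ------------------------------------------------------------- oracles


def _power_iteration_axis(X, tol=1e-12, max_iter=10_000):
    """Independent leading-eigenvector oracle: explicit Q plus power
    iteration, no SVD/eigh."""
    Xc = X - X.mean(axis=0)
    Q = Xc.T @ Xc
    rng = np.random.default_rng(12345)
    v = rng.normal(size=Q.shape[0])
    v /= np.linalg.norm(v)
    for _ in range(max_iter):
        w = Q @ v
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w /= nw
        if min(np.linalg.norm(w - v), np.linalg.norm(w + v)) < tol:
            v = w
            break
        v = w
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def _brute_force_decompose(X, indices):
    """Recursive sign-split using the power-iteration oracle; returns the
    set of (frozenset of member indices) over all tree nodes."""
    bins = {frozenset(indices)}
    if len(indices) < 2:
        return bins
    Xc = X[indices] - X[indices].mean(axis=0)
    if not np.any(Xc):
        return bins
    axis = _power_iteration_axis(X[indices])
    w = Xc @ axis
    left = indices[w < 0]
    right = indices[w >= 0]
    bins |= _brute_force_decompose(X, left)
    bins |= _brute_force_decompose(X, right)
    return bins


def _atlas_from_matrix(X):
    n = X.shape[0]
    coords = np.column_stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)])
    return ExpressionAtlas(coords, [f"g{j}" for j in range(X.shape[1])], X)


# ----------------------------------------------------- principal_axis


def test_principal_axis_hand_worked_2d():
    """2x2 eigenproblem by hand: all points on the diagonal, so the axis
    is (1,1)/sqrt(2) and coefficients are the diagonal positions."""
    X = np.array([[1.0, 1], [-1, -1], [2, 2], [-2, -2]])
    axis, w = principal_axis(X)
    np.testing.assert_allclose(axis, [1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-12)
    np.testing.assert_allclose(
        w, [np.sqrt(2), -np.sqrt(2), 2 * np.sqrt(2), -2 * np.sqrt(2)], atol=1e-12
    )


def test_principal_axis_single_varying_gene():
    X = np.array([[0.0, 1, 5], [0, 2, 5], [0, 4, 5]])
    axis, _ = principal_axis(X)
    np.testing.assert_allclose(np.abs(axis), [0, 1, 0], atol=1e-12)
    assert axis[1] > 0


def test_principal_axis_degenerate_rows():
    with pytest.raises(ZeroVarianceError):
        principal_axis(np.ones((4, 3)))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_principal_axis_matches_power_iteration(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 9))
    g = int(rng.integers(2, 6))
    X = rng.normal(size=(n, g))
    axis, w = principal_axis(X)
    assert np.linalg.norm(axis) == pytest.approx(1.0)
    assert axis[int(np.argmax(np.abs(axis)))] > 0
    oracle = _power_iteration_axis(X)
    assert min(np.linalg.norm(axis - oracle), np.linalg.norm(axis + oracle)) < 1e-6


# ----------------------------------------------------------- decompose


def test_decompose_two_voxels(small_atlas):
    X = np.array([[1.0, 0.0], [0.0, 1.0]])
    tree = m.decompose(_atlas_from_matrix(X))
    assert len(tree.nodes) == 3
    leaves = [n for n in tree.nodes if n.is_leaf]
    assert sorted(len(n.members) for n in leaves) == [1, 1]
    assert tree.max_depth() == 1


def test_decompose_identical_voxels_is_single_degenerate_leaf():
    X = np.ones((5, 3))
    tree = m.decompose(_atlas_from_matrix(X))
    assert len(tree.nodes) == 1
    assert tree.root.degenerate and tree.root.is_leaf


@pytest.mark.parametrize("seed", range(8))
def test_decompose_matches_bruteforce_oracle(seed):
    """On <= 8-voxel random atlases the produced bins equal those of an
    independent power-iteration implementation, and counts follow
    binary-tree arithmetic (n leaves, n-1 internal nodes)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 9))
    X = rng.normal(size=(n, 4))
    tree = m.decompose(_atlas_from_matrix(X))
    got = {frozenset(int(v) for v in node.members) for node in tree.nodes}
    expected = _brute_force_decompose(X, np.arange(n))
    assert got == expected
    leaves = [node for node in tree.nodes if node.is_leaf]
    assert len(leaves) == n
    assert len(tree.nodes) - len(leaves) == n - 1


def test_partition_invariant_and_root_mean(small_tree, small_atlas):
    for depth in range(4):
        members = [n.members for n in small_tree.nodes_at_depth(depth)]
        if not members:
            break
        cat = np.concatenate(members)
        assert cat.size == len(set(cat.tolist())) == small_atlas.n_voxels
    np.testing.assert_allclose(
        small_tree.root.mean, small_atlas.X.mean(axis=0), atol=1e-12
    )


def test_node_at_path_and_newick(small_tree):
    node = small_tree.node_at_path("L")
    assert node.depth == 1 and node.path == "L"
    nwk = small_tree.to_newick()
    assert nwk.endswith(";") and "root" in nwk


def test_tree_json_roundtrip(tmp_path, small_tree):
    path = tmp_path / "tree.json"
    small_tree.to_json(path)
    back = m.HierarchyTree.from_json(path)
    assert len(back.nodes) == len(small_tree.nodes)
    for a, b in zip(small_tree.nodes, back.nodes):
        assert a.path == b.path
        np.testing.assert_array_equal(a.members, b.members)
        np.testing.assert_allclose(a.mean, b.mean)


# ------------------------------------------------------------- project


def test_self_projection_reproduces_decomposition(small_tree, small_atlas):
    assign = small_tree.assignment()
    proj = m.project(small_tree, small_atlas)
    assert proj == assign
    for depth in (0, 1, 2, 3):
        proj_d = m.project(small_tree, small_atlas, max_depth=depth)
        assert all(proj_d[v] == assign[v][:depth] for v in assign)


def test_project_depth_zero_and_gene_mismatch(small_tree, small_atlas):
    proj = m.project(small_tree, small_atlas, max_depth=0)
    assert set(proj.values()) == {""}
    other = ExpressionAtlas(
        small_atlas.coords, ["x" + g for g in small_atlas.genes], small_atlas.X
    )
    with pytest.raises(ValueError):
        m.project(small_tree, other)


def test_shuffled_projection_splits_symmetrically_at_root(small_tree, small_atlas):
    """Structure-destroyed voxels projected onto a structured hierarchy
    split ~50/50 at the root (whose centering mean is zero), and agree
    with the original assignment only at chance at depth 1."""
    sh = m.shuffle_control(small_atlas, seed=21)
    proj = m.project(small_tree, sh, max_depth=1)
    n = len(proj)
    n_left = sum(lab == "L" for lab in proj.values())
    se = np.sqrt(0.25 * n)
    assert abs(n_left - n / 2) < 4 * se
    agree = m.agreement_at_depth(small_tree.assignment(1), proj, 1)
    # chance level is Sum_b p_b q_b; with near-balanced bins ~ 1/2
    assert abs(agree - 0.5) < 0.15


# ----------------------------------------------------- spread profile


def test_spread_profile_normalization_and_singletons(small_tree, small_atlas):
    prof = m.spread_profile(small_tree, small_atlas.coords.astype(float))
    assert prof.loc[prof.depth == 0, "median"].item() == pytest.approx(1.0)
    deepest = max(
        n.depth for n in small_tree.nodes if n.is_leaf and len(n.members) == 1
    )
    # a singleton region has spread exactly 0
    singles = [n for n in small_tree.nodes if len(n.members) == 1]
    assert singles
    row = prof.loc[prof.depth == deepest]
    assert row["median"].item() >= 0.0
    assert prof["median"].iloc[-1] < prof["median"].iloc[0]


# ---------------------------------------------------------- agreement


def test_agreement_identity_and_prefix_monotonicity():
    a = {0: "LLL", 1: "LRL", 2: "RRL"}
    assert m.agreement_at_depth(a, a, 2) == 1.0
    b = {0: "RLL", 1: "LRL", 2: "RRL"}  # voxel 0 mismatch at depth 1
    for d in (1, 2, 3):
        assert m.agreement_at_depth(a, b, d) == pytest.approx(2 / 3)


def test_agreement_random_matches_chance():
    rng = np.random.default_rng(3)
    n = 4000
    a = {v: "".join(rng.choice(["L", "R"], 3)) for v in range(n)}
    b = {v: "".join(rng.choice(["L", "R"], 3)) for v in range(n)}
    got = m.agreement_at_depth(a, b, 3)
    se = np.sqrt((1 / 8) * (7 / 8) / n)
    assert abs(got - 1 / 8) < 4 * se


def test_agreement_rejects_voxel_mismatch():
    with pytest.raises(ValueError):
        m.agreement_at_depth({0: "L"}, {1: "L"}, 1)


def test_depth_weighted_agreement_endpoints_and_chance():
    a = {v: "LLRLR" for v in range(10)}
    assert m.depth_weighted_agreement(a, a) == 1.0
    b = {v: "RLRLR" for v in range(10)}  # depth-1 mismatch forfeits all
    assert m.depth_weighted_agreement(a, b) == 0.0
    rng = np.random.default_rng(4)
    n, D = 3000, 5
    ra = {v: "".join(rng.choice(["L", "R"], D)) for v in range(n)}
    rb = {v: "".join(rng.choice(["L", "R"], D)) for v in range(n)}
    expected = sum(d * 2.0**-d for d in range(1, D + 1)) / sum(range(1, D + 1))
    assert m.depth_weighted_agreement(ra, rb) == pytest.approx(expected, abs=0.02)


# ----------------------------------------------------- axis correlation


def test_axis_correlation_trivial_cases():
    tree_a = m.decompose(
        _atlas_from_matrix(np.random.default_rng(0).normal(size=(6, 4)))
    )
    r = m.axis_correlation([tree_a], [(0, ""), (0, "")])
    np.testing.assert_allclose(r, np.ones((2, 2)), atol=1e-12)


def test_axis_correlation_perturbed_copies_agree():
    """Root axes of decompositions of noise-perturbed copies of one atlas
    correlate near 1, far above the cross-depth baseline."""
    rng = np.random.default_rng(5)
    X = rng.normal(size=(60, 20))
    X[:, 0] += np.linspace(-4, 4, 60)  # one dominant direction
    t1 = m.decompose(_atlas_from_matrix(X + 0.05 * rng.normal(size=X.shape)))
    t2 = m.decompose(_atlas_from_matrix(X + 0.05 * rng.normal(size=X.shape)))
    r = m.axis_correlation([t1, t2], [(0, ""), (1, ""), (0, "L")])
    assert abs(r[0, 1]) > 0.95
    assert abs(r[0, 1]) > abs(r[0, 2])


def test_harmonized_relabel_fixes_arbitrary_sign():
    """Flipping an atlas's sign flips every split's L/R; the relabeler
    recovers the correspondence."""
    rng = np.random.default_rng(6)
    X = rng.normal(size=(30, 8))
    t_ref = m.decompose(_atlas_from_matrix(X))
    t_flip = m.decompose(_atlas_from_matrix(-X))
    translate = m.harmonized_relabel(t_ref, t_flip)
    a = t_ref.assignment()
    b = {v: translate(lab) for v, lab in t_flip.assignment().items()}
    assert m.agreement_at_depth(a, b, 1) == 1.0
    assert m.depth_weighted_agreement(a, b) > 0.9


# ---------------------------------------- reconstruction determination


def _oracle_tree_from_truth(forest, expr, grid, max_generation):
    """HierarchyTree built from the TRUE progeny memberships, with means
    recomputed from member cells (voxel_dim=1: one voxel per cell)."""
    from mitomap.hierarchy import HierarchyNode, HierarchyTree

    cells, _ = grid.cells_and_coords()
    vox_of_cell = {int(c): i for i, c in enumerate(cells)}
    gen = forest.generations()
    nodes = []

    def build(node_id, parent, depth, path):
        nid = len(nodes)
        members = np.array(
            sorted(vox_of_cell[int(c)] for c in forest.leaf_descendants(node_id)),
            dtype=np.int64,
        )
        leaf_rows = expr.X[forest.leaf_descendants(node_id)]
        hn = HierarchyNode(
            node_id=nid,
            parent=parent,
            depth=depth,
            path=path,
            members=members,
            mean=leaf_rows.mean(axis=0),
        )
        nodes.append(hn)
        if forest.left[node_id] >= 0 and depth < max_generation + 1:
            d = expr.X[forest.left[node_id]] - expr.X[forest.right[node_id]]
            hn.axis = d / np.linalg.norm(d)
            hn.left = build(int(forest.left[node_id]), nid, depth + 1, path + "L")
            hn.right = build(int(forest.right[node_id]), nid, depth + 1, path + "R")
        return nid

    build(0, -1, 0, "")
    return HierarchyTree(
        nodes=nodes, n_voxels=len(cells), n_genes=expr.X.shape[1], genes=[]
    )


@pytest.fixture(scope="module")
def truth_sim():
    params = m.SimParams(
        n_roots=1, n_divisions=600, n_genes=120, symmetric_prob=0.0, seed=23
    )
    return (params,) + m.simulate_tissue(params)


def test_determination_oracle_membership(truth_sim):
    """With true memberships and true asymmetry axes, asymmetry
    determination is exactly 1; expression determination is bounded by
    the mean-of-progeny estimator's irreducible variance (~1 per gene
    from early shared differentials) and so sits well above chance but
    below 1 even with a perfect tree."""
    params, forest, expr, asym, grid = truth_sim
    tree = _oracle_tree_from_truth(forest, expr, grid, max_generation=3)
    cells, _ = grid.cells_and_coords()
    members = [np.array([int(c)]) for c in cells]
    det = m.reconstruction_determination(
        forest, expr, asym, tree, members, max_generation=2
    )
    assert det.r2_asym.round(9).eq(1.0).all()
    assert (det.r2_expr > 0.25).all()
    assert (det.n_unmatched == 0).all()


def test_determination_recovers_early_generations_from_leaves(truth_sim):
    """The decomposition of raw leaf expression determines early ancestors
    far above a shuffled-expression baseline."""
    params, forest, expr, asym, grid = truth_sim
    cells, coords = grid.cells_and_coords()
    atlas = ExpressionAtlas(
        coords, [f"g{j}" for j in range(params.n_genes)], expr.X[cells]
    )
    members = [np.array([int(c)]) for c in cells]
    tree = m.decompose(atlas)
    det = m.reconstruction_determination(
        forest, expr, asym, tree, members, max_generation=4
    )
    sh_tree = m.decompose(m.shuffle_control(atlas, seed=9))
    det_sh = m.reconstruction_determination(
        forest, expr, asym, sh_tree, members, max_generation=4
    )
    early = det[det.generation <= 1]
    early_sh = det_sh[det_sh.generation <= 1]
    assert (early.r2_asym > 0.05).all()
    assert early.r2_asym.mean() > 10 * early_sh.r2_asym.mean()
    assert (early.r2_expr > 0.2).all()
    assert early.r2_expr.mean() > 10 * early_sh.r2_expr.mean()
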