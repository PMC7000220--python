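import numpy as np
import pandas as pd
import pytest

from heartsc.pseudotime import (Module, ModuleSet, PseudotimeTrajectory,
                                build_modules, classify_module_dynamics,
                                order_cells, smooth_profiles, som_1d,
                                som_gene_filter)
from heartsc.stemid import LineageTree

from conftest import make_matrix


def _tree(projections, links):
    proj = pd.DataFrame(projections,
                        columns=["cell_id", "cluster", "target", "t"]
                        ).set_index("cell_id")
    ldf = pd.DataFrame([{"cluster_i": min(a, b), "cluster_j": max(a, b),
                         "n_cells": 1, "p": 0.0, "padj": 0.0,
                         "significant": True} for a, b in links])
    ent = pd.Series(0.5, index=proj.index)
    scores = pd.Series(dtype=float)
    return LineageTree(proj, ldf, ent, scores)


def test_order_cells_sorts_by_projection():
    tree = _tree([("a", 1, 2, 0.2), ("b", 1, 2, 0.8), ("c", 1, 2, 0.5)],
                 [(1, 2)])
    traj = order_cells(tree, [1, 2])
    assert traj.ordered_cells == ["a", "c", "b"]
    assert (np.diff(traj.coords) > 0).all()


def test_order_cells_reversal_is_exact_mirror():
    tree = _tree([("a", 1, 2, 0.2), ("b", 2, 1, 0.3), ("c", 1, 2, 0.9)],
                 [(1, 2)])
    fwd = order_cells(tree, [1, 2]).ordered_cells
    rev = order_cells(tree, [2, 1]).ordered_cells
    assert rev == fwd[::-1]


def test_order_cells_unlinked_path_raises():
    tree = _tree([("a", 1, 2, 0.2)], [(1, 2)])
    with pytest.raises(ValueError):
        order_cells(tree, [1, 3])


def test_som_gene_filter_boundaries():
    m = make_matrix(np.array([[1, 1, 1], [2, 0, 0], [0, 0, 0]]))
    assert som_gene_filter(m) == ["g1"]
    assert som_gene_filter(m, min_count=1) == ["g0", "g1"]


def _linear_traj(n_cells=30):
    cells = [f"c{i}" for i in range(n_cells)]
    return PseudotimeTrajectory([1, 2], cells, np.arange(n_cells, dtype=float))


def test_smoothing_preserves_linear_signal():
    n = 40
    counts = np.vstack([np.arange(n) * 3 + 2,        # linear gene
                        np.full(n, 7)])              # constant gene
    m = make_matrix(counts.astype(int))
    traj = PseudotimeTrajectory([1, 2], [f"c{i}" for i in range(n)],
                                np.arange(n, dtype=float))
    with pytest.warns(UserWarning):                  # constant gene dropped
        prof = smooth_profiles(m, traj, span=0.5, transform="none")
    assert list(prof.index) == ["g0"]
    z = (counts[0] - counts[0].mean()) / counts[0].std()
    interior = slice(5, n - 5)
    assert np.max(np.abs(prof.loc["g0"].to_numpy()[interior] - z[interior])) \
        < 1e-6


def test_profiles_are_z_scaled():
    # smooth planted signals: the z-transform centring survives smoothing
    rng = np.random.default_rng(0)
    n = 60
    t = np.linspace(0, 1, n)
    counts = np.vstack([
        np.rint(10 + 8 * np.sin(2 * np.pi * t * f)
                + rng.normal(0, 0.5, n)).astype(int).clip(0)
        for f in (0.5, 1.0, 1.5, 2.0)])
    m = make_matrix(counts)
    traj = _linear_traj(n)
    prof = smooth_profiles(m, traj, span=0.3)
    assert np.abs(prof.mean(axis=1)).max() < 0.1
    # the pre-smoothing z-transform itself has sd exactly 1
    x = np.log2(counts + 1.0)
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    assert np.allclose(z.std(axis=1), 1.0)


def _two_group_profiles(n_each=20, n_t=40, seed=0):
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, n_t)
    up = np.vstack([t + rng.normal(0, 0.05, n_t) for _ in range(n_each)])
    down = np.vstack([1 - t + rng.normal(0, 0.05, n_t)
                      for _ in range(n_each)])
    prof = np.vstack([up, down])
    prof = (prof - prof.mean(axis=1, keepdims=True)) / prof.std(
        axis=1, keepdims=True)
    ids = [f"up{i}" for i in range(n_each)] + [f"dn{i}" for i in range(n_each)]
    return pd.DataFrame(prof, index=ids)


def test_som_separates_anticorrelated_groups_contiguously():
    prof = _two_group_profiles()
    som = som_1d(prof, n_nodes=10, seed=0, epochs=50)
    up_nodes = set(som.assignment[[g for g in prof.index if g.startswith("up")]])
    dn_nodes = set(som.assignment[[g for g in prof.index if g.startswith("dn")]])
    assert not (up_nodes & dn_nodes)
    # the two groups occupy non-interleaved node ranges
    assert max(up_nodes) < min(dn_nodes) or max(dn_nodes) < min(up_nodes)


def test_som_single_profile_and_errors():
    prof = _two_group_profiles(n_each=1)
    som = som_1d(prof.iloc[[0]], n_nodes=5, seed=0, epochs=5)
    assert len(som.assignment) == 1
    with pytest.raises(ValueError):
        som_1d(prof, n_nodes=1)


def test_som_topological_ordering_of_smooth_profiles():
    # planted smooth shifts: adjacent nodes more correlated than distant ones
    rng = np.random.default_rng(1)
    t = np.linspace(0, 1, 50)
    prof = np.vstack([np.exp(-0.5 * ((t - c) / 0.15) ** 2)
                      + rng.normal(0, 0.02, 50)
                      for c in np.repeat(np.linspace(0.1, 0.9, 30), 8)])
    prof = pd.DataFrame(prof)
    som = som_1d(prof, n_nodes=20, seed=0, epochs=80)
    node_prof = som.node_mean_profiles(prof)
    nodes = sorted(node_prof.index)
    adj, far = [], []
    for i, n1 in enumerate(nodes):
        for n2 in nodes[i + 1:]:
            r = np.corrcoef(node_prof.loc[n1], node_prof.loc[n2])[0, 1]
            if n2 - n1 == 1:
                adj.append(r)
            elif n2 - n1 >= 10:
                far.append(r)
    assert np.mean(adj) >= np.mean(far)


def test_som_seed_reproducible():
    prof = _two_group_profiles(seed=3)
    a = som_1d(prof, n_nodes=12, seed=7, epochs=30)
    b = som_1d(prof, n_nodes=12, seed=7, epochs=30)
    assert a.assignment.equals(b.assignment)


def _module_set(assignment, profiles, **kwargs):
    som = som_1d(profiles, n_nodes=kwargs.pop("n_nodes", 10), seed=0,
                 epochs=kwargs.pop("epochs", 40))
    return build_modules(som, profiles, **kwargs)


def test_build_modules_drops_sparse_nodes_and_merges_identical():
    prof = _two_group_profiles(n_each=30, seed=4)
    ms = _module_set(None, prof, n_nodes=8)
    # two anti-correlated groups cannot share a module (r < 0 << 0.9)
    mods = ms.gene_to_module()
    up_mods = set(mods[[g for g in mods.index if g.startswith("up")]])
    dn_mods = set(mods[[g for g in mods.index if g.startswith("dn")]])
    assert not (up_mods & dn_mods)
    # module gene sets partition the module-assigned genes
    all_genes = [g for mod in ms.modules for g in mod.genes]
    assert len(all_genes) == len(set(all_genes))


def test_build_modules_error_when_everything_sparse():
    prof = _two_group_profiles(n_each=2, seed=5)
    som = som_1d(prof, n_nodes=10, seed=0, epochs=20)
    with pytest.raises(ValueError):
        build_modules(som, prof, min_profiles=10)


@pytest.mark.parametrize("shape,expected", [
    (lambda t: np.exp(-4 * t), "early_decline"),
    (lambda t: 1 - np.exp(-6 * t), "early_plateau"),
    (lambda t: t ** 3, "late_rise"),
    (lambda t: np.sin(np.pi * np.minimum(t / 0.7, 1) / 2) * (t <= 0.7)
     + (t > 0.7) * np.cos(np.pi * (t - 0.7)), "rise_then_peak"),
])
def test_classify_module_dynamics_rules(shape, expected):
    t = np.linspace(0, 1, 60)
    p = shape(t)
    ms = ModuleSet(pd.Series(dtype=int), pd.DataFrame(),
                   [Module(1, [0], ["g"], p)])
    assert classify_module_dynamics(ms)[1] == expected


def test_classify_interior_peak():
    t = np.linspace(0, 1, 50)
    p = np.sin(np.pi * t / 0.7 / 2)
    p[t > 0.7] = np.sin(np.pi / 2) - 2.0 * (t[t > 0.7] - 0.7)
    ms = ModuleSet(pd.Series(dtype=int), pd.DataFrame(),
                   [Module(1, [0], ["g"], p)])
    assert classify_module_dynamics(ms)[1] == "rise_then_peak"
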