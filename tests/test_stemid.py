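import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from heartsc.cluster import kmedoids, pairwise_distance
from heartsc.qc import downsample, filter_cells, filter_genes
from heartsc.stemid import (build_lineage_tree, entropy, entropy_per_cell,
                            link_significance, project_cells, stemid_scores)
from heartsc.synthetic import simulate

from conftest import gradient_only_config, make_matrix


# ---- projection geometry ---------------------------------------------------

def _manual_clustering(counts, assignment, medoids):
    """A ClusterResult with hand-picked medoids (geometry under control)."""
    from heartsc.cluster import ClusterResult, DistanceMatrix
    m = make_matrix(np.array(counts))
    n = m.n_cells
    dm = DistanceMatrix(m.cell_ids, np.zeros((n, n)))
    cr = ClusterResult(pd.Series(assignment, index=m.cell_ids),
                       medoids, len(medoids), dm)
    return m, cr


def test_projection_closed_forms():
    # two genes; log2(15+1) = 4, so medoid profiles are (4, 0) and (0, 4).
    # cell "x" equals the other medoid -> t = 1; "mid" has log2(3+1) = 2
    # on both genes -> exact midpoint -> t = 0.5; a medoid itself -> t = 0.
    counts = [[15, 0, 0, 3],
              [0, 15, 15, 3]]
    m, cr = _manual_clustering(
        counts, {"c0": 1, "c1": 2, "c2": 1, "c3": 1},
        {1: "c0", 2: "c1"})
    proj = project_cells(m, cr)
    assert proj.loc["c0", "t"] == pytest.approx(0.0, abs=1e-12)
    assert proj.loc["c2", "t"] == pytest.approx(1.0, abs=1e-12)
    assert proj.loc["c3", "t"] == pytest.approx(0.5, abs=1e-12)
    assert proj.loc["c2", "target"] == 2


def test_projection_picks_maximal_link():
    # three clusters; the probe sits along the 1->3 direction
    counts = [[15, 0, 0, 7],
              [0, 15, 0, 0],
              [0, 0, 15, 7]]
    m, cr = _manual_clustering(
        counts, {"c0": 1, "c1": 2, "c2": 3, "c3": 1},
        {1: "c0", 2: "c1", 3: "c2"})
    proj = project_cells(m, cr)
    assert proj.loc["c3", "target"] == 3


def test_coincident_medoids_rejected():
    counts = [[15, 15, 0, 1],
              [0, 0, 15, 1]]
    m, cr = _manual_clustering(
        counts, {"c0": 1, "c1": 2, "c2": 1, "c3": 2},
        {1: "c0", 2: "c1"})     # identical medoid profiles
    with pytest.raises(ValueError):
        project_cells(m, cr)


# ---- link significance -----------------------------------------------------

def _proj_frame(rows):
    return pd.DataFrame(rows, columns=["cell_id", "cluster", "target", "t"]
                        ).set_index("cell_id")


def _fake_clustering(sizes):
    cells, labels = [], []
    for cl, n in sizes.items():
        for i in range(n):
            cells.append(f"k{cl}_{i}")
            labels.append(cl)
    assignment = pd.Series(labels, index=cells, name="cluster")
    medoids = {cl: f"k{cl}_0" for cl in sizes}
    from heartsc.cluster import ClusterResult, DistanceMatrix
    n = len(cells)
    dm = DistanceMatrix(np.array(cells, dtype=object), np.zeros((n, n)))
    return ClusterResult(assignment, medoids, len(sizes), dm)


def test_concentrated_link_matches_binomial_tail():
    # all 30 cells of cluster 1 choose link (1,2) out of 3 candidates
    cr = _fake_clustering({1: 30, 2: 1, 3: 1, 4: 1})
    rows = [(f"k1_{i}", 1, 2, 0.5) for i in range(30)]
    rows += [("k2_0", 2, 3, 0.1), ("k3_0", 3, 2, 0.1), ("k4_0", 4, 3, 0.1)]
    links = link_significance(_proj_frame(rows), cr, alpha=0.05)
    row = links[(links.cluster_i == 1) & (links.cluster_j == 2)].iloc[0]
    assert row.p == pytest.approx(float(binom.sf(29, 30, 1 / 3)), rel=1e-9)
    assert row.significant
    # a link with zero cells from either side has p = 1
    empty = links[(links.cluster_i == 1) & (links.cluster_j == 4)].iloc[0]
    assert empty.p == 1.0 and not empty.significant


def test_uniform_assignment_type1_controlled():
    rng = np.random.default_rng(0)
    k, n_i = 5, 40
    n_sig = 0
    n_links = 0
    for rep in range(200):
        rows = []
        for cl in range(1, k + 1):
            others = [j for j in range(1, k + 1) if j != cl]
            for i in range(n_i):
                rows.append((f"k{cl}_{i}", cl, rng.choice(others), 0.5))
        cr = _fake_clustering({cl: n_i for cl in range(1, k + 1)})
        links = link_significance(_proj_frame(rows), cr, alpha=0.05)
        n_sig += int(links.significant.sum())
        n_links += len(links)
    assert n_sig / n_links <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_links)


def test_two_clusters_trivially_significant_with_warning():
    cr = _fake_clustering({1: 3, 2: 3})
    rows = [(f"k1_{i}", 1, 2, 0.5) for i in range(3)]
    rows += [(f"k2_{i}", 2, 1, 0.5) for i in range(3)]
    with pytest.warns(UserWarning):
        links = link_significance(_proj_frame(rows), cr)
    assert links.significant.all()


def test_permutation_null_agrees_with_binomial():
    cr = _fake_clustering({1: 30, 2: 1, 3: 1, 4: 1})
    rows = [(f"k1_{i}", 1, 2, 0.5) for i in range(30)]
    rows += [("k2_0", 2, 3, 0.1), ("k3_0", 3, 2, 0.1), ("k4_0", 4, 3, 0.1)]
    links = link_significance(_proj_frame(rows), cr, method="permutation",
                              n_perm=2000, seed=1)
    row = links[(links.cluster_i == 1) & (links.cluster_j == 2)].iloc[0]
    assert row.significant          # overwhelming enrichment survives MC


# ---- entropy ---------------------------------------------------------------

def test_entropy_closed_forms():
    assert entropy(np.ones(50)) == pytest.approx(1.0)
    v = np.zeros(50)
    v[3] = 17
    assert entropy(v) == pytest.approx(0.0)
    expected = -(0.5 * np.log(0.5) + 2 * 0.25 * np.log(0.25)) / np.log(3)
    assert entropy(np.array([2, 1, 1])) == pytest.approx(expected)
    assert expected == pytest.approx(0.946, abs=5e-4)
    with pytest.raises(ValueError):
        entropy(np.zeros(5))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.lists(st.integers(min_value=0, max_value=50), min_size=3,
                max_size=30))
def test_entropy_decreases_when_mass_concentrates(xs):
    x = np.array(xs)
    low = [i for i in np.argsort(x) if x[i] > 0]
    if len(low) < 2:
        return
    src, dst = low[0], int(np.argmax(x))
    if src == dst:
        return
    y = x.copy()
    y[src] -= 1
    y[dst] += 1
    if y.sum() == 0:
        return
    assert entropy(y) <= entropy(x) + 1e-12


def test_entropy_expectation_invariant_to_downsampling_seed():
    rng = np.random.default_rng(3)
    m = make_matrix(rng.integers(0, 40, (60, 1)) * 20)
    e1 = [entropy_per_cell(downsample(m, 3500, seed=s)).iloc[0]
          for s in range(100)]
    e2 = [entropy_per_cell(downsample(m, 3500, seed=s)).iloc[0]
          for s in range(100, 200)]
    se = np.sqrt(np.var(e1) / 100 + np.var(e2) / 100)
    assert abs(np.mean(e1) - np.mean(e2)) < 2 * se + 1e-9


# ---- scores and the planted-path property ----------------------------------

def test_stemid_score_is_links_times_median_entropy():
    links = pd.DataFrame({
        "cluster_i": [1, 1, 2], "cluster_j": [2, 3, 3],
        "n_cells": [5, 5, 5], "p": [0.001] * 3, "padj": [0.003] * 3,
        "significant": [True, True, False]})
    cr = _fake_clustering({1: 3, 2: 3, 3: 3})
    ent = pd.Series(0.8, index=cr.assignment.index)
    scores = stemid_scores(links, ent, cr)
    assert scores[1] == pytest.approx(2 * 0.8)      # two significant links
    assert scores[2] == pytest.approx(1 * 0.8)
    assert scores[3] == pytest.approx(0.8)
    links.loc[:, "significant"] = False
    assert (stemid_scores(links, ent, cr) == 0).all()


def test_planted_path_links_recovered():
    """A -> B -> C -> D gradient: the three true adjacencies are found and
    no false gradient link appears, in >= 90% of seeded runs."""
    wins = 0
    runs = 30
    for seed in range(runs):
        # 60 cells per state, the default scene's post-filter occupancy
        cfg = gradient_only_config(seed, n_cells=60, n_genes=800)
        m, ann, gt = simulate(cfg)
        md = filter_genes(downsample(filter_cells(m), seed=seed + 1))
        cr = kmedoids(pairwise_distance(md), k=4, seed=seed + 2)
        tree = build_lineage_tree(md, cr, seed=seed + 3)
        # map clusters to gradient position via ground truth majority
        pos = {}
        for cl in cr.medoids:
            types = gt.cell_type[cr.cells_of(cl)]
            pos[cl] = types.mode()[0]
        order = ["cm_remote", "cm_intermediate1", "cm_intermediate2",
                 "cm_border"]
        by_type = {t: cl for cl, t in pos.items()}
        if len(by_type) < 4:
            continue
        true_links = {tuple(sorted((by_type[a], by_type[b])))
                      for a, b in zip(order[:-1], order[1:])}
        got = {tuple(sorted((int(r.cluster_i), int(r.cluster_j))))
               for r in tree.links[tree.links.significant].itertuples()}
        if got == true_links:
            wins += 1
    assert wins >= 0.9 * runs
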