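"""Pseudotime ordering along a cluster path and SOM co-expression modules.

Cells assigned to the links of a chosen cluster path (e.g. remote ->
intermediate -> intermediate -> border) are assembled in pseudo-temporal
order by their projection coordinate.  Each gene's z-transformed
expression profile along that order is smoothed by local regression and
the profiles are topologically ordered on a one-dimensional
self-organizing map; well-populated neighbouring nodes with near-identical
average profiles are merged into co-expression modules, which are then
labelled by the temporal shape of their mean profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .cluster import transform_counts
from .io_counts import CountMatrix
from .stemid import LineageTree

__all__ = [
    "PseudotimeTrajectory", "Module", "ModuleSet", "order_cells",
    "som_gene_filter", "smooth_profiles", "som_1d", "SOMResult",
    "build_modules", "classify_module_dynamics",
]


@dataclass
class PseudotimeTrajectory:
    path: list                       # ordered cluster ids
    ordered_cells: list              # cell ids, pseudotime rank = position
    coords: np.ndarray               # segment index + within-link coordinate
    profiles: pd.DataFrame | None = None   # genes x ordered cells (smoothed z)


@dataclass
class Module:
    module_id: int
    nodes: list
    genes: list
    mean_profile: np.ndarray


@dataclass
class ModuleSet:
    node_assignment: pd.Series       # gene -> SOM node
    node_profiles: pd.DataFrame      # retained node -> mean profile (rows)
    modules: list = field(default_factory=list)

    def gene_to_module(self) -> pd.Series:
        out = {}
        for mod in self.modules:
            for g in mod.genes:
                out[g] = mod.module_id
        return pd.Series(out, name="module")


def order_cells(tree: LineageTree, path: list) -> PseudotimeTrajectory:
    """Assemble cells on the path's links in pseudo-temporal order.

    For segment (a, b), cells of cluster a on link (a, b) keep their
    projection coordinate t; cells of cluster b on the same link enter at
    1 - t so the coordinate always increases in the direction of travel.
    Segments are concatenated in path order; ties break by cell id.
    """
    if len(path) < 2:
        raise ValueError("path needs at least two clusters")
    proj = tree.projections
    ordered, coords = [], []
    for s, (a, b) in enumerate(zip(path[:-1], path[1:])):
        if not tree.has_link(a, b):
            raise ValueError(f"clusters {a} and {b} are not linked")
        on_link = proj[((proj.cluster == a) & (proj.target == b)) |
                       ((proj.cluster == b) & (proj.target == a))]
        seg = []
        for cell, row in on_link.iterrows():
            t = row.t if row.cluster == a else 1.0 - row.t
            seg.append((t, cell))
        for t, cell in sorted(seg):
            if cell not in ordered:          # each cell appears once
                ordered.append(cell)
                coords.append(s + t)
    return PseudotimeTrajectory(list(path), ordered, np.array(coords))


def som_gene_filter(m: CountMatrix, cells=None, min_count: int = 2) -> list:
    """Genes with >= ``min_count`` transcripts in at least one cell."""
    sub = m.drop_spikeins()
    if cells is not None:
        pos = {c: i for i, c in enumerate(sub.cell_ids)}
        sub = sub.subset_cells(np.array([pos[c] for c in cells]))
    keep = (sub.counts >= min_count).any(axis=1)
    return [g for g, k in zip(sub.gene_ids, keep) if k]


def smooth_profiles(m: CountMatrix, traj: PseudotimeTrajectory,
                    span: float = 0.3, min_count: int = 2,
                    transform: str = "log2p1") -> pd.DataFrame:
    """Locally-smoothed z-profile of each gene along the trajectory.

    Per gene: z-transform the (log) expression over the trajectory cells,
    then locally weighted linear regression over pseudotime rank with
    fractional window ``span``, evaluated at every ordered cell.
    Zero-variance genes are excluded with a warning.
    """
    if len(traj.ordered_cells) < 10:
        raise ValueError("trajectory too short for profile smoothing")
    sub = m.drop_spikeins()
    pos = {c: i for i, c in enumerate(sub.cell_ids)}
    cols = np.array([pos[c] for c in traj.ordered_cells])
    genes = som_gene_filter(m, cells=traj.ordered_cells, min_count=min_count)
    gpos = {g: i for i, g in enumerate(sub.gene_ids)}
    x = transform_counts(sub, transform)[:, cols]
    ranks = np.arange(len(cols), dtype=float)

    rows, kept = [], []
    n_const = 0
    for g in genes:
        v = x[gpos[g]]
        sd = v.std()
        if sd == 0:
            n_const += 1
            continue
        z = (v - v.mean()) / sd
        sm = lowess(z, ranks, frac=span, return_sorted=False,
                    delta=0.01 * len(ranks))
        rows.append(sm)
        kept.append(g)
    if n_const:
        warnings.warn(f"{n_const} zero-variance genes excluded from smoothing")
    if not rows:
        raise ValueError("no gene with variance along the trajectory")
    prof = pd.DataFrame(np.vstack(rows), index=kept,
                        columns=traj.ordered_cells)
    traj.profiles = prof
    return prof


@dataclass
class SOMResult:
    assignment: pd.Series        # gene -> node index
    weights: np.ndarray          # n_nodes x n_timepoints
    n_nodes: int

    def node_mean_profiles(self, profiles: pd.DataFrame) -> pd.DataFrame:
        """Average member profile per populated node."""
        rows, idx = [], []
        for node, genes in self.assignment.groupby(self.assignment):
            rows.append(profiles.loc[genes.index].mean(axis=0).to_numpy())
            idx.append(node)
        return pd.DataFrame(np.vstack(rows), index=idx)


def som_1d(profiles: pd.DataFrame, n_nodes: int = 1000, seed: int = 0,
           epochs: int = 100, radius_start: float | None = None,
           radius_end: float = 1.0, matching: str = "correlation") -> SOMResult:
    """Topologically order profiles on a 1-D self-organizing map.

    Batch-update SOM on a chain of ``n_nodes`` nodes: per epoch every
    profile is assigned to its best-matching node and each node moves to
    the Gaussian-neighbourhood-weighted mean of the assigned profiles;
    the neighbourhood radius decays exponentially from ``radius_start``
    (default n_nodes/10) to ``radius_end``.

    With ``matching='correlation'`` (default) profiles are centred and
    scaled to unit norm before matching, so nodes group genes by the
    *shape* of their temporal profile rather than its amplitude —
    consistent with the correlation-based module merging downstream.
    ``matching='euclidean'`` uses the raw profiles.

    Node weights are initialised as window averages over profiles sorted
    by the position of their maximum (a topologically sensible start);
    deterministic given the seed, which only jitters the initial weights.
    """
    if n_nodes < 2:
        raise ValueError("need at least two SOM nodes")
    P = profiles.to_numpy(dtype=float)
    n_prof, dim = P.shape
    if n_prof < 1:
        raise ValueError("no profiles to map")
    if matching == "correlation":
        P = P - P.mean(axis=1, keepdims=True)
        nrm = np.linalg.norm(P, axis=1, keepdims=True)
        P = P / np.where(nrm > 0, nrm, 1.0)
    elif matching != "euclidean":
        raise ValueError(f"unknown matching: {matching}")
    rng = np.random.default_rng(seed)
    order = np.argsort(P.argmax(axis=1), kind="stable")
    edges = np.linspace(0, n_prof, n_nodes + 1).astype(int)
    W = np.vstack([P[order][max(0, a):max(a + 1, b)].mean(axis=0)
                   for a, b in zip(edges[:-1], edges[1:])])
    W = W + rng.normal(0.0, 1e-3, size=(n_nodes, dim))
    if radius_start is None:
        radius_start = max(1.0, n_nodes / 10.0)
    node_pos = np.arange(n_nodes, dtype=float)

    p_sq = (P ** 2).sum(axis=1)[:, None]
    for e in range(epochs):
        sigma = radius_start * (radius_end / radius_start) ** (
            e / max(1, epochs - 1))
        d2 = p_sq + (W ** 2).sum(axis=1)[None, :] - 2.0 * P @ W.T
        bmu = np.argmin(d2, axis=1)
        H = np.exp(-0.5 * ((node_pos[:, None] - node_pos[None, :]) / sigma) ** 2)
        S = np.zeros((n_nodes, dim))
        np.add.at(S, bmu, P)
        cnt = np.bincount(bmu, minlength=n_nodes).astype(float)
        num = H @ S
        den = (H @ cnt)[:, None]
        good = den[:, 0] > 1e-12
        W[good] = num[good] / den[good]

    d2 = p_sq + (W ** 2).sum(axis=1)[None, :] - 2.0 * P @ W.T
    bmu = np.argmin(d2, axis=1)
    return SOMResult(pd.Series(bmu, index=profiles.index, name="node"),
                     W, n_nodes)


def build_modules(som: SOMResult, profiles: pd.DataFrame,
                  min_profiles: int = 3, merge_r: float = 0.9) -> ModuleSet:
    """Merge well-populated neighbouring SOM nodes into co-expression modules.

    Nodes with <= ``min_profiles`` assigned genes are dropped; runs of
    adjacent retained nodes merge while the next node's mean profile
    correlates at Pearson r > ``merge_r`` with the mean profile of the
    module grown so far (recomputed after each merge).  Testing against
    the running module mean rather than only the previous node prevents a
    single intermediate node from bridging two distinct expression
    programmes.  Module mean profiles are recomputed after merging.
    """
    counts = som.assignment.value_counts()
    retained = sorted(int(n) for n in counts.index if counts[n] > min_profiles)
    if not retained:
        raise ValueError("no SOM node has more than "
                         f"{min_profiles} assigned profiles")
    node_prof = som.node_mean_profiles(profiles).loc[retained]

    def genes_of(nodes: list[int]) -> list:
        return list(som.assignment.index[som.assignment.isin(nodes)])

    groups: list[list[int]] = [[retained[0]]]
    run_mean = node_prof.loc[retained[0]].to_numpy()
    for node in retained[1:]:
        r = np.corrcoef(run_mean, node_prof.loc[node])[0, 1]
        if r > merge_r:
            groups[-1].append(node)
            run_mean = profiles.loc[genes_of(groups[-1])].mean(axis=0).to_numpy()
        else:
            groups.append([node])
            run_mean = node_prof.loc[node].to_numpy()

    modules = []
    for mid, nodes in enumerate(groups, start=1):
        genes = [g for g in som.assignment.index
                 if som.assignment[g] in nodes]
        mean_prof = profiles.loc[genes].mean(axis=0).to_numpy()
        modules.append(Module(mid, nodes, genes, mean_prof))
    return ModuleSet(som.assignment.copy(), node_prof, modules)


def classify_module_dynamics(ms: ModuleSet) -> dict:
    """Label each module's temporal shape.

    Rule-based on the mean profile: position of the maximum, net change,
    early attainment of the plateau level, and an interior-peak test
    (maximum strictly before the final decile with a terminal decline
    implies ``rise_then_peak``).
    """
    labels = {}
    for mod in ms.modules:
        p = np.asarray(mod.mean_profile, dtype=float)
        n = len(p)
        rng_ = p.max() - p.min()
        if rng_ <= 0:
            labels[mod.module_id] = "other"
            continue
        frac_max = float(np.argmax(p)) / (n - 1)
        net = p[-1] - p[0]
        early_val = p[int(round(0.3 * (n - 1)))]
        terminal_drop = (p.max() - p[-1]) / rng_
        initial_rise = (p.max() - p[0]) / rng_
        if frac_max <= 0.1 and net < 0:
            labels[mod.module_id] = "early_decline"
        elif frac_max < 0.9 and terminal_drop > 0.25 and initial_rise > 0.25:
            labels[mod.module_id] = "rise_then_peak"
        elif net > 0 and (early_val - p.min()) / rng_ >= 0.7:
            labels[mod.module_id] = "early_plateau"
        elif net > 0 and frac_max >= 0.9:
            labels[mod.module_id] = "late_rise"
        else:
            labels[mod.module_id] = "other"
    return labels
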