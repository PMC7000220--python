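"""Correlation-distance k-medoids clustering of single-cell transcriptomes.

Cells are compared by d(i, j) = 1 - Pearson correlation of their
(log-transformed) expression vectors, and partitioned with PAM-style
k-medoids (greedy build + swap) on the precomputed distance matrix.
Cluster count can be chosen by a within-cluster dispersion saturation
rule, and clusters are annotated with cell types via marker-gene panels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .io_counts import CountMatrix

__all__ = [
    "DistanceMatrix", "ClusterResult", "pairwise_distance", "kmedoids",
    "select_k", "annotate_clusters", "summarize_by_cluster",
    "library_composition", "embed_2d",
]


@dataclass
class DistanceMatrix:
    cell_ids: np.ndarray
    d: np.ndarray          # symmetric, zero diagonal, entries in [0, 2]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.cell_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match cell_ids")


@dataclass
class ClusterResult:
    assignment: pd.Series      # cell_id -> cluster id (1..k)
    medoids: dict              # cluster id -> cell_id
    k: int
    dm: DistanceMatrix

    def cells_of(self, cluster: int) -> np.ndarray:
        return self.assignment.index[self.assignment == cluster].to_numpy()


def transform_counts(m: CountMatrix, transform: str = "log2p1") -> np.ndarray:
    """Genes x cells value matrix used for distances and projections."""
    x = m.drop_spikeins().counts.astype(float)
    if transform == "log2p1":
        return np.log2(x + 1.0)
    if transform == "none":
        return x
    raise ValueError(f"unknown transform: {transform}")


def pairwise_distance(m: CountMatrix,
                      transform: str = "log2p1") -> DistanceMatrix:
    """All pairwise 1 - Pearson correlation distances between cells."""
    if m.n_cells < 2:
        raise ValueError("need at least two cells")
    x = transform_counts(m, transform)
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = m.cell_ids[int(np.argmax(sd == 0))]
        raise ValueError(f"cell {bad!r} has a constant expression vector; "
                         "correlation undefined")
    corr = np.corrcoef(x, rowvar=False)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return DistanceMatrix(m.cell_ids.copy(), d)


def _pam_objective(d: np.ndarray, medoids: np.ndarray) -> float:
    return float(d[:, medoids].min(axis=1).sum())


def _pam_build(d: np.ndarray, k: int) -> np.ndarray:
    """Greedy BUILD initialization: repeatedly add the best new medoid."""
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=1)))]
    nearest = d[:, medoids[0]].copy()
    for _ in range(k - 1):
        gain = np.minimum(d, nearest[:, None]).sum(axis=0)
        gain[medoids] = np.inf
        h = int(np.argmin(gain))
        medoids.append(h)
        nearest = np.minimum(nearest, d[:, h])
    return np.array(sorted(medoids))


def _pam_swap(d: np.ndarray, medoids: np.ndarray,
              max_iter: int = 100) -> tuple[np.ndarray, float]:
    medoids = medoids.copy()
    obj = _pam_objective(d, medoids)
    for _ in range(max_iter):
        dist_to_m = d[:, medoids]                       # n x k
        order = np.argsort(dist_to_m, axis=1)
        nearest = dist_to_m[np.arange(len(d)), order[:, 0]]
        second = dist_to_m[np.arange(len(d)), order[:, 1]]
        nearest_m = order[:, 0]
        best = (obj, None, None)
        for mi in range(len(medoids)):
            base = np.where(nearest_m == mi, second, nearest)
            cand = np.minimum(d, base[:, None]).sum(axis=0)
            cand[medoids] = np.inf
            h = int(np.argmin(cand))
            if cand[h] < best[0] - 1e-12:
                best = (float(cand[h]), mi, h)
        if best[1] is None:
            break
        new_obj, mi, h = best
        assert new_obj <= obj + 1e-9, "swap must not increase the objective"
        medoids[mi] = h
        obj = new_obj
    return np.sort(medoids), obj


def kmedoids(dm: DistanceMatrix, k: int, seed: int = 0,
             n_restarts: int = 3) -> ClusterResult:
    """PAM k-medoids: greedy build + random restarts, then swap refinement."""
    n = len(dm.cell_ids)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    rng = np.random.default_rng(seed)
    best_medoids, best_obj = None, np.inf
    for r in range(max(1, n_restarts)):
        init = (_pam_build(dm.d, k) if r == 0
                else np.sort(rng.choice(n, size=k, replace=False)))
        medoids, obj = _pam_swap(dm.d, init)
        if obj < best_obj - 1e-12:
            best_medoids, best_obj = medoids, obj
    labels = np.argmin(dm.d[:, best_medoids], axis=1)
    labels[best_medoids] = np.arange(k)      # each medoid stays in its cluster
    assignment = pd.Series(labels + 1, index=dm.cell_ids, name="cluster")
    medoid_map = {i + 1: dm.cell_ids[m] for i, m in enumerate(best_medoids)}
    return ClusterResult(assignment, medoid_map, k, dm)


def select_k(dm: DistanceMatrix, k_max: int = 20, seed: int = 0,
             threshold: float = 0.05, n_restarts: int = 3) -> int:
    """Smallest k after which within-cluster dispersion stops improving.

    Returns the smallest k with (W(k) - W(k+1)) / W(2) < ``threshold``,
    where W is the total distance to assigned medoids; ``k_max`` if the
    decrease never saturates.  Normalizing by the k = 2 baseline (rather
    than by W(k) itself) keeps the rule scale-free: once the true
    structure is resolved, further splits shave a large share of an
    already tiny residual, which a W(k)-relative rule mistakes for
    ongoing improvement.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    k_max = min(k_max, len(dm.cell_ids))
    w = {}
    for k in range(2, k_max + 2):
        if k > len(dm.cell_ids):
            break
        cr = kmedoids(dm, k, seed=seed, n_restarts=n_restarts)
        w[k] = _pam_objective(dm.d, np.array(
            [int(np.where(dm.cell_ids == cid)[0][0])
             for cid in cr.medoids.values()]))
    baseline = w.get(2, 0.0)
    if baseline <= 0:
        return 2
    for k in range(2, k_max + 1):
        if k + 1 not in w:
            break
        if w[k] <= 0:
            return k
        if (w[k] - w[k + 1]) / baseline < threshold:
            return k
    return k_max


def annotate_clusters(m: CountMatrix, cr: ClusterResult,
                      markers: dict) -> dict:
    """Label clusters by the marker panel with highest mean scaled expression.

    Expression is z-scaled per gene (log2 counts across cells) so panels
    of differently expressed genes are comparable; a cluster with zero
    raw marker expression is labelled ``unassigned``.
    """
    if not markers:
        raise ValueError("empty marker map")
    x = transform_counts(m)
    genes = list(m.drop_spikeins().gene_ids)
    gene_pos = {g: i for i, g in enumerate(genes)}
    sd = x.std(axis=1)
    z = (x - x.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)[:, None]
    cell_pos = {c: i for i, c in enumerate(m.cell_ids)}

    panel_idx = {}
    for ctype, gset in markers.items():
        present = [gene_pos[g] for g in gset if g in gene_pos]
        missing = [g for g in gset if g not in gene_pos]
        if missing:
            warnings.warn(f"markers for {ctype!r} missing from matrix: "
                          f"{missing}")
        panel_idx[ctype] = present

    labels = {}
    for cl in sorted(set(cr.assignment)):
        cols = [cell_pos[c] for c in cr.cells_of(cl)]
        raw_total = 0
        scores = {}
        for ctype, idx in panel_idx.items():
            if not idx:
                continue
            raw_total += m.counts[np.ix_(idx, cols)].sum()
            scores[ctype] = float(z[np.ix_(idx, cols)].mean())
        if not scores or raw_total == 0:
            labels[cl] = "unassigned"
            continue
        best = max(scores.values())
        winners = sorted(t for t, s in scores.items() if s == best)
        if len(winners) > 1:
            warnings.warn(f"cluster {cl}: marker score tie between "
                          f"{winners}; choosing {winners[0]!r}")
        labels[cl] = winners[0]
    return labels


def summarize_by_cluster(ann: pd.DataFrame, cr: ClusterResult,
                         field: str) -> pd.DataFrame:
    """Per-cluster arithmetic mean of a numeric annotation field."""
    if field not in ann.columns:
        raise KeyError(f"annotation field {field!r} missing")
    ann = ann.set_index("cell_id") if "cell_id" in ann.columns else ann
    vals = pd.to_numeric(ann[field])
    rows = []
    for cl in sorted(set(cr.assignment)):
        cells = [c for c in cr.cells_of(cl) if c in vals.index]
        rows.append({"cluster": cl, "mean": float(vals[cells].mean()),
                     "n": len(cells)})
    return pd.DataFrame(rows).set_index("cluster")


def library_composition(ann: pd.DataFrame, cr: ClusterResult,
                        alpha: float = 0.01) -> pd.DataFrame:
    """Cluster x library cell counts; warns on plate-specific clustering."""
    ann = ann.set_index("cell_id") if "cell_id" in ann.columns else ann
    lib = ann["library_id"].reindex(cr.assignment.index)
    table = pd.crosstab(cr.assignment, lib)
    if table.shape[0] > 1 and table.shape[1] > 1:
        p = chi2_contingency(table.to_numpy() + 1)[1]   # +1: sparse cells
        if p < alpha:
            warnings.warn(f"cluster composition differs between libraries "
                          f"(chi-square p={p:.2g})")
    return table


def embed_2d(dm: DistanceMatrix, seed: int = 0, backend=None) -> np.ndarray:
    """2-D visualization hook (t-SNE on the precomputed distances).

    Carries no analytical weight; a custom ``backend(d) -> (n, 2)`` can
    be supplied.
    """
    if backend is not None:
        return np.asarray(backend(dm.d))
    from sklearn.manifold import TSNE
    n = len(dm.cell_ids)
    tsne = TSNE(n_components=2, metric="precomputed", init="random",
                random_state=seed, perplexity=min(30.0, max(2.0, n / 4)))
    return tsne.fit_transform(dm.d)
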