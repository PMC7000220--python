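"""Lineage-tree inference and stemness scoring on clustered transcriptomes.

Each cell is projected onto the straight lines connecting its own cluster
medoid with every other cluster medoid (in the same transformed expression
space used for distances); the link with the maximal projection coordinate
claims the cell.  Links enriched for cells beyond what uniform assignment
would produce are called significant.  A cluster's stemness score is the
number of significant links touching it multiplied by the median
transcriptome entropy of its cells: progenitor-like populations sit at
junctions of the tree and spread their transcriptome over many genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .cluster import ClusterResult, transform_counts
from .io_counts import CountMatrix

__all__ = [
    "LineageTree", "project_cells", "link_significance", "entropy",
    "entropy_per_cell", "stemid_scores", "build_lineage_tree",
]


@dataclass
class LineageTree:
    projections: pd.DataFrame   # index cell_id: cluster, target, t
    links: pd.DataFrame         # cluster_i, cluster_j, n_cells, p, padj, significant
    entropy: pd.Series          # cell_id -> [0, 1]
    stemid_score: pd.Series     # cluster -> score

    def has_link(self, i: int, j: int) -> bool:
        a, b = min(i, j), max(i, j)
        sel = (self.links.cluster_i == a) & (self.links.cluster_j == b)
        return bool(sel.any())

    def to_edge_table(self) -> pd.DataFrame:
        return self.links.copy()


def project_cells(m: CountMatrix, cr: ClusterResult,
                  transform: str = "log2p1") -> pd.DataFrame:
    """Assign each cell to its maximal-projection inter-medoid link.

    For cell x in cluster i with medoid profile m_i, the projection onto
    the link towards cluster j is t = (x - m_i).(m_j - m_i) / |m_j - m_i|^2
    (0 at the own medoid, 1 at the other medoid, not clamped).  Returns a
    frame indexed by cell id with columns ``cluster``, ``target``, ``t``.
    """
    x = transform_counts(m, transform)
    cell_pos = {c: i for i, c in enumerate(m.cell_ids)}
    clusters = sorted(cr.medoids)
    medoid_prof = {cl: x[:, cell_pos[cr.medoids[cl]]] for cl in clusters}
    for a_i, a in enumerate(clusters):
        for b in clusters[a_i + 1:]:
            if np.allclose(medoid_prof[a], medoid_prof[b]):
                raise ValueError(f"medoids of clusters {a} and {b} coincide")

    rows = []
    for cell, cl in cr.assignment.items():
        xi = x[:, cell_pos[cell]]
        mi = medoid_prof[cl]
        best_t, best_j = -np.inf, None
        for j in clusters:
            if j == cl:
                continue
            v = medoid_prof[j] - mi
            t = float((xi - mi) @ v / (v @ v))
            if t > best_t + 1e-15:
                best_t, best_j = t, j
        rows.append((cell, cl, best_j, best_t))
    return pd.DataFrame(rows, columns=["cell_id", "cluster", "target", "t"]
                        ).set_index("cell_id")


def link_significance(projections: pd.DataFrame, cr: ClusterResult,
                      alpha: float = 0.05, method: str = "binomial",
                      n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Test each inter-cluster link for cell enrichment.

    Under the null every cell of a cluster picks one of the k-1 candidate
    links uniformly, so the count on link (i, j) seen from i is
    Binomial(n_i, 1/(k-1)); one-sided enrichment p-values are BH-corrected
    across all directed tests and a link is significant if enriched from
    either endpoint.  ``method='permutation'`` replaces the binomial tail
    by a Monte-Carlo null of uniformly re-drawn link choices.
    """
    clusters = sorted(cr.medoids)
    k = len(clusters)
    pairs = [(a, b) for i, a in enumerate(clusters) for b in clusters[i + 1:]]
    counts = {}
    for cell, row in projections.iterrows():
        key = (min(row.cluster, row.target), max(row.cluster, row.target))
        counts.setdefault(key, {})
        counts[key][row.cluster] = counts[key].get(row.cluster, 0) + 1
    sizes = cr.assignment.value_counts().to_dict()

    if k < 3:
        warnings.warn("fewer than 3 clusters: no null alternative, "
                      "all links reported significant")
        rows = [dict(cluster_i=a, cluster_j=b,
                     n_cells=sum(counts.get((a, b), {}).values()),
                     p=0.0, padj=0.0, significant=True) for a, b in pairs]
        return pd.DataFrame(rows)

    rng = np.random.default_rng(seed)
    directed = []      # (pair, origin, count, n_origin, p)
    for a, b in pairs:
        for origin, other in ((a, b), (b, a)):
            c = counts.get((a, b), {}).get(origin, 0)
            n = sizes.get(origin, 0)
            if n == 0:
                p = 1.0
            elif method == "binomial":
                p = float(binom.sf(c - 1, n, 1.0 / (k - 1)))
            elif method == "permutation":
                null = rng.binomial(n, 1.0 / (k - 1), size=n_perm)
                p = float((null >= c).sum() + 1) / (n_perm + 1)
            else:
                raise ValueError(f"unknown method: {method}")
            directed.append([(a, b), origin, c, n, p])

    pvals = np.array([d[4] for d in directed])
    padj = multipletests(pvals, method="fdr_bh")[1]
    rows = []
    for a, b in pairs:
        idx = [i for i, d in enumerate(directed) if d[0] == (a, b)]
        p_link = float(min(pvals[i] for i in idx))
        padj_link = float(min(padj[i] for i in idx))
        rows.append(dict(
            cluster_i=a, cluster_j=b,
            n_cells=sum(counts.get((a, b), {}).values()),
            p=p_link, padj=padj_link, significant=bool(padj_link < alpha)))
    return pd.DataFrame(rows)


def entropy(counts_vec: np.ndarray, n_genes: int | None = None) -> float:
    """Normalized Shannon entropy of one cell's transcriptome, in [0, 1].

    E = -sum(p_g ln p_g) / ln(G) over expressed genes, with G the number
    of genes in the filtered matrix, so a uniform transcriptome scores 1
    and a single expressed gene scores 0.
    """
    x = np.asarray(counts_vec, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("entropy undefined for an all-zero cell")
    G = len(x) if n_genes is None else n_genes
    if G < 2:
        raise ValueError("need at least two genes")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum() / np.log(G))


def entropy_per_cell(m: CountMatrix) -> pd.Series:
    sub = m.drop_spikeins()
    vals = [entropy(sub.counts[:, j]) for j in range(sub.n_cells)]
    return pd.Series(vals, index=sub.cell_ids, name="entropy")


def stemid_scores(links: pd.DataFrame, cell_entropy: pd.Series,
                  cr: ClusterResult) -> pd.Series:
    """Per cluster: (# significant links touching it) x median cell entropy."""
    scores = {}
    for cl in sorted(cr.medoids):
        n_sig = int(((links.significant) &
                     ((links.cluster_i == cl) | (links.cluster_j == cl))).sum())
        cells = cr.cells_of(cl)
        med = float(cell_entropy[cells].median()) if len(cells) else 0.0
        scores[cl] = n_sig * med
    return pd.Series(scores, name="stemid_score")


def build_lineage_tree(m: CountMatrix, cr: ClusterResult,
                       alpha: float = 0.05, method: str = "binomial",
                       seed: int = 0) -> LineageTree:
    """Convenience: projections + link tests + entropy + stemness scores."""
    proj = project_cells(m, cr)
    links = link_significance(proj, cr, alpha=alpha, method=method, seed=seed)
    ent = entropy_per_cell(m)
    scores = stemid_scores(links, ent, cr)
    return LineageTree(proj, links, ent, scores)
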