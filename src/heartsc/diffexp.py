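"""Negative-binomial differential expression between cell groups.

The test follows the exact-style NB comparison used for small-sample
count data: a smooth mean-variance trend is fitted across genes (local
regression on the log-log scale with a Poisson floor), each gene's two
group totals are modelled as NB draws with pooled mean split by group
size, and the two-sided p-value sums the probabilities of all outcomes
at most as likely as the observed split.  P-values are
Benjamini-Hochberg corrected.  Input matrices are assumed downsampled to
equal per-cell totals, i.e. unit size factors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import nbinom, norm, poisson
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .io_counts import CountMatrix

__all__ = ["fit_dispersion", "diffexp", "count_de", "benjamini_hochberg"]

_EXACT_TOTAL_CAP = 200_000   # above this, use a normal approximation


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone, clipped to [0, 1])."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def fit_dispersion(m: CountMatrix, groups: tuple) -> "callable":
    """Fit a smooth monotone-ish mean -> variance function across genes.

    Per-gene means over all cells of both groups and within-group pooled
    variances feed a lowess regression of log variance on log mean; the
    returned function interpolates that trend and never falls below the
    Poisson floor (variance >= mean).
    """
    sub = m.drop_spikeins()
    pos = {c: i for i, c in enumerate(sub.cell_ids)}
    idx = [np.array([pos[c] for c in g]) for g in groups]
    if any(len(i) < 2 for i in idx):
        raise ValueError("need at least 2 cells per group")
    x = sub.counts.astype(float)
    all_cols = np.concatenate(idx)
    mean = x[:, all_cols].mean(axis=1)
    dof, ss = 0.0, np.zeros(sub.n_genes)
    for cols in idx:
        ss += x[:, cols].var(axis=1, ddof=1) * (len(cols) - 1)
        dof += len(cols) - 1
    var = ss / dof

    ok = (mean > 0) & (var > 0)
    if ok.sum() < 50:
        raise ValueError("fewer than 50 informative genes; "
                         "mean-variance fit unreliable")
    lx, ly = np.log(mean[ok]), np.log(var[ok])
    fit = lowess(ly, lx, frac=0.5, return_sorted=True)
    fx, fy = fit[:, 0], fit[:, 1]

    def var_of_mean(mu):
        mu = np.asarray(mu, dtype=float)
        out = np.exp(np.interp(np.log(np.maximum(mu, 1e-12)), fx, fy))
        return np.maximum(out, mu)          # Poisson floor

    return var_of_mean


def _group_total_logpmf(k: np.ndarray, mean: float, var: float) -> np.ndarray:
    """log PMF of a group total with NB(mean, var), Poisson if var <= mean."""
    if var <= mean * (1.0 + 1e-9):
        return poisson.logpmf(k, mean)
    r = mean ** 2 / (var - mean)
    p = r / (r + mean)
    return nbinom.logpmf(k, r, p)


def _exact_nb_p(kA: int, kB: int, nA: int, nB: int, mu: float,
                var_fn) -> float:
    """Two-sided exact p: total probability of splits as or less likely."""
    kS = kA + kB
    if kS == 0:
        return 1.0
    v = float(var_fn(mu))
    meanA, varA = nA * mu, nA * v
    meanB, varB = nB * mu, nB * v
    if kS > _EXACT_TOTAL_CAP:
        # normal approximation to the conditional split A | A+B = kS
        exp_a = meanA + varA / (varA + varB) * (kS - meanA - meanB)
        sd = max(np.sqrt(varA * varB / (varA + varB)), 1.0)
        z = (kA - exp_a) / sd
        return float(min(1.0, 2.0 * norm.sf(abs(z))))
    a = np.arange(kS + 1)
    logp = (_group_total_logpmf(a, meanA, varA) +
            _group_total_logpmf(kS - a, meanB, varB))
    logp_obs = logp[kA]
    mx = logp.max()
    w = np.exp(logp - mx)
    denom = w.sum()
    if denom <= 0 or not np.isfinite(denom):
        return 1.0
    num = w[logp <= logp_obs + 1e-9].sum()
    return float(min(1.0, num / denom))


def diffexp(m: CountMatrix, cells_A, cells_B,
            pseudocount: float = 0.1) -> pd.DataFrame:
    """NB differential expression table for two disjoint cell groups.

    Columns: ``mean_A``, ``mean_B`` (normalized per-cell means),
    ``log2_fold_change`` (B over A with ``pseudocount``), ``p_value``,
    ``padj`` (BH).  Genes absent from both groups get p = 1.
    """
    cells_A, cells_B = list(cells_A), list(cells_B)
    if not cells_A or not cells_B:
        raise ValueError("both cell groups must be non-empty")
    if set(cells_A) & set(cells_B):
        raise ValueError("cell groups must be disjoint")
    sub = m.drop_spikeins()
    pos = {c: i for i, c in enumerate(sub.cell_ids)}
    iA = np.array([pos[c] for c in cells_A])
    iB = np.array([pos[c] for c in cells_B])
    nA, nB = len(iA), len(iB)
    var_fn = fit_dispersion(m, (cells_A, cells_B))

    kA = sub.counts[:, iA].sum(axis=1)
    kB = sub.counts[:, iB].sum(axis=1)
    mu = (kA + kB) / (nA + nB)
    meanA, meanB = kA / nA, kB / nB

    pvals = np.array([
        _exact_nb_p(int(a), int(b), nA, nB, float(u), var_fn)
        for a, b, u in zip(kA, kB, mu)])
    padj = benjamini_hochberg(pvals)
    lfc = np.log2((meanB + pseudocount) / (meanA + pseudocount))
    return pd.DataFrame({
        "mean_A": meanA, "mean_B": meanB, "log2_fold_change": lfc,
        "p_value": pvals, "padj": padj,
    }, index=sub.gene_ids)


def count_de(res: pd.DataFrame, p_threshold: float,
             use_adjusted: bool = False) -> int:
    """Number of genes passing the p-value threshold (raw by default)."""
    col = "padj" if use_adjusted else "p_value"
    return int((res[col] < p_threshold).sum())
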