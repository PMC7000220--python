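"""Cell/gene filtering and downsampling normalization.

The normalization strategy for plate-based UMI data: drop cells whose
total transcript count falls below a fixed cutoff (default 3500), then
sample each remaining cell's transcript pool without replacement down to
exactly that cutoff, so all cells are directly comparable, and finally
discard genes detected at >3 transcripts in no more than one cell.
Spike-in rows never contribute to totals or sampling pools.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io_counts import CountMatrix

__all__ = ["filter_cells", "filter_genes", "downsample", "qc_report"]


class EmptyFilterError(ValueError):
    """All cells removed by a filter; carries a totals summary."""


def filter_cells(m: CountMatrix, min_total: int = 3500) -> CountMatrix:
    """Retain cells with non-spike-in total >= ``min_total`` (inclusive)."""
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    totals = m.column_sums()
    keep = totals >= min_total
    if not keep.any():
        q = np.percentile(totals, [0, 25, 50, 75, 100]) if len(totals) else []
        raise EmptyFilterError(
            f"no cell reaches {min_total} transcripts; totals quartiles: {q}")
    return m.subset_cells(np.where(keep)[0])


def filter_genes(m: CountMatrix, min_count: int = 4,
                 min_cells: int = 2) -> CountMatrix:
    """Retain genes with >= ``min_count`` transcripts in >= ``min_cells`` cells.

    The defaults encode the literal ">3 transcripts in >1 cell" rule.
    Spike-in rows are always dropped here: they are reagents, not genes.
    """
    if min_count < 1 or min_cells < 1:
        raise ValueError("thresholds must be >= 1")
    keep = ((m.counts >= min_count).sum(axis=1) >= min_cells) & ~m.spikein_mask
    if not keep.any():
        warnings.warn("gene filter removed every gene")
    return m.subset_genes(np.where(keep)[0])


def downsample(m: CountMatrix, target: int = 3500,
               seed: int = 0) -> CountMatrix:
    """Sample each cell down to exactly ``target`` transcripts.

    A without-replacement draw from the cell's transcript pool, i.e. a
    multivariate hypergeometric sample over its gene counts; spike-ins
    are excluded from the pool and dropped from the result.  Column sums
    of the result all equal ``target``.
    """
    m = m.drop_spikeins()
    totals = m.counts.sum(axis=0)
    short = totals < target
    if short.any():
        bad = m.cell_ids[np.where(short)[0][0]]
        raise ValueError(
            f"cell {bad!r} has only {int(totals[short][0])} transcripts, "
            f"below the downsampling target {target}; run filter_cells first")
    rng = np.random.default_rng(seed)
    out = np.empty_like(m.counts)
    for j in range(m.n_cells):
        col = m.counts[:, j]
        if totals[j] == target:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, target)
    return CountMatrix(out, m.gene_ids.copy(), m.cell_ids.copy(),
                       np.zeros(m.n_genes, dtype=bool))


def qc_report(raw: CountMatrix) -> dict:
    """Summary of a raw matrix: cell/gene tallies and the totals histogram."""
    sub = raw.drop_spikeins()
    totals = sub.counts.sum(axis=0)
    detected = int((sub.counts.sum(axis=1) >= 1).sum())
    hist, edges = (np.histogram(np.log10(totals + 1), bins=20)
                   if len(totals) else (np.array([]), np.array([])))
    return {
        "n_cells": sub.n_cells,
        "n_genes_detected": detected,
        "mean_total_per_cell": float(totals.mean()) if len(totals) else 0.0,
        "totals": pd.Series(totals, index=sub.cell_ids),
        "log10_totals_hist": (hist, edges),
    }
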