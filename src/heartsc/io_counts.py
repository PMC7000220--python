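"""Count-matrix container and readers/writers for plate-based scRNA-seq data.

The on-disk convention is gene-major (genes are rows, cells are columns),
matching how plate-based (SORT-seq / CEL-Seq2) count tables are usually
distributed: a TSV/CSV whose first column holds gene identifiers and whose
header row holds cell identifiers, or a MatrixMarket coordinate file with
``genes.tsv`` / ``barcodes.tsv`` sidecars.

ERCC spike-in rows are tagged at load time via a configurable identifier
prefix and are excluded from all downstream analysis (totals, distances,
entropy, differential expression).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CountMatrix",
    "FormatError",
    "read_counts",
    "write_counts",
    "merge_matrices",
    "read_annotations",
]

DEFAULT_SPIKEIN_PREFIX = "ERCC-"


class FormatError(ValueError):
    """Raised when an input file violates the count-matrix format contract."""


@dataclass
class CountMatrix:
    """Integer UMI counts, genes x cells, with identifiers and spike-in flags.

    Attributes
    ----------
    counts : ndarray of int, shape (n_genes, n_cells)
    gene_ids, cell_ids : ndarray of str, unique
    spikein_mask : boolean ndarray per gene; True marks spike-in rows
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    spikein_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D genes x cells matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise FormatError("counts contain non-integer entries")
            self.counts = as_int
        if (self.counts < 0).any():
            raise FormatError("counts contain negative entries")
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if len(self.gene_ids) != self.counts.shape[0]:
            raise FormatError("gene_ids length does not match counts rows")
        if len(self.cell_ids) != self.counts.shape[1]:
            raise FormatError("cell_ids length does not match counts columns")
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                raise FormatError(f"duplicate {name} identifiers")
        if self.spikein_mask is None:
            self.spikein_mask = np.zeros(len(self.gene_ids), dtype=bool)
        self.spikein_mask = np.asarray(self.spikein_mask, dtype=bool)
        if len(self.spikein_mask) != len(self.gene_ids):
            raise FormatError("spikein_mask length does not match gene_ids")

    # -- basic queries -----------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def column_sums(self, include_spikeins: bool = False) -> np.ndarray:
        """Total counts per cell, excluding spike-ins by default."""
        if include_spikeins:
            return self.counts.sum(axis=0)
        return self.counts[~self.spikein_mask].sum(axis=0)

    def drop_spikeins(self) -> "CountMatrix":
        keep = ~self.spikein_mask
        return CountMatrix(self.counts[keep], self.gene_ids[keep],
                           self.cell_ids, np.zeros(keep.sum(), dtype=bool))

    def subset_cells(self, cell_index: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.counts[:, cell_index], self.gene_ids,
                           self.cell_ids[cell_index], self.spikein_mask.copy())

    def subset_genes(self, gene_index: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.counts[gene_index], self.gene_ids[gene_index],
                           self.cell_ids, self.spikein_mask[gene_index])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids,
                            columns=self.cell_ids)


def _mask_from_prefix(gene_ids: np.ndarray, spikein_prefix: str) -> np.ndarray:
    return np.array([str(g).startswith(spikein_prefix) for g in gene_ids])


def read_counts(path: str, format: str | None = None,
                spikein_prefix: str = DEFAULT_SPIKEIN_PREFIX) -> CountMatrix:
    """Read a gene-major count matrix from TSV, CSV or MatrixMarket.

    For ``mtx``, sidecar files ``genes.tsv`` and ``barcodes.tsv`` are
    expected next to the matrix file (one identifier per line).
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        format = {"tsv": "tsv", "txt": "tsv", "csv": "csv", "mtx": "mtx"}.get(ext)
        if format is None:
            raise FormatError(f"cannot infer format from path: {path}")
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        gene_ids = df.index.to_numpy(dtype=object)
        cell_ids = df.columns.to_numpy(dtype=object)
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric entries in count table")
        counts = values
    elif format == "mtx":
        mat = scipy.io.mmread(path)
        counts = np.asarray(scipy.sparse.coo_matrix(mat).todense())
        d = os.path.dirname(path)
        gene_ids = pd.read_csv(os.path.join(d, "genes.tsv"), sep="\t",
                               header=None)[0].to_numpy(dtype=object)
        cell_ids = pd.read_csv(os.path.join(d, "barcodes.tsv"), sep="\t",
                               header=None)[0].to_numpy(dtype=object)
    else:
        raise FormatError(f"unsupported format: {format}")
    return CountMatrix(counts, gene_ids, cell_ids,
                       _mask_from_prefix(gene_ids, spikein_prefix))


def write_counts(m: CountMatrix, path: str, format: str | None = None) -> None:
    """Write a count matrix; inverse of :func:`read_counts` per format."""
    if format is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        format = {"tsv": "tsv", "txt": "tsv", "csv": "csv", "mtx": "mtx"}.get(ext)
        if format is None:
            raise FormatError(f"cannot infer format from path: {path}")
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        m.to_frame().to_csv(path, sep=sep)
    elif format == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(m.counts), field="integer")
        d = os.path.dirname(path)
        pd.Series(m.gene_ids).to_csv(os.path.join(d, "genes.tsv"),
                                     sep="\t", header=False, index=False)
        pd.Series(m.cell_ids).to_csv(os.path.join(d, "barcodes.tsv"),
                                     sep="\t", header=False, index=False)
    else:
        raise FormatError(f"unsupported format: {format}")


def merge_matrices(a: CountMatrix, b: CountMatrix,
                   prefixes: tuple[str, str] | None = None) -> CountMatrix:
    """Merge two count matrices over the union of their gene sets.

    Cells are concatenated (a first).  Counts for genes absent from one
    input are zero.  If the cell-identifier sets overlap, ``prefixes``
    must be given; cells are then namespaced ``<prefix>:<id>``.
    """
    a_cells = list(a.cell_ids)
    b_cells = list(b.cell_ids)
    if prefixes is not None:
        a_cells = [f"{prefixes[0]}:{c}" for c in a_cells]
        b_cells = [f"{prefixes[1]}:{c}" for c in b_cells]
    if set(a_cells) & set(b_cells):
        raise FormatError("cell identifiers collide between the two matrices"
                          " (pass distinct prefixes)")
    genes = list(a.gene_ids) + [g for g in b.gene_ids if g not in set(a.gene_ids)]
    gene_pos = {g: i for i, g in enumerate(genes)}
    counts = np.zeros((len(genes), len(a_cells) + len(b_cells)), dtype=np.int64)
    for src, offset in ((a, 0), (b, len(a_cells))):
        rows = [gene_pos[g] for g in src.gene_ids]
        counts[rows, offset:offset + src.n_cells] = src.counts
    spike = np.zeros(len(genes), dtype=bool)
    for src in (a, b):
        for g, s in zip(src.gene_ids, src.spikein_mask):
            if s:
                spike[gene_pos[g]] = True
    return CountMatrix(counts, np.array(genes, dtype=object),
                       np.array(a_cells + b_cells, dtype=object), spike)


def read_annotations(path: str) -> pd.DataFrame:
    """Read a per-cell annotation TSV; requires a ``cell_id`` column."""
    df = pd.read_csv(path, sep="\t")
    if "cell_id" not in df.columns:
        raise FormatError("annotation file lacks required column 'cell_id'")
    if df["cell_id"].duplicated().any():
        raise FormatError("duplicate cell_id entries in annotation file")
    return df
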