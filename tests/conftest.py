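import numpy as np
import pytest

from heartsc.io_counts import CountMatrix
from heartsc.synthetic import GRADIENT_TYPES, default_config, simulate


def make_matrix(counts, gene_ids=None, cell_ids=None, spike_prefix="ERCC-"):
    counts = np.asarray(counts)
    g, c = counts.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(g)]
    if cell_ids is None:
        cell_ids = [f"c{j}" for j in range(c)]
    mask = np.array([str(x).startswith(spike_prefix) for x in gene_ids])
    return CountMatrix(counts, np.array(gene_ids, dtype=object),
                       np.array(cell_ids, dtype=object), mask)


@pytest.fixture(scope="session")
def small_scene():
    """A reduced copy of the default scene: fast, but same structure."""
    cfg = default_config(seed=5, n_genes=1200, cells_scale=0.35)
    m, ann, gt = simulate(cfg)
    return cfg, m, ann, gt


def gradient_only_config(seed, n_cells=40, n_genes=800):
    """A scene with only the four gradient cardiomyocyte states.

    Library sizes are tightened so nearly every cell survives the read
    cutoff; expression structure (markers, maturity programme,
    archetypes) is that of the default scene.
    """
    cfg = default_config(seed=seed, n_genes=n_genes)
    cfg.n_cells_per_type = {t: n_cells for t in GRADIENT_TYPES}
    cfg.libsize_log_mean = 9.0
    cfg.libsize_log_sd = 0.3
    return cfg
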