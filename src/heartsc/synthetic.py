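"""Ground-truthed synthetic scRNA-seq scenes of a regenerating heart.

The generator emulates the statistical structure the downstream analysis
assumes: negative-binomially distributed UMI counts over a handful of cell
types, log-normal library sizes straddling the per-cell read cutoff, a
continuous dedifferentiation gradient across four cardiomyocyte states
(remote -> intermediate -> intermediate -> border zone) with an embryonic
cardiomyocyte type parked at the border end, and four planted temporal
expression archetypes along the gradient:

* ``early_decline``   — high at the start, rapid monotone decay
                        (mitochondrial / OXPHOS-like programme),
* ``early_plateau``   — induced early, then constant (translation /
                        cell-cycle-like),
* ``late_rise``       — convex monotone increase peaking at the end
                        (cardiac muscle development-like),
* ``rise_then_peak``  — rapid rise with an interior maximum, then decline
                        (glycolysis-like).

Every cell carries a ground-truth type, gradient cells a true pseudotime
u in [0, 1], and every planted gene its archetype, so clustering, lineage
scoring, trajectory ordering and module recovery can all be measured
against truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .io_counts import CountMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ARCHETYPE_SHAPES",
    "default_config",
    "simulate",
    "planted_summary",
]

# Mean-modulation curves along pseudotime u in [0,1]; mutually
# distinguishable and qualitatively matching the four temporal programmes.
ARCHETYPE_SHAPES = {
    "early_decline": lambda u: np.exp(-5.0 * u),
    "early_plateau": lambda u: 1.0 - np.exp(-5.0 * u),
    "late_rise": lambda u: u ** 3,
    "rise_then_peak": lambda u: np.sin(np.pi * u * 0.9),
}

GRADIENT_TYPES = ("cm_remote", "cm_intermediate1", "cm_intermediate2",
                  "cm_border")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic scene; defaults via :func:`default_config`."""

    n_cells_per_type: dict
    n_genes: int
    type_means: dict            # cell type -> mean expression vector
    dispersion: float           # NB size parameter (inf => Poisson)
    libsize_log_mean: float
    libsize_log_sd: float
    gradient_types: tuple       # ordered dedifferentiation axis
    archetypes: dict            # name -> (gene index array, amplitude)
    seed: int
    marker_genes: dict = field(default_factory=dict)   # type -> gene id list
    mature_gene_idx: np.ndarray | None = None          # maturity programme
    mature_amplitude: float = 100.0
    # off-gradient differentiated types carry their own high-mass
    # specialization programme (keeps their transcriptome entropy low,
    # as in real differentiated cells): type -> (gene idx, amplitude)
    specialization: dict = field(default_factory=dict)
    n_spikeins: int = 8
    spikein_mean: float = 30.0

    def validate(self) -> None:
        if self.n_genes <= 0 or not self.n_cells_per_type or \
                sum(self.n_cells_per_type.values()) <= 0:
            raise ValueError("simulation needs at least one gene and one cell")
        if len(self.gradient_types) < 2:
            raise ValueError("gradient needs at least two cell types")
        if not set(self.gradient_types) <= set(self.n_cells_per_type):
            raise ValueError("gradient_types must be simulated cell types")
        seen: set = set()
        for name, (idx, _amp) in self.archetypes.items():
            s = set(np.asarray(idx).tolist())
            if seen & s:
                raise ValueError("archetype gene sets must be pairwise disjoint")
            seen |= s
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass
class GroundTruth:
    """Planted truth: per-cell type, per-gradient-cell pseudotime, per-gene archetype."""

    cell_type: pd.Series          # index cell_id
    true_pseudotime: pd.Series    # index cell_id, NaN off-gradient
    archetype: pd.Series          # index gene_id, planted genes only


def default_config(seed: int = 0, n_genes: int = 2000,
                   cells_scale: float = 1.0) -> SimulationConfig:
    """The default regenerating-heart scene.

    Two 384-cell plates (768 cells total) over eight types: the four
    gradient cardiomyocyte states, an embryonic cardiomyocyte type at the
    border end of the gradient, plus endothelial, fibroblast and immune
    cells off the gradient.  Library sizes are log-normal with mean
    ~10.4k reads and roughly half the cells below the 3500-read cutoff.
    ``cells_scale`` shrinks every type count proportionally (for quick
    tests); gene count and all rates are independent of it.
    """
    rng = np.random.default_rng(seed + 777_001)
    base = dict(cm_remote=120, cm_intermediate1=120, cm_intermediate2=120,
                cm_border=120, cm_embryonic=80, endothelial=80,
                fibroblast=64, immune=64)
    n_cells = {t: max(4, int(round(n * cells_scale))) for t, n in base.items()}

    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    types = list(base)
    # disjoint gene blocks: per-type markers, maturity programme, archetypes.
    # The maturity programme concentrates a large share of the cell's reads
    # on a handful of transcripts (mitochondrially encoded and myosin genes
    # dominate reads in mature cardiomyocytes), which is what makes the
    # mature transcriptome entropy low.
    n_mark, n_mature, n_arch = 12, 20, 40
    cursor = 0
    marker_idx = {}
    for t in types:
        marker_idx[t] = np.arange(cursor, cursor + n_mark)
        cursor += n_mark
    mature_idx = np.arange(cursor, cursor + n_mature)
    cursor += n_mature
    archetypes = {}
    for name in ARCHETYPE_SHAPES:
        archetypes[name] = (np.arange(cursor, cursor + n_arch), 4.0)
        cursor += n_arch
    specialization = {}
    for t in ("endothelial", "fibroblast", "immune"):
        specialization[t] = (np.arange(cursor, cursor + 40), 25.0)
        cursor += 40
    if cursor > n_genes:
        raise ValueError("n_genes too small for the default scene layout")

    # temporally structured programmes (mitochondrial, sarcomeric,
    # glycolytic) are well-expressed genes in this tissue; plant the
    # archetypes at a moderate expression level rather than the noise floor
    for name in ARCHETYPE_SHAPES:
        baseline[archetypes[name][0]] *= 5.0

    type_means = {}
    for t in types:
        mu = baseline.copy()
        mu[marker_idx[t]] *= 15.0
        if t in specialization:
            idx, amp = specialization[t]
            mu[idx] *= 1.0 + amp
        type_means[t] = mu
    marker_genes = {t: [f"gene_{i:05d}" for i in marker_idx[t]] for t in types}

    return SimulationConfig(
        n_cells_per_type=n_cells,
        n_genes=n_genes,
        type_means=type_means,
        dispersion=2.0,
        libsize_log_mean=8.13,   # mean ~10.4k reads, ~half below 3500
        libsize_log_sd=1.5,
        gradient_types=GRADIENT_TYPES,
        archetypes=archetypes,
        seed=seed,
        marker_genes=marker_genes,
        mature_gene_idx=mature_idx,
        mature_amplitude=100.0,
        specialization=specialization,
    )


def _modulate(mean: np.ndarray, u: float, cfg: SimulationConfig) -> np.ndarray:
    """Apply gradient-position-dependent modulation to a mean vector."""
    mu = mean.copy()
    if cfg.mature_gene_idx is not None:
        mu[cfg.mature_gene_idx] *= 1.0 + cfg.mature_amplitude * np.exp(-3.0 * u)
    for name, (idx, amp) in cfg.archetypes.items():
        mu[idx] *= 0.5 + amp * ARCHETYPE_SHAPES[name](u)
    return mu


def simulate(config: SimulationConfig):
    """Draw one scene; returns ``(CountMatrix, annotations, GroundTruth)``.

    Counts are NB(mean = library-size-scaled type/pseudotime mean,
    size = dispersion), sampled as a Gamma–Poisson mixture; identical
    seeds give identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"gene_{i:05d}" for i in range(config.n_genes)]
    gene_ids += [f"ERCC-{i:05d}" for i in range(config.n_spikeins)]

    grad = list(config.gradient_types)
    n_seg = len(grad)
    columns, cell_ids, cell_types, pseudotimes, fluor = [], [], [], [], []
    for t in sorted(config.n_cells_per_type):
        n = config.n_cells_per_type[t]
        for j in range(n):
            cid = f"{t}_{j:04d}"
            if t in grad:
                seg = grad.index(t)
                u = rng.uniform(seg / n_seg, (seg + 1) / n_seg)
            elif t == "cm_embryonic":
                u = 1.0       # parked at the border end of the gradient
            else:
                u = None
            mu = config.type_means[t]
            mu = _modulate(mu, u, config) if u is not None else mu
            p = mu / mu.sum()
            lib = rng.lognormal(config.libsize_log_mean, config.libsize_log_sd)
            cell_mean = lib * p
            if np.isinf(config.dispersion):
                cnt = rng.poisson(cell_mean)
            else:
                lam = rng.gamma(config.dispersion,
                                cell_mean / config.dispersion)
                cnt = rng.poisson(lam)
            if config.n_spikeins:
                cnt = np.concatenate([
                    cnt, rng.poisson(config.spikein_mean,
                                     size=config.n_spikeins)])
            columns.append(cnt)
            cell_ids.append(cid)
            cell_types.append(t)
            pseudotimes.append(u if t in grad else np.nan)
            # nppa-reporter-like signal: bright at the border end
            base_f = 20.0 + 180.0 * (u if u is not None else 0.0)
            fluor.append(base_f * rng.lognormal(0.0, 0.25))

    counts = np.column_stack(columns).astype(np.int64)
    spike = np.array([g.startswith("ERCC-") for g in gene_ids])
    cm = CountMatrix(counts, np.array(gene_ids, dtype=object),
                     np.array(cell_ids, dtype=object), spike)

    n_total = len(cell_ids)
    ann = pd.DataFrame({
        "cell_id": cell_ids,
        "library_id": [f"plate{1 + (i % 2)}" for i in range(n_total)],
        "fluor_intensity": fluor,
        "condition": ["embryonic" if t == "cm_embryonic" else "adult-injured"
                      for t in cell_types],
    })

    arch = {}
    for name, (idx, _amp) in config.archetypes.items():
        for i in np.asarray(idx):
            arch[gene_ids[int(i)]] = name
    gt = GroundTruth(
        cell_type=pd.Series(cell_types, index=cell_ids, name="cell_type"),
        true_pseudotime=pd.Series(pseudotimes, index=cell_ids,
                                  name="true_pseudotime"),
        archetype=pd.Series(arch, name="archetype"),
    )
    return cm, ann, gt


def planted_summary(gt: GroundTruth, modules=None, trajectory=None) -> dict:
    """Recovery report against planted truth.

    For each archetype, the fraction of its planted genes landing in a
    single recovered module (and which module); if a trajectory is given,
    the Spearman rank correlation between the recovered cell order and
    the true pseudotime.
    """
    report: dict = {}
    if modules is not None:
        gene_to_module = {}
        for mod in modules.modules:
            for g in mod.genes:
                gene_to_module[g] = mod.module_id
        conc, best = {}, {}
        for name in gt.archetype.unique():
            genes = gt.archetype.index[gt.archetype == name]
            assigned = [gene_to_module[g] for g in genes if g in gene_to_module]
            if not assigned:
                conc[name], best[name] = 0.0, None
                continue
            vals, cnts = np.unique(assigned, return_counts=True)
            top = int(np.argmax(cnts))
            conc[name] = float(cnts[top]) / len(genes)
            best[name] = vals[top]
        report["archetype_concentration"] = conc
        report["archetype_module"] = best
    if trajectory is not None:
        cells = [c for c in trajectory.ordered_cells
                 if c in gt.true_pseudotime.index
                 and np.isfinite(gt.true_pseudotime[c])]
        if len(cells) >= 3:
            ranks = np.arange(len(cells))
            truth = gt.true_pseudotime[cells].to_numpy()
            rho = spearmanr(ranks, truth).statistic
            report["order_spearman"] = float(rho)
        else:
            warnings.warn("too few gradient cells on trajectory for Spearman")
            report["order_spearman"] = np.nan
    return report
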