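"""End-to-end pipeline: simulate/load -> QC -> cluster -> lineage tree ->
pseudotime modules -> differential expression -> gene-set enrichment.

A single YAML config drives the run; every stage gets its own seed derived
from the master seed by stable hashing of the stage name, every
intermediate artifact is written to the run directory, and a manifest
(parameters + seeds + versions + stage status) makes the run reproducible:
re-running with the same config is bit-identical for deterministic stages.
"""

from __future__ import annotations

import json
import os
import zlib

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import (ClusterResult, annotate_clusters, kmedoids,
                      library_composition, pairwise_distance, select_k)
from .diffexp import count_de, diffexp
from .gsea import gsea_test, read_gmt
from .io_counts import CountMatrix, read_annotations, read_counts, write_counts
from .pseudotime import (build_modules, classify_module_dynamics, order_cells,
                         smooth_profiles, som_1d)
from .qc import downsample, filter_cells, filter_genes, qc_report
from .stemid import build_lineage_tree
from .synthetic import default_config, simulate

__all__ = ["stage_seed", "run_pipeline", "load_cluster_result",
           "write_cluster_result"]

STAGES = ("qc", "cluster", "stemid", "pseudotime", "diffexp", "gsea")


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from the master seed."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_cluster_result(cr: ClusterResult, labels: dict | None,
                         path: str) -> None:
    medoid_cells = set(cr.medoids.values())
    df = pd.DataFrame({
        "cell_id": cr.assignment.index,
        "cluster": cr.assignment.values,
        "is_medoid": [c in medoid_cells for c in cr.assignment.index],
    })
    if labels:
        df["cell_type"] = [labels.get(cl, "unassigned")
                           for cl in cr.assignment.values]
    df.to_csv(path, sep="\t", index=False)


def load_cluster_result(path: str, m: CountMatrix) -> ClusterResult:
    """Rebuild a ClusterResult (and its distance matrix) from a TSV."""
    df = pd.read_csv(path, sep="\t")
    dm = pairwise_distance(m)
    assignment = pd.Series(df.cluster.values, index=df.cell_id.values,
                           name="cluster").reindex(m.cell_ids)
    medoids = {int(r.cluster): r.cell_id
               for r in df[df.is_medoid].itertuples()}
    return ClusterResult(assignment, medoids,
                         int(assignment.max()), dm)


def _validate_config(cfg: dict) -> dict:
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    if ("simulate" not in cfg) == ("input" not in cfg):
        raise ValueError("config needs exactly one of 'simulate' or 'input'")
    known = {"seed", "simulate", "input", "qc", "cluster", "stemid",
             "pseudotime", "diffexp", "gsea"}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    cfg.setdefault("seed", 0)
    for sec in ("qc", "cluster", "stemid", "pseudotime", "diffexp", "gsea"):
        cfg.setdefault(sec, {})
        if not isinstance(cfg[sec], dict):
            raise ValueError(f"config section {sec!r} must be a mapping")
    return cfg


def run_pipeline(config, out_dir: str) -> dict:
    """Run all stages; returns the manifest (also written to the run dir)."""
    if isinstance(config, str):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = _validate_config(dict(config))
    os.makedirs(out_dir, exist_ok=True)
    master = int(cfg["seed"])
    manifest: dict = {"version": __version__,
                      "versions": {"numpy": np.__version__,
                                   "pandas": pd.__version__},
                      "config": _jsonable(cfg), "stages": []}
    summary: dict = {}

    def record(stage, status, seed=None, **info):
        manifest["stages"].append(
            {"stage": stage, "status": status, "seed": seed,
             **_jsonable(info)})

    # ---- input / simulate -------------------------------------------------
    gt = None
    sim_cfg = None
    if "simulate" in cfg:
        s = dict(cfg["simulate"] or {})
        sim_cfg = default_config(seed=stage_seed(master, "simulate"),
                                 n_genes=int(s.get("n_genes", 2000)),
                                 cells_scale=float(s.get("cells_scale", 1.0)))
        m, ann, gt = simulate(sim_cfg)
        write_counts(m, os.path.join(out_dir, "counts.tsv"))
        ann.to_csv(os.path.join(out_dir, "annotations.tsv"), sep="\t",
                   index=False)
        pd.DataFrame({"cell_id": gt.cell_type.index,
                      "cell_type": gt.cell_type.values,
                      "true_pseudotime": gt.true_pseudotime.values}
                     ).to_csv(os.path.join(out_dir, "ground_truth_cells.tsv"),
                              sep="\t", index=False)
        gt.archetype.rename_axis("gene_id").to_frame().to_csv(
            os.path.join(out_dir, "ground_truth_genes.tsv"), sep="\t")
        record("simulate", "ok", seed=sim_cfg.seed,
               shape=[m.n_genes, m.n_cells])
    else:
        inp = cfg["input"]
        m = read_counts(inp["counts"], format=inp.get("format"))
        ann = (read_annotations(inp["annotations"])
               if inp.get("annotations") else None)
        record("input", "ok", shape=[m.n_genes, m.n_cells])

    status_fail = False
    cr = tree = traj = modules = None
    de_pair = None
    try:
        # ---- qc -----------------------------------------------------------
        q = cfg["qc"]
        seed = stage_seed(master, "qc")
        rep = qc_report(m)
        summary["qc"] = {k: rep[k] for k in
                         ("n_cells", "n_genes_detected", "mean_total_per_cell")}
        mf = filter_cells(m, int(q.get("min_total", 3500)))
        md = downsample(mf, int(q.get("target", 3500)), seed=seed)
        md = filter_genes(md, int(q.get("gene_min_count", 4)),
                          int(q.get("gene_min_cells", 2)))
        summary["qc"]["n_cells_retained"] = md.n_cells
        summary["qc"]["n_genes_retained"] = md.n_genes
        write_counts(md, os.path.join(out_dir, "normalized.tsv"))
        record("qc", "ok", seed=seed, shape=[md.n_genes, md.n_cells],
               cells_dropped=m.n_cells - md.n_cells)

        # ---- cluster ------------------------------------------------------
        c = cfg["cluster"]
        seed = stage_seed(master, "cluster")
        dm = pairwise_distance(md, c.get("transform", "log2p1"))
        k = c.get("k")
        if k is None:
            k = select_k(dm, k_max=int(c.get("k_max", 20)), seed=seed,
                         n_restarts=int(c.get("n_restarts", 3)))
        cr = kmedoids(dm, int(k), seed=seed,
                      n_restarts=int(c.get("n_restarts", 3)))
        markers = c.get("markers")
        if markers is None and sim_cfg is not None:
            markers = sim_cfg.marker_genes
        labels = annotate_clusters(md, cr, markers) if markers else None
        write_cluster_result(cr, labels,
                             os.path.join(out_dir, "clusters.tsv"))
        if ann is not None and "library_id" in ann.columns:
            library_composition(ann, cr).to_csv(
                os.path.join(out_dir, "library_composition.tsv"), sep="\t")
        summary["cluster"] = {"k": int(cr.k), "labels": labels}
        record("cluster", "ok", seed=seed, k=int(cr.k))

        # ---- stemid -------------------------------------------------------
        s = cfg["stemid"]
        seed = stage_seed(master, "stemid")
        tree = build_lineage_tree(md, cr, alpha=float(s.get("alpha", 0.05)),
                                  method=s.get("method", "binomial"),
                                  seed=seed)
        tree.links.to_csv(os.path.join(out_dir, "links.tsv"), sep="\t",
                          index=False)
        tree.entropy.rename_axis("cell_id").to_frame().to_csv(
            os.path.join(out_dir, "entropy.tsv"), sep="\t")
        tree.stemid_score.rename_axis("cluster").to_frame().to_csv(
            os.path.join(out_dir, "stemid_scores.tsv"), sep="\t")
        summary["stemid"] = {"scores": tree.stemid_score.to_dict()}
        record("stemid", "ok", seed=seed,
               n_significant_links=int(tree.links.significant.sum()))

        # ---- pseudotime / modules ----------------------------------------
        p = cfg["pseudotime"]
        seed = stage_seed(master, "pseudotime")
        path = p.get("path", "auto")
        if path == "auto":
            path = _auto_path(labels, tree)
        path = [int(x) for x in path]
        traj = order_cells(tree, path)
        prof = smooth_profiles(md, traj, span=float(p.get("span", 0.3)))
        # ~13 profiles per node (the regime a 1000-node map operates in on
        # a full transcriptome) keeps the >3-profiles retention meaningful
        n_nodes = p.get("som_nodes", "auto")
        if n_nodes == "auto":
            n_nodes = int(np.clip(len(prof) // 13, 10, 1000))
        som = som_1d(prof, n_nodes=int(n_nodes),
                     seed=seed, epochs=int(p.get("som_epochs", 100)))
        modules = build_modules(som, prof,
                                min_profiles=int(p.get("min_profiles", 3)),
                                merge_r=float(p.get("merge_r", 0.9)))
        dynamics = classify_module_dynamics(modules)
        g2m = modules.gene_to_module()
        pd.DataFrame({
            "gene": g2m.index, "node": som.assignment[g2m.index].values,
            "module": g2m.values,
            "dynamics": [dynamics[mid] for mid in g2m.values],
        }).to_csv(os.path.join(out_dir, "modules.tsv"), sep="\t", index=False)
        pd.DataFrame({"cell_id": traj.ordered_cells,
                      "rank": np.arange(len(traj.ordered_cells)),
                      "coord": traj.coords}).to_csv(
            os.path.join(out_dir, "trajectory.tsv"), sep="\t", index=False)
        pd.DataFrame(np.vstack([mod.mean_profile for mod in modules.modules]),
                     index=[mod.module_id for mod in modules.modules]
                     ).to_csv(os.path.join(out_dir, "module_profiles.tsv"),
                              sep="\t")
        summary["pseudotime"] = {"path": path,
                                 "n_cells": len(traj.ordered_cells),
                                 "n_modules": len(modules.modules),
                                 "dynamics": dynamics}
        record("pseudotime", "ok", seed=seed,
               n_modules=len(modules.modules))

        # ---- diffexp ------------------------------------------------------
        d = cfg["diffexp"]
        seed = stage_seed(master, "diffexp")
        pair = d.get("clusters", "auto")
        if pair == "auto":
            # the central comparison: remote vs border-zone cardiomyocytes
            if labels and "cm_remote" in labels.values() \
                    and "cm_border" in labels.values():
                pair = [min(c for c, l in labels.items() if l == "cm_remote"),
                        min(c for c, l in labels.items() if l == "cm_border")]
            else:
                pair = [path[0], path[-1]]
        de_pair = [int(pair[0]), int(pair[1])]
        res = diffexp(md, cr.cells_of(de_pair[0]), cr.cells_of(de_pair[1]),
                      pseudocount=float(d.get("pseudocount", 0.1)))
        res.rename_axis("gene").to_csv(os.path.join(out_dir, "diffexp.tsv"),
                                       sep="\t")
        summary["diffexp"] = {
            "clusters": de_pair,
            "n_de_raw_p01": count_de(res, 0.01),
            "n_de_padj05": count_de(res, 0.05, use_adjusted=True)}
        record("diffexp", "ok", seed=seed, n_genes=len(res))

        # ---- gsea ---------------------------------------------------------
        g = cfg["gsea"]
        seed = stage_seed(master, "gsea")
        if g.get("gmt"):
            gene_sets = read_gmt(g["gmt"])
        elif sim_cfg is not None:
            # planted glycolysis-like programme as the default query set
            idx = sim_cfg.archetypes["rise_then_peak"][0]
            gene_sets = {"planted_rise_then_peak":
                         {f"gene_{i:05d}" for i in np.asarray(idx)}}
        else:
            gene_sets = {}
        rows = []
        for name, gset in gene_sets.items():
            r = gsea_test(md, list(cr.cells_of(de_pair[0])),
                          list(cr.cells_of(de_pair[1])), gset,
                          n_perm=int(g.get("n_perm", 1000)), seed=seed)
            rows.append({"set": name, "ES": r.es, "NES": r.nes,
                         "p": r.p, "p_label": r.p_label,
                         "n_perm": r.n_perm, "seed": r.seed})
        pd.DataFrame(rows).to_csv(os.path.join(out_dir, "gsea.tsv"),
                                  sep="\t", index=False)
        summary["gsea"] = rows
        record("gsea", "ok", seed=seed, n_sets=len(rows))
    except Exception as exc:                        # noqa: BLE001
        status_fail = True
        record("failed", "error", error=f"{type(exc).__name__}: {exc}")

    manifest["summary"] = _jsonable(summary)
    manifest["ok"] = not status_fail
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)
    return manifest


def _auto_path(labels: dict | None, tree) -> list:
    """Derive the dedifferentiation path from gradient-type annotations.

    The embryonic cardiomyocyte cluster, when present and linked, is
    appended as the endpoint: dedifferentiating border-zone cells converge
    on the embryonic state, so the path must reach it to cover the full
    gradient.
    """
    from .synthetic import GRADIENT_TYPES
    if not labels:
        raise ValueError("pseudotime path 'auto' needs cluster annotations")
    path = []
    for t in GRADIENT_TYPES + ("cm_embryonic",):
        cands = [cl for cl, lab in labels.items() if lab == t]
        if cands:
            cl = min(cands)
            if t == "cm_embryonic" and path and not tree.has_link(path[-1], cl):
                continue
            path.append(cl)
    if len(path) < 2:
        raise ValueError("could not derive a gradient path from annotations")
    return path
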