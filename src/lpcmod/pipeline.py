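"""End-to-end orchestration: simulate -> qc -> annotate -> modules -> spatial.

A single global seed fans out to per-stage seeds by fixed offsets so
each stage is individually reproducible; identical config + seed give
identical numeric outputs.  Every stage writes its artifacts under the
output directory and contributes a block to the consolidated report
(report.json and report.md).
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import (MarkerPanelSet, assign_cell_types, cluster_mean_zscores,
                       identify_lpc_clusters, lpc_proportions, score_gene_module)
from .io import (write_cell_map, write_cohort_bundle, write_json)
from .modules import (cluster_frequency_table, cut_modules, frequency_correlation,
                      module_markers, ward_d_linkage)
from .qc import QCConfig, run_qc
from .simulate import CohortSimConfig, SpatialSimConfig, simulate_cohort, simulate_spatial
from .spatial import (cluster_distance_profiles, knn_type_distance_profiles,
                      pseudobulk_correlation, pseudobulk_profile,
                      rank_colocalization)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

# fixed per-stage seed offsets
SEED_COHORT, SEED_SPATIAL, SEED_SCORE = 1, 2, 3


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "lpcmod_run"
    cohort: CohortSimConfig = field(default_factory=CohortSimConfig)
    spatial: SpatialSimConfig = field(default_factory=SpatialSimConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    panels: MarkerPanelSet = field(default_factory=MarkerPanelSet)
    tau: float = 0.5
    min_z: float = 0.5
    k_modules: int = 4
    k_neighbors: int = 4
    k_profile_groups: int = 2
    top_n: int = 250
    sample_unit: str = "individual"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        kwargs: dict[str, Any] = {}
        nested = {"cohort": CohortSimConfig, "spatial": SpatialSimConfig,
                  "qc": QCConfig, "panels": MarkerPanelSet}
        for key, value in raw.items():
            if key in nested and isinstance(value, dict):
                kwargs[key] = nested[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _stage(report: dict, name: str, t0: float, **results: Any) -> None:
    report["stages"].append({"stage": name,
                             "seconds": round(time.perf_counter() - t0, 3),
                             **results})


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns the report dict (also written to disk)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"version": __version__, "seed": cfg.seed, "stages": []}
    stage_name = "simulate"
    try:
        # -- simulate -----------------------------------------------------
        t0 = time.perf_counter()
        cohort_cfg = dataclasses.replace(cfg.cohort, seed=cfg.seed + SEED_COHORT)
        spatial_cfg = dataclasses.replace(cfg.spatial, seed=cfg.seed + SEED_SPATIAL)
        adata, truth = simulate_cohort(cohort_cfg)
        cells = simulate_spatial(spatial_cfg)
        write_cohort_bundle(adata, out / "cohort")
        truth.to_csv(out / "cohort" / "truth.csv")
        write_cell_map(cells, out / "spatial" / "cells.csv")
        _stage(report, "simulate", t0, n_cells=int(adata.n_obs),
               n_genes=int(adata.n_vars), n_spatial_cells=int(len(cells)))

        # -- qc -----------------------------------------------------------
        stage_name = "qc"
        t0 = time.perf_counter()
        filtered, qc_report = run_qc(adata, cfg.qc)
        write_cohort_bundle(filtered, out / "qc")
        write_json(qc_report.to_dict(), out / "qc" / "qc_report.json")
        _stage(report, "qc", t0, **qc_report.to_dict())

        # -- annotate -----------------------------------------------------
        stage_name = "annotate"
        t0 = time.perf_counter()
        z = cluster_mean_zscores(filtered, "cluster")
        assignment = assign_cell_types(z, cfg.panels, min_z=cfg.min_z)
        flags = identify_lpc_clusters(z, cfg.panels, tau=cfg.tau)
        assignment.table["lpc_flag"] = flags
        labels = assignment.cell_labels(filtered.obs["cluster"])
        lpc_clusters = list(flags[flags].index)
        labels[filtered.obs["cluster"].isin(lpc_clusters)] = "LPC"
        filtered.obs["assigned_type"] = labels
        scores = score_gene_module(filtered, cfg.panels.regeneration_set,
                                   seed=cfg.seed + SEED_SCORE)
        filtered.obs["regeneration_score"] = scores
        props = lpc_proportions(labels, filtered.obs["individual"])
        (out / "annotate").mkdir(parents=True, exist_ok=True)
        assignment.table.to_csv(out / "annotate" / "assignments.csv")
        filtered.obs[["assigned_type", "regeneration_score"]].to_csv(
            out / "annotate" / "cells.csv")
        props.per_individual.to_csv(out / "annotate" / "proportions.csv", index=False)
        _stage(report, "annotate", t0, lpc_clusters=lpc_clusters,
               lpc_proportion_mean=props.mean, lpc_proportion_sd=props.sd,
               n_unassigned_clusters=int((assignment.table["type"] == "unassigned").sum()))

        # -- modules ------------------------------------------------------
        stage_name = "modules"
        t0 = time.perf_counter()
        unit = filtered.obs["individual"] if cfg.sample_unit == "individual" \
            else filtered.obs["condition"]
        freq = cluster_frequency_table(filtered.obs["cluster"], unit)
        corr, dist = frequency_correlation(freq)
        tree = ward_d_linkage(dist)
        k = min(cfg.k_modules, tree.n_leaves)
        modules = cut_modules(tree, k)
        deg, top_sets = module_markers(filtered, modules, top_n=cfg.top_n)
        (out / "modules").mkdir(parents=True, exist_ok=True)
        corr.to_csv(out / "modules" / "correlation.csv")
        modules.to_csv(out / "modules" / "modules.csv")
        deg.to_csv(out / "modules" / "deg.csv", index=False)
        (out / "modules" / "linkage.nwk").write_text(tree.to_newick() + "\n")
        write_json(tree.to_nested_lists(), out / "modules" / "linkage.json")
        _stage(report, "modules", t0, k=int(k),
               module_sizes={str(m): int((modules == m).sum())
                             for m in sorted(modules.unique())},
               lpc_cluster_module={c: int(modules[c]) for c in lpc_clusters
                                   if c in modules.index})

        # -- spatial ------------------------------------------------------
        stage_name = "spatial"
        t0 = time.perf_counter()
        profiles = knn_type_distance_profiles(cells, spatial_cfg.lpc_name,
                                              k=cfg.k_neighbors)
        ranking = rank_colocalization(profiles)
        groups, _ = cluster_distance_profiles(profiles, cfg.k_profile_groups)
        (out / "spatial").mkdir(parents=True, exist_ok=True)
        profiles.mean.to_csv(out / "spatial" / "profiles.csv")
        ranking.to_csv(out / "spatial" / "ranking.csv", index=False)
        groups.to_csv(out / "spatial" / "groups.csv")

        # split-half pseudo-bulk concordance of the LPC population
        lpc_mask = (filtered.obs["assigned_type"] == "LPC").to_numpy()
        r = None
        if lpc_mask.sum() >= 4:
            inds = np.asarray(sorted(filtered.obs.loc[lpc_mask, "individual"].unique()))
            half_a = set(inds[::2])
            mask_a = lpc_mask & filtered.obs["individual"].isin(half_a).to_numpy()
            mask_b = lpc_mask & ~filtered.obs["individual"].isin(half_a).to_numpy()
            if mask_a.sum() > 0 and mask_b.sum() > 0:
                pa = pseudobulk_profile(filtered, mask_a, "lpc_half_a")
                pb = pseudobulk_profile(filtered, mask_b, "lpc_half_b")
                r = pseudobulk_correlation(pa, pb)
        _stage(report, "spatial", t0,
               colocalization_ranking=ranking["cell_type"].tolist(),
               nearest_type=str(ranking["cell_type"].iloc[0]),
               lpc_pseudobulk_split_half_r=r)
    except Exception as exc:  # preserve partial outputs, name the stage
        raise RuntimeError(f"pipeline failed in stage {stage_name!r}: {exc}") from exc

    write_json(report, out / "report.json")
    (out / "report.md").write_text(_render_md(report))
    return report


def _render_md(report: dict) -> str:
    lines = [f"# lpcmod run report (v{report['version']}, seed {report['seed']})", ""]
    for block in report["stages"]:
        lines.append(f"## {block['stage']}")
        for k, v in block.items():
            if k != "stage":
                lines.append(f"- {k}: {v}")
        lines.append("")
    return "\n".join(lines)
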