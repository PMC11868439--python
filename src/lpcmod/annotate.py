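"""Marker-panel annotation of clusters and LPC statistics.

Clusters are characterised by a gene x cluster z-score matrix of
per-cluster mean log-normalised expression (each gene standardised
across clusters).  A cluster is assigned the panel with the highest
mean panel z-score (if above a floor), and flagged as the bipotent
liver-progenitor (LPC) cluster when the progenitor, hepatocyte and
cholangiocyte panels are *all* elevated — the bipotency signature.
A Tirosh-style module score (expression-bin matched control genes)
quantifies gene-set activity per cell, and LPC proportions are
summarised over the epithelial+LPC pool per individual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData

from .expression import log_normalized
from .simulate import (CHOLANGIOCYTE_MARKERS, HEPATOCYTE_MARKERS,
                       PROGENITOR_MARKERS, REGENERATION_SET)
from .stats import pairwise_rank_sum

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerPanelSet",
    "ZScoreMatrix",
    "CellTypeAssignment",
    "LPCProportionSummary",
    "cluster_mean_zscores",
    "assign_cell_types",
    "identify_lpc_clusters",
    "score_gene_module",
    "lpc_proportions",
]


@dataclass
class MarkerPanelSet:
    """Named marker panels plus the regeneration gene set.

    ``lineage_panels`` drive cluster assignment; ``subpop_panels``
    (LPC1 ALB+/APOA1+, LPC2 STMN1+, LPC3 S100A6+) are reused with the
    same assignment machinery on LPC cells only.
    """

    panels: dict[str, list[str]] = field(default_factory=lambda: {
        "hepatocyte": list(HEPATOCYTE_MARKERS),
        "cholangiocyte": list(CHOLANGIOCYTE_MARKERS),
        "progenitor": list(PROGENITOR_MARKERS),
    })
    subpop_panels: dict[str, list[str]] = field(default_factory=lambda: {
        "LPC1": ["ALB", "APOA1"],
        "LPC2": ["STMN1", "NPM1", "ACTB", "PTMA"],
        "LPC3": ["S100A6", "S100A4"],
    })
    regeneration_set: list[str] = field(default_factory=lambda: list(REGENERATION_SET))

    def __post_init__(self) -> None:
        for name, genes in {**self.panels, **self.subpop_panels}.items():
            if not genes:
                raise ValueError(f"panel {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"panel {name!r} has duplicate genes")


@dataclass
class ZScoreMatrix:
    """Gene x cluster z-scores with the underlying cluster-mean basis.

    Rows have mean 0 and unit sample sd (ddof=1) across clusters;
    zero-variance rows are all-zero by convention.
    """

    values: pd.DataFrame
    basis: pd.DataFrame

    @property
    def clusters(self) -> list[str]:
        return list(self.values.columns)


def cluster_mean_zscores(adata: AnnData, clusters: Sequence | str = "cluster"
                         ) -> ZScoreMatrix:
    """Standardise per-cluster mean log-normalised expression per gene.

    ``clusters`` is either an obs column name or a per-cell label
    sequence.  Requires at least two clusters (sample sd undefined
    otherwise).
    """
    labels = adata.obs[clusters] if isinstance(clusters, str) else pd.Series(
        np.asarray(clusters), index=adata.obs_names)
    labels = pd.Series(np.asarray(labels, dtype=object), index=adata.obs_names)
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ValueError("z-scores need at least 2 clusters")
    X = log_normalized(adata)
    means = np.zeros((adata.n_vars, len(uniq)))
    lab_arr = labels.to_numpy()
    for j, c in enumerate(uniq):
        mask = lab_arr == c
        means[:, j] = np.asarray(X[mask].mean(axis=0)).ravel()
    basis = pd.DataFrame(means, index=adata.var_names, columns=uniq)
    mu = basis.mean(axis=1)
    sd = basis.std(axis=1, ddof=1)
    z = basis.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    return ZScoreMatrix(values=z, basis=basis)


def _panel_means(z: ZScoreMatrix, panels: Mapping[str, Sequence[str]]
                 ) -> pd.DataFrame:
    """Mean panel z-score per cluster; missing genes dropped with warning."""
    rows = {}
    for name, genes in panels.items():
        present = [g for g in genes if g in z.values.index]
        if not present:
            raise ValueError(f"no genes of panel {name!r} present in matrix")
        if len(present) < len(genes):
            logger.warning("panel %s: dropped %d absent genes", name,
                           len(genes) - len(present))
        rows[name] = z.values.loc[present].mean(axis=0)
    return pd.DataFrame(rows).T  # panels x clusters


@dataclass
class CellTypeAssignment:
    """Cluster -> label map with the panel z-summary behind it."""

    table: pd.DataFrame  # index cluster; columns: type, max_panel_z, lpc_flag
    panel_z: pd.DataFrame  # panels x clusters

    @property
    def mapping(self) -> dict[str, str]:
        return self.table["type"].to_dict()

    def cell_labels(self, clusters: pd.Series) -> pd.Series:
        return clusters.map(self.mapping).fillna("unassigned")


def assign_cell_types(z: ZScoreMatrix, panels: Mapping[str, Sequence[str]] | MarkerPanelSet,
                      min_z: float = 0.5) -> CellTypeAssignment:
    """Label each cluster with the argmax panel, floored at ``min_z``.

    Ties are broken deterministically by panel name order (the order
    of ``panels``); clusters whose best panel mean z falls below
    ``min_z`` are labelled ``"unassigned"``.
    """
    if isinstance(panels, MarkerPanelSet):
        panels = panels.panels
    pz = _panel_means(z, panels)
    types, best = [], []
    for c in pz.columns:
        col = pz[c]
        top = col.max()
        # first panel attaining the max, in panel declaration order
        winner = next(name for name in pz.index if col[name] == top)
        types.append(winner if top >= min_z else "unassigned")
        best.append(top)
    table = pd.DataFrame({"type": types, "max_panel_z": best}, index=pz.columns)
    return CellTypeAssignment(table=table, panel_z=pz)


def identify_lpc_clusters(z: ZScoreMatrix, panels: MarkerPanelSet | Mapping[str, Sequence[str]],
                          tau: float = 0.5) -> pd.Series:
    """Flag clusters co-elevating progenitor, hepatocyte and cholangiocyte panels.

    A cluster is the putative bipotent LPC cluster iff all three panel
    mean z-scores are >= ``tau``.  Flags are monotone non-increasing
    in ``tau``.
    """
    if isinstance(panels, MarkerPanelSet):
        panels = panels.panels
    for required in ("progenitor", "hepatocyte", "cholangiocyte"):
        if required not in panels:
            raise ValueError(f"panel set lacks {required!r}")
    pz = _panel_means(z, panels)
    flags = ((pz.loc["progenitor"] >= tau)
             & (pz.loc["hepatocyte"] >= tau)
             & (pz.loc["cholangiocyte"] >= tau))
    flags.name = "lpc_flag"
    return flags


def score_gene_module(adata: AnnData, gene_set: Sequence[str], *,
                      n_bins: int = 24, n_ctrl: int = 100,
                      seed: int = 0) -> np.ndarray:
    """Per-cell module score with expression-bin matched controls.

    Genes are ranked by mean log-normalised expression and cut into
    ``n_bins`` equal-frequency bins; each set gene contributes
    ``n_ctrl`` control genes sampled with replacement from its bin.
    The score is the per-cell mean expression of the set minus the
    mean over the pooled controls, so a cell with flat expression
    scores exactly zero.
    """
    present = [g for g in gene_set if g in adata.var_names]
    if not present:
        raise ValueError("gene set entirely absent from the matrix")
    if len(present) < len(gene_set):
        logger.warning("module score: dropped %d absent genes",
                       len(gene_set) - len(present))
    X = log_normalized(adata, dense=True)
    gene_means = X.mean(axis=0)
    # stable ordering: by mean, ties by gene name
    order = np.lexsort((np.asarray(adata.var_names), gene_means))
    bins = np.array_split(order, n_bins)
    bin_of = np.empty(adata.n_vars, dtype=int)
    for b, idx in enumerate(bins):
        bin_of[idx] = b
    gene_index = {g: j for j, g in enumerate(adata.var_names)}
    rng = np.random.default_rng(seed)
    ctrl_idx: list[np.ndarray] = []
    for g in present:
        pool = bins[bin_of[gene_index[g]]]
        if pool.size < n_ctrl:
            logger.info("bin of %s has %d < %d genes; sampling with replacement",
                        g, pool.size, n_ctrl)
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl = np.concatenate(ctrl_idx)
    set_idx = np.array([gene_index[g] for g in present])
    # shifted means: subtracting a per-cell reference value before averaging
    # keeps the score exactly zero for cells with flat expression
    ref = X[:, set_idx[0]][:, None]
    return (X[:, set_idx] - ref).mean(axis=1) - (X[:, ctrl] - ref).mean(axis=1)


@dataclass
class LPCProportionSummary:
    """Per-individual LPC share of the epithelial+LPC pool."""

    per_individual: pd.DataFrame  # individual, n_pool, n_lpc, proportion
    mean: float
    sd: float
    excluded: list[str] = field(default_factory=list)


def lpc_proportions(cell_types: pd.Series, individuals: pd.Series, *,
                    lpc_label: str = "LPC",
                    epithelial_labels: Sequence[str] = ("hepatocyte", "cholangiocyte"),
                    ) -> LPCProportionSummary:
    """LPC proportion among epithelial+LPC cells, per individual.

    The denominator pool is cells labelled hepatocyte, cholangiocyte
    or LPC; individuals with an empty pool are excluded (logged).
    Cohort mean and sample sd (ddof=1) are over included individuals.
    """
    df = pd.DataFrame({"type": np.asarray(cell_types),
                       "individual": np.asarray(individuals)})
    pool_labels = set(epithelial_labels) | {lpc_label}
    pool = df[df["type"].isin(pool_labels)]
    rows, excluded = [], []
    for ind, grp in df.groupby("individual", sort=True):
        sub = pool[pool["individual"] == ind]
        if len(sub) == 0:
            excluded.append(str(ind))
            logger.warning("individual %s has no epithelial+LPC cells; excluded", ind)
            continue
        n_lpc = int((sub["type"] == lpc_label).sum())
        rows.append({"individual": ind, "n_pool": len(sub), "n_lpc": n_lpc,
                     "proportion": n_lpc / len(sub)})
    per_ind = pd.DataFrame(rows)
    props = per_ind["proportion"].to_numpy()
    mean = float(props.mean()) if props.size else float("nan")
    sd = float(props.std(ddof=1)) if props.size > 1 else 0.0
    return LPCProportionSummary(per_individual=per_ind, mean=mean, sd=sd,
                                excluded=excluded)


def compare_subpopulation_proportions(per_group: Mapping[str, Sequence[float]]
                                      ) -> pd.DataFrame:
    """Pairwise two-sided rank-sum tests of proportion vectors."""
    return pairwise_rank_sum(per_group)
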