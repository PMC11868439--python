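"""Spatial colocalization statistics on cellbin centroid maps.

For each source cell (LPC by default) and each target cell type the
statistic is the mean Euclidean distance to the k nearest cells of
that type (k = 4 by default), computed from centroid coordinates.
Profiles are ranked by median to order types from spatially nearest
to farthest, clustered (ward.D on log, column-standardised rows) to
reveal source-cell neighbourhood groups, and complemented by
pseudo-bulk expression concordance between populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from .modules import LinkageTree, cut_modules, ward_d_linkage

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceProfiles",
    "knn_type_distance_profiles",
    "rank_colocalization",
    "cluster_distance_profiles",
    "pseudobulk_profile",
    "pseudobulk_correlation",
]


@dataclass
class DistanceProfiles:
    """Per-source-cell mean k-nearest distances to each target type.

    ``mean`` is source cells x types (NaN where a type has fewer than
    k eligible cells); ``raw`` keeps the individual k distances per
    type for audit.
    """

    mean: pd.DataFrame
    k: int
    source_type: str
    raw: dict[str, np.ndarray] = field(default_factory=dict)


def knn_type_distance_profiles(cells: pd.DataFrame, source_type: str,
                               k: int = 4) -> DistanceProfiles:
    """Mean distance from each source cell to the k nearest of each type.

    For the source cells' own type the source cell itself is excluded
    from the neighbour pool.  Types with fewer than k eligible cells
    yield NaN entries (recorded, never silently zero).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(cells) == 0:
        raise ValueError("empty cell map")
    types = sorted(cells["cell_type"].unique())
    if source_type not in types:
        raise ValueError(f"source type {source_type!r} absent from map")
    src = cells[cells["cell_type"] == source_type]
    src_xy = src[["x", "y"]].to_numpy(dtype=float)
    profile = pd.DataFrame(index=pd.Index(src["cell_id"], name="cell_id"),
                           columns=types, dtype=float)
    raw: dict[str, np.ndarray] = {}
    for t in types:
        tgt = cells[cells["cell_type"] == t]
        tgt_xy = tgt[["x", "y"]].to_numpy(dtype=float)
        self_type = t == source_type
        needed = k + 1 if self_type else k
        if len(tgt) < needed:
            logger.warning("type %s has %d cells (< %d needed for k=%d); NaN",
                           t, len(tgt), needed, k)
            profile[t] = np.nan
            raw[t] = np.full((len(src), k), np.nan)
            continue
        tree = cKDTree(tgt_xy)
        dist, _ = tree.query(src_xy, k=needed)
        dist = np.asarray(dist, dtype=float).reshape(len(src_xy), needed)
        if self_type:
            dist = dist[:, 1:]  # drop the zero self-distance
        raw[t] = dist
        profile[t] = dist.mean(axis=1)
    return DistanceProfiles(mean=profile, k=k, source_type=source_type, raw=raw)


def rank_colocalization(profiles: DistanceProfiles) -> pd.DataFrame:
    """Order target types by the median profile entry, ascending.

    All-missing columns are excluded (logged).  Returns a table of
    median, first and third quartile per type, nearest first.
    """
    rows = []
    for t in profiles.mean.columns:
        col = profiles.mean[t].dropna()
        if col.empty:
            logger.warning("type %s excluded from ranking: all entries missing", t)
            continue
        rows.append({"cell_type": t, "median": float(col.median()),
                     "q1": float(col.quantile(0.25)),
                     "q3": float(col.quantile(0.75)),
                     "n": int(col.size)})
    if not rows:
        raise ValueError("no valid columns to rank")
    out = pd.DataFrame(rows).sort_values("median", kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def cluster_distance_profiles(profiles: DistanceProfiles, k_groups: int,
                              ) -> tuple[pd.Series, LinkageTree]:
    """Group source cells by their distance profiles.

    Missing entries are imputed with the column median, rows are
    log1p-transformed and each column standardised, then clustered
    with the same ward.D engine as the cellular-module stage on
    Euclidean row distances and cut at ``k_groups``.
    """
    M = profiles.mean.copy()
    M = M.drop(columns=[c for c in M.columns if M[c].isna().all()])
    if len(M) < k_groups:
        raise ValueError("fewer source cells than requested groups")
    M = M.fillna(M.median())
    Z = np.log1p(M.to_numpy(dtype=float))
    mu = Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (Z - mu) / sd
    D = squareform(pdist(Z, metric="euclidean"))
    tree = ward_d_linkage(D, labels=[str(i) for i in M.index])
    groups = cut_modules(tree, k_groups)
    groups.index = M.index
    groups.name = "group"
    return groups, tree


# ---------------------------------------------------------------------------
# pseudo-bulk concordance
# ---------------------------------------------------------------------------

def pseudobulk_profile(adata: AnnData, cell_mask: np.ndarray | pd.Series | None = None,
                       label: str = "") -> pd.Series:
    """Aggregate a cell subset into one log1p(CPM) expression vector."""
    if cell_mask is None:
        mask = np.ones(adata.n_obs, dtype=bool)
    else:
        mask = np.asarray(cell_mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty cell subset")
    X = adata.X
    if sp.issparse(X):
        sums = np.asarray(X[mask].sum(axis=0)).ravel().astype(float)
    else:
        sums = np.asarray(X)[mask].sum(axis=0).astype(float)
    total = sums.sum()
    if total == 0:
        raise ValueError("subset has zero total counts")
    cpm = sums / total * 1e6
    out = pd.Series(np.log1p(cpm), index=adata.var_names, name=label or "pseudobulk")
    return out


def pseudobulk_from_gem(gem: pd.DataFrame, cell_ids: set[str] | None = None) -> pd.Series:
    """Pseudo-bulk from a GEM table (geneID, x, y, MIDCount [, cell_id])."""
    sub = gem if cell_ids is None else gem[gem["cell_id"].isin(cell_ids)]
    if len(sub) == 0:
        raise ValueError("empty GEM subset")
    sums = sub.groupby("geneID")["MIDCount"].sum().astype(float)
    cpm = sums / sums.sum() * 1e6
    return pd.Series(np.log1p(cpm.to_numpy()), index=sums.index, name="pseudobulk")


def pseudobulk_correlation(a: pd.Series, b: pd.Series) -> float:
    """Pearson r between two pseudo-bulk vectors on shared genes."""
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared genes")
    x = a.loc[shared].to_numpy(dtype=float)
    y = b.loc[shared].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance pseudo-bulk vector")
    return float(pearsonr(x, y).statistic)
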