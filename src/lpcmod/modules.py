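"""Cellular-module discovery from cluster-frequency correlations.

A cellular module (CM) is a group of cell clusters whose frequencies
covary across sample units (individuals by default).  The pipeline:
cluster-frequency table -> Pearson correlation across units ->
correlation distance d = 1 - r -> agglomerative "ward.D" clustering ->
cut at k modules -> rank-sum marker statistics per module.

The linkage applies the Lance-Williams recurrence with Ward
coefficients directly to the supplied (unsquared) dissimilarities —
the "ward.D" dialect.  The squared-input variant ("ward.D2", which
squares the dissimilarities before updating and reports square-root
heights) is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .expression import normalized_counts
from .stats import bh_adjust, rank_sum_test_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "LinkageTree",
    "cluster_frequency_table",
    "frequency_correlation",
    "ward_d_linkage",
    "cut_modules",
    "module_markers",
    "fraction_expressing",
]


def cluster_frequency_table(clusters: pd.Series | Sequence,
                            sample_units: pd.Series | Sequence) -> pd.DataFrame:
    """Cluster x unit proportion table; columns sum to one.

    Units with zero cells cannot occur by construction (units are taken
    from the per-cell labels); empty categorical levels are dropped
    with a log entry.
    """
    df = pd.DataFrame({"cluster": np.asarray(clusters, dtype=object),
                       "unit": np.asarray(sample_units, dtype=object)})
    counts = pd.crosstab(df["cluster"], df["unit"])
    empty = counts.columns[(counts.sum(axis=0) == 0)]
    if len(empty):
        logger.warning("dropping %d empty sample units", len(empty))
        counts = counts.drop(columns=list(empty))
    freq = counts / counts.sum(axis=0)
    freq.index.name = "cluster"
    freq.columns.name = "unit"
    return freq


def frequency_correlation(freq: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation between cluster rows, and d = 1 - r.

    Needs at least 3 sample units.  Zero-variance rows get r = 0
    against everything (logged); the diagonal stays 1.
    """
    if freq.shape[1] < 3:
        raise ValueError("correlation needs at least 3 sample units")
    values = freq.to_numpy(dtype=float)
    sd = values.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("%d zero-variance cluster rows; correlations set to 0",
                       int(degenerate.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values)
    r = np.where(np.isfinite(r), r, 0.0)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    corr = pd.DataFrame(r, index=freq.index, columns=freq.index)
    dist = 1.0 - corr
    np.fill_diagonal(dist.values, 0.0)
    return corr, dist


# ---------------------------------------------------------------------------
# ward.D linkage
# ---------------------------------------------------------------------------

@dataclass
class LinkageTree:
    """Agglomeration history: scipy-style merge matrix plus leaf labels.

    ``merges`` has one row per merge: [id_a, id_b, height, size] with
    leaves numbered 0..n-1 and internal nodes n, n+1, ... in merge
    order.
    """

    merges: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_scipy(self) -> np.ndarray:
        return np.asarray(self.merges, dtype=np.float64)

    def to_newick(self) -> str:
        """Newick string; branch lengths = parent height - child height."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for step, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            node[n + step] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[n + step] = h
        return node[n + self.n_leaves - 2] + ";"

    def to_nested_lists(self):
        """Nested [left, right] lists with leaf labels at the tips."""
        n = self.n_leaves
        node = {i: self.labels[i] for i in range(n)}
        for step, (a, b, _, _) in enumerate(self.merges):
            node[n + step] = [node[int(a)], node[int(b)]]
        return node[n + self.n_leaves - 2]


def ward_d_linkage(d: np.ndarray | pd.DataFrame, labels: Sequence[str] | None = None,
                   *, dialect: str = "ward.D") -> LinkageTree:
    """Agglomerative Ward clustering of a dissimilarity matrix.

    ``dialect="ward.D"`` feeds the supplied dissimilarities directly
    into the Lance-Williams recurrence

        d(k, i+j) = [(n_i+n_k) d(k,i) + (n_j+n_k) d(k,j) - n_k d(i,j)]
                    / (n_i + n_j + n_k);

    ``dialect="ward.D2"`` squares the input first and reports
    square-root merge heights.  The nearest active pair is merged at
    each step; ties are broken by the lexicographically smallest pair
    of cluster representatives (smallest contained leaf index).
    """
    if isinstance(d, pd.DataFrame):
        if labels is None:
            labels = [str(c) for c in d.index]
        d = d.to_numpy(dtype=float)
    D = np.asarray(d, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("dissimilarity matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("dissimilarities must be nonnegative")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("diagonal must be zero")
    if labels is None:
        labels = [str(i) for i in range(n)]
    if dialect not in ("ward.D", "ward.D2"):
        raise ValueError(f"unknown dialect {dialect!r}")

    D = (D + D.T) / 2.0  # enforce exact symmetry (inputs agree to rounding)
    work = D.astype(float).copy() if dialect == "ward.D" else D.astype(float) ** 2
    np.fill_diagonal(work, np.inf)
    sizes = np.ones(n)
    active = np.ones(n, dtype=bool)
    rep = np.arange(n)          # smallest leaf index in each cluster slot
    node_id = np.arange(n)      # scipy-style id of the cluster in each slot
    merges = np.zeros((n - 1, 4))

    for step in range(n - 1):
        idx = np.flatnonzero(active)
        sub = work[np.ix_(idx, idx)]
        m = sub.min()
        # tie-break: lexicographically smallest (rep_i, rep_j) pair
        cand = np.argwhere(np.isclose(sub, m, rtol=0.0, atol=0.0))
        best = None
        for a, b in cand:
            if a >= b:
                continue
            i, j = idx[a], idx[b]
            key = tuple(sorted((rep[i], rep[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        height = work[i, j] if dialect == "ward.D" else float(np.sqrt(work[i, j]))
        merges[step] = [node_id[i], node_id[j], height, sizes[i] + sizes[j]]

        ni, nj = sizes[i], sizes[j]
        others = idx[(idx != i) & (idx != j)]
        if others.size:
            nk = sizes[others]
            new = ((ni + nk) * work[i, others] + (nj + nk) * work[j, others]
                   - nk * work[i, j]) / (ni + nj + nk)
            work[i, others] = new
            work[others, i] = new
        sizes[i] = ni + nj
        rep[i] = min(rep[i], rep[j])
        node_id[i] = n + step
        active[j] = False
        work[j, :] = np.inf
        work[:, j] = np.inf

    return LinkageTree(merges=merges, labels=[str(x) for x in labels])


def cut_modules(tree: LinkageTree, k: int) -> pd.Series:
    """Partition leaves into ``k`` modules by undoing the last k-1 merges.

    Module ids 1..k are assigned by the order of each module's
    smallest leaf index (deterministic).
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b, _, _ = tree.merges[step]
        new = n + step
        parent[find(int(a))] = new
        parent[find(int(b))] = new
    roots = [find(i) for i in range(n)]
    first_leaf: dict[int, int] = {}
    for leaf, r in enumerate(roots):
        first_leaf.setdefault(r, leaf)
    order = sorted(first_leaf, key=first_leaf.get)
    module_of_root = {r: m + 1 for m, r in enumerate(order)}
    assignment = pd.Series([module_of_root[r] for r in roots],
                           index=tree.labels, name="module")
    return assignment


# ---------------------------------------------------------------------------
# module characterisation
# ---------------------------------------------------------------------------

def module_markers(adata: AnnData, modules: Mapping[str, int] | pd.Series, *,
                   cluster_key: str = "cluster", top_n: int = 250,
                   padj_max: float = 0.01, min_cells: int = 3
                   ) -> tuple[pd.DataFrame, dict[int, list[str]]]:
    """Per-module marker genes by two-sided Wilcoxon rank-sum tests.

    Each module's cells are tested against all other cells per gene
    (tie-corrected normal approximation), p-values are BH-adjusted
    within the module contrast, and the ``top_n`` upregulated genes
    (positive log2 fold-change of mean normalised expression, pseudocount
    1) with adjusted p below ``padj_max`` are retained, ranked by
    fold-change.
    """
    modules = pd.Series(modules)
    cell_modules = pd.Series(adata.obs[cluster_key], index=adata.obs_names).map(
        modules.to_dict())
    Xn = normalized_counts(adata)
    Xn_dense = np.asarray(Xn.todense())
    Xraw = adata.X
    expressed = (Xraw > 0) if sp.issparse(Xraw) else (np.asarray(Xraw) > 0)
    rows = []
    top_sets: dict[int, list[str]] = {}
    for m in sorted(pd.unique(modules.dropna())):
        mask = (cell_modules == m).to_numpy()
        if mask.sum() < min_cells or (~mask).sum() == 0:
            logger.warning("module %s has < %d cells; contrast skipped", m, min_cells)
            continue
        u, p = rank_sum_test_matrix(Xn_dense, mask)
        padj = bh_adjust(p)
        mean_in = Xn_dense[mask].mean(axis=0)
        mean_out = Xn_dense[~mask].mean(axis=0)
        log2fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        if sp.issparse(Xraw):
            frac_in = np.asarray(expressed[mask].mean(axis=0)).ravel()
            frac_out = np.asarray(expressed[~mask].mean(axis=0)).ravel()
        else:
            frac_in = expressed[mask].mean(axis=0)
            frac_out = expressed[~mask].mean(axis=0)
        frac_in = np.clip(frac_in, 0.0, 1.0)
        frac_out = np.clip(frac_out, 0.0, 1.0)
        table = pd.DataFrame({
            "module": m, "gene": adata.var_names, "log2fc": log2fc,
            "statistic": u, "pvalue": p, "padj": padj,
            "frac_in": frac_in, "frac_out": frac_out,
        })
        rows.append(table)
        sig = table[(table["padj"] < padj_max) & (table["log2fc"] > 0)]
        sig = sig.sort_values(["log2fc", "gene"], ascending=[False, True])
        top_sets[int(m)] = sig["gene"].head(top_n).tolist()
    if not rows:
        raise ValueError("no module had enough cells for a contrast")
    return pd.concat(rows, ignore_index=True), top_sets


def fraction_expressing(adata: AnnData, gene_sets: Mapping[int, Sequence[str]],
                        modules: Mapping[str, int] | pd.Series, *,
                        cluster_key: str = "cluster") -> pd.DataFrame:
    """Fraction of cells expressing each set, per module and complement.

    The per-set value is the fraction of cells with count > 0 averaged
    over the set's genes.
    """
    modules = pd.Series(modules)
    cell_modules = pd.Series(adata.obs[cluster_key], index=adata.obs_names).map(
        modules.to_dict())
    X = adata.X
    expressed = (X > 0) if sp.issparse(X) else (np.asarray(X) > 0)
    gene_index = {g: j for j, g in enumerate(adata.var_names)}
    rows = []
    for set_id, genes in gene_sets.items():
        if not len(genes):
            raise ValueError(f"gene set {set_id!r} is empty")
        cols = [gene_index[g] for g in genes if g in gene_index]
        for m in sorted(pd.unique(modules.dropna())):
            mask = (cell_modules == m).to_numpy()
            if sp.issparse(X):
                f_in = float(np.asarray(expressed[mask][:, cols].mean(axis=0)).mean())
                f_out = float(np.asarray(expressed[~mask][:, cols].mean(axis=0)).mean())
            else:
                f_in = float(expressed[np.ix_(mask, cols)].mean())
                f_out = float(expressed[np.ix_(~mask, cols)].mean())
            rows.append({"gene_set": set_id, "module": m,
                         "fraction_in": f_in, "fraction_out": f_out})
    return pd.DataFrame(rows)
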