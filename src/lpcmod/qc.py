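"""Cell- and gene-level quality control with an auditable report.

Rule order (recorded in the report): detected-gene bounds -> UMI floor
-> mitochondrial percentage -> ambient-contamination score -> top-rate
doublet removal -> gene prevalence filter.  Bound semantics follow the
filter definitions exactly: detected genes strictly above ``genes_min``
and strictly below ``genes_max``; UMI strictly above ``umi_min``; mito
percentage strictly below ``mito_max_pct``; contamination scores
strictly exceeding ``contamination_max`` are removed (a score equal to
the threshold is retained); genes must be detected in at least
``min_cells_per_gene`` retained cells (inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import scipy.sparse as sp
from anndata import AnnData

logger = logging.getLogger(__name__)

__all__ = ["QCConfig", "QCReport", "filter_cells", "filter_genes", "run_qc"]

RULE_ORDER = [
    "gene_count", "umi", "mito_pct", "contamination", "doublet_rate",
]


@dataclass
class QCConfig:
    genes_min: int = 200          # exclusive lower bound on detected genes
    genes_max: int = 6000         # exclusive upper bound on detected genes
    umi_min: int = 150            # exclusive lower bound on total UMI
    mito_max_pct: float = 50.0    # exclusive upper bound, percent
    min_cells_per_gene: int = 3   # inclusive
    contamination_max: float = 0.4  # removal is strict (> threshold)
    doublet_rate: float = 0.05    # fraction of remaining cells removed

    def __post_init__(self) -> None:
        if self.genes_min >= self.genes_max:
            raise ValueError("genes_min must be below genes_max")
        for name in ("genes_min", "umi_min", "mito_max_pct",
                     "min_cells_per_gene", "contamination_max", "doublet_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class QCReport:
    """Accounting of the filtering run; counts reconcile exactly.

    A removed cell is attributed to the first rule (in ``rule_order``)
    that rejects it.
    """

    n_cells_in: int = 0
    n_cells_out: int = 0
    n_genes_in: int = 0
    n_genes_out: int = 0
    removed_by_rule: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    rule_order: list[str] = field(default_factory=lambda: list(RULE_ORDER))

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def check_conservation(self) -> None:
        removed = sum(v for k, v in self.removed_by_rule.items() if k != "gene_prevalence")
        if self.n_cells_out + removed != self.n_cells_in:
            raise AssertionError("QC report cell counts do not reconcile")
        gene_removed = self.removed_by_rule.get("gene_prevalence", 0)
        if self.n_genes_out + gene_removed != self.n_genes_in:
            raise AssertionError("QC report gene counts do not reconcile")


def _dense_stats(adata: AnnData) -> tuple[np.ndarray, np.ndarray]:
    X = adata.X
    if sp.issparse(X):
        X = X.tocsr()
        detected = X.getnnz(axis=1)
        umi = np.asarray(X.sum(axis=1)).ravel()
    else:
        X = np.asarray(X)
        detected = (X > 0).sum(axis=1)
        umi = X.sum(axis=1)
    return np.asarray(detected).ravel(), umi


def _mito_fraction(adata: AnnData, report: QCReport) -> np.ndarray:
    if "mito_fraction" in adata.obs:
        return adata.obs["mito_fraction"].to_numpy(dtype=float)
    if "is_mito" in adata.var:
        mask = adata.var["is_mito"].to_numpy(dtype=bool)
        X = adata.X
        if sp.issparse(X):
            mito = np.asarray(X[:, mask].sum(axis=1)).ravel()
            total = np.asarray(X.sum(axis=1)).ravel()
        else:
            X = np.asarray(X)
            mito = X[:, mask].sum(axis=1)
            total = X.sum(axis=1)
        report.warnings.append("mito_fraction recomputed from is_mito genes")
        return np.divide(mito, total, out=np.zeros_like(mito, dtype=float),
                         where=total > 0)
    report.warnings.append("mito rule skipped: no mito_fraction or is_mito")
    return np.zeros(adata.n_obs)


def filter_cells(adata: AnnData, cfg: QCConfig) -> tuple[AnnData, QCReport]:
    """Apply the four metric thresholds plus the doublet-rate removal.

    Returns the retained cells (genes untouched) and a report whose
    per-rule removal counts sum with the survivors to the input count.
    """
    if (sp.issparse(adata.X) and (adata.X.data < 0).any()) or \
            (not sp.issparse(adata.X) and (np.asarray(adata.X) < 0).any()):
        raise ValueError("counts must be nonnegative")
    report = QCReport(n_cells_in=adata.n_obs, n_genes_in=adata.n_vars,
                      n_genes_out=adata.n_vars)
    detected, umi = _dense_stats(adata)
    mito_pct = 100.0 * _mito_fraction(adata, report)

    alive = np.ones(adata.n_obs, dtype=bool)

    def apply_rule(name: str, bad: np.ndarray) -> None:
        newly = bad & alive
        report.removed_by_rule[name] = int(newly.sum())
        alive[newly] = False

    apply_rule("gene_count",
               ~((detected > cfg.genes_min) & (detected < cfg.genes_max)))
    apply_rule("umi", ~(umi > cfg.umi_min))
    apply_rule("mito_pct", ~(mito_pct < cfg.mito_max_pct))

    if "contamination_score" in adata.obs:
        contam = adata.obs["contamination_score"].to_numpy(dtype=float)
        apply_rule("contamination", contam > cfg.contamination_max)
    else:
        report.warnings.append("contamination rule skipped: column missing")
        report.removed_by_rule["contamination"] = 0

    if "doublet_score" in adata.obs and cfg.doublet_rate > 0:
        idx = np.flatnonzero(alive)
        n_remove = int(np.floor(cfg.doublet_rate * idx.size))
        if n_remove > 0:
            scores = adata.obs["doublet_score"].to_numpy(dtype=float)[idx]
            # stable sort: ties resolved by cell order (cell_id order)
            order = np.argsort(-scores, kind="stable")
            drop = idx[order[:n_remove]]
            bad = np.zeros(adata.n_obs, dtype=bool)
            bad[drop] = True
            apply_rule("doublet_rate", bad)
        else:
            report.removed_by_rule["doublet_rate"] = 0
    else:
        if "doublet_score" not in adata.obs:
            report.warnings.append("doublet rule skipped: column missing")
        report.removed_by_rule["doublet_rate"] = 0

    out = adata[alive].copy()
    report.n_cells_out = out.n_obs
    report.check_conservation()
    return out, report


def filter_genes(adata: AnnData, cfg: QCConfig,
                 report: QCReport | None = None) -> AnnData:
    """Keep genes detected (count > 0) in >= ``min_cells_per_gene`` cells.

    Expects cell filtering to have been applied already.
    """
    if adata.n_obs == 0:
        raise ValueError("no cells left before gene filtering")
    X = adata.X
    if sp.issparse(X):
        prevalence = np.asarray((X > 0).sum(axis=0)).ravel()
    else:
        prevalence = (np.asarray(X) > 0).sum(axis=0)
    keep = prevalence >= cfg.min_cells_per_gene
    if not keep.any():
        raise ValueError("gene filter removed every gene")
    out = adata[:, keep].copy()
    if report is not None:
        report.removed_by_rule["gene_prevalence"] = int((~keep).sum())
        report.n_genes_out = out.n_vars
        report.check_conservation()
    return out


def run_qc(adata: AnnData, cfg: QCConfig | None = None) -> tuple[AnnData, QCReport]:
    """Cell filtering followed by gene filtering, with one report."""
    cfg = cfg or QCConfig()
    filtered, report = filter_cells(adata, cfg)
    filtered = filter_genes(filtered, cfg, report)
    return filtered, report
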