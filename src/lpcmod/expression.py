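"""Expression normalisation helpers shared across stages.

All downstream statistics (cluster z-scores, module scores, marker
tests) run on library-size normalised expression: counts scaled to a
common total per cell (counts-per-10k by default), optionally log1p
transformed.  Pseudo-bulk uses counts-per-million on summed counts.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from anndata import AnnData

__all__ = ["normalized_counts", "log_normalized", "TARGET_SUM"]

TARGET_SUM = 1e4


def _counts_matrix(adata: AnnData) -> sp.csr_matrix:
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(np.asarray(X))
    return X.tocsr().astype(np.float64)


def normalized_counts(adata: AnnData, target_sum: float = TARGET_SUM) -> sp.csr_matrix:
    """Counts scaled so every cell sums to ``target_sum`` (CP10K)."""
    X = _counts_matrix(adata)
    totals = np.asarray(X.sum(axis=1)).ravel()
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals), where=totals > 0)
    return sp.diags(scale) @ X


def log_normalized(adata: AnnData, target_sum: float = TARGET_SUM,
                   dense: bool = False) -> sp.csr_matrix | np.ndarray:
    """log1p of counts-per-``target_sum`` normalised expression."""
    X = normalized_counts(adata, target_sum)
    X.data = np.log1p(X.data)
    if dense:
        return np.asarray(X.todense())
    return X
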