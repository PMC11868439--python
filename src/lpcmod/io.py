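"""Readers and writers for the on-disk exchange formats.

A single-cell cohort travels as a Matrix-Market + TSV bundle
(``matrix.mtx`` genes x cells, ``genes.tsv``, ``cells.tsv``), the
spatial cell map as a centroid CSV (``cell_id,x,y,cell_type``), and
spatial expression optionally as a Stereo-seq style GEM TSV
(``geneID, x, y, MIDCount``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.io import mmread, mmwrite

__all__ = [
    "write_cohort_bundle",
    "read_cohort_bundle",
    "write_cell_map",
    "read_cell_map",
    "write_gem",
    "read_gem",
    "write_json",
]

CELL_COLUMNS = [
    "cell_id", "individual", "condition", "cluster",
    "mito_fraction", "contamination_score", "doublet_score",
]


def write_cohort_bundle(adata: AnnData, outdir: str | Path) -> Path:
    """Write counts + metadata as matrix.mtx / genes.tsv / cells.tsv.

    The matrix is stored genes x cells (the common exchange
    convention); cell order in ``cells.tsv`` matches matrix columns.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(np.asarray(X))
    mmwrite(str(outdir / "matrix.mtx"), X.T.tocoo(), field="integer")

    genes = pd.DataFrame({"gene_id": adata.var_names})
    for col in ("is_mito", "marker_of"):
        if col in adata.var:
            genes[col] = adata.var[col].to_numpy()
    genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)

    cells = pd.DataFrame({"cell_id": adata.obs_names})
    for col in adata.obs.columns:
        cells[col] = adata.obs[col].to_numpy()
    cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    return outdir


def read_cohort_bundle(indir: str | Path) -> AnnData:
    """Read a matrix.mtx / genes.tsv / cells.tsv bundle into AnnData."""
    indir = Path(indir)
    for name in ("matrix.mtx", "genes.tsv", "cells.tsv"):
        if not (indir / name).exists():
            raise FileNotFoundError(f"missing bundle member {indir / name}")
    X = sp.csr_matrix(mmread(str(indir / "matrix.mtx")).T)
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", dtype={"gene_id": str})
    cells = pd.read_csv(indir / "cells.tsv", sep="\t", dtype={"cell_id": str})
    var = genes.set_index("gene_id")
    obs = cells.set_index("cell_id")
    adata = AnnData(X=X, obs=obs, var=var)
    return adata


def write_cell_map(cells: pd.DataFrame, path: str | Path) -> Path:
    """Write a centroid table (cell_id, x, y, cell_type) as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cells[["cell_id", "x", "y", "cell_type"]].to_csv(path, index=False)
    return path


def read_cell_map(path: str | Path) -> pd.DataFrame:
    cells = pd.read_csv(path, dtype={"cell_id": str, "cell_type": str})
    required = {"cell_id", "x", "y", "cell_type"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"centroid CSV missing columns: {sorted(missing)}")
    return cells


def write_gem(gem: pd.DataFrame, path: str | Path) -> Path:
    """Write a GEM-style TSV (geneID, x, y, MIDCount [, cell_id])."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gem.to_csv(path, sep="\t", index=False)
    return path


def read_gem(path: str | Path) -> pd.DataFrame:
    gem = pd.read_csv(path, sep="\t")
    required = {"geneID", "x", "y", "MIDCount"}
    missing = required - set(gem.columns)
    if missing:
        raise ValueError(f"GEM TSV missing columns: {sorted(missing)}")
    return gem


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=_default) + "\n")
    return path
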