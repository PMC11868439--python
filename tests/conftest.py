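"""Shared fixtures: tiny hand-built matrices and seeded simulations."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

from lpcmod.simulate import CohortSimConfig, simulate_cohort


def make_adata(counts, obs=None, var=None, genes=None, cells=None):
    """Build a small AnnData from a dense count array."""
    counts = np.asarray(counts)
    n, g = counts.shape
    cells = cells or [f"cell_{i}" for i in range(n)]
    genes = genes or [f"g{j}" for j in range(g)]
    obs = pd.DataFrame(obs or {}, index=pd.Index(cells, name="cell_id"))
    var = pd.DataFrame(var or {}, index=pd.Index(genes, name="gene_id"))
    return AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort simulation shared across tests."""
    adata, truth = simulate_cohort(CohortSimConfig(seed=11))
    return adata, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
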