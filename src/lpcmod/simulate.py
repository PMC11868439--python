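"""Synthetic single-cell cohorts and spatial cellbin maps with planted truth.

The cohort generator emulates the statistical structure the downstream
stages assume, without emulating any real dataset:

* per-individual cell-type composition follows a logistic-normal model:
  softmax of log baseline frequencies plus latent-factor loadings (so
  groups of types covary across individuals) plus independent noise;
* a rare bipotent liver-progenitor (LPC) population is planted at a
  per-individual fraction of the epithelial (hepatocyte +
  cholangiocyte) + LPC pool, drawn from a truncated normal;
* counts are negative-binomial (gamma-Poisson) with a shared dispersion
  and lognormal per-cell library sizes; marker genes of each type get a
  planted log2 fold-change, and LPC cells elevate hepatocyte,
  cholangiocyte and progenitor panels simultaneously;
* ambient-contamination and doublet scores are drawn from Beta
  mixtures with a small "bad cell" component, and a small high-mito
  subpopulation is planted, so the QC thresholds have work to do.

The spatial generator places cholangiocytes as a Thomas cluster
process, LPCs as Gaussian displacements around cholangiocyte parents
(attraction), and the remaining types uniformly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

logger = logging.getLogger(__name__)

__all__ = [
    "CellTypeSpec",
    "CohortSimConfig",
    "SpatialSimConfig",
    "simulate_cohort",
    "simulate_frequency_table",
    "simulate_spatial",
    "default_cell_types",
]

LPC_NAME = "LPC"

HEPATOCYTE_MARKERS = ["PCK1", "TF", "ALB", "HP"]
CHOLANGIOCYTE_MARKERS = ["SOX9", "KRT7", "KRT18", "SOX4"]
PROGENITOR_MARKERS = ["EPCAM", "PCNA", "HNF1A", "CDK1", "CD24", "TACSTD2", "NFKB1"]
REGENERATION_SET = [
    "EPCAM", "TACSTD2", "FGFR2", "TM4SF4", "CLDN1", "ANXA4", "WWTR1",
    "MYC", "STMN1", "PSMA4", "SNRPB", "ERH", "NME1", "TMEM14B",
]


@dataclass
class CellTypeSpec:
    """A simulated cell type: its name and marker fold-changes.

    ``markers`` maps gene name -> log2 fold-change of that gene's
    expected expression in this type relative to baseline.
    """

    name: str
    markers: dict[str, float] = field(default_factory=dict)


def default_cell_types() -> list[CellTypeSpec]:
    """Liver-like default type set with planted marker panels.

    The LPC type co-elevates hepatocyte, cholangiocyte and progenitor
    panels (the bipotency signature) plus the regeneration gene set at
    a weaker effect.
    """
    lfc = 3.0
    lpc_markers = {g: lfc for g in HEPATOCYTE_MARKERS + CHOLANGIOCYTE_MARKERS + PROGENITOR_MARKERS}
    for g in REGENERATION_SET:
        lpc_markers.setdefault(g, 1.5)
    return [
        CellTypeSpec("hepatocyte", {g: lfc for g in HEPATOCYTE_MARKERS}),
        CellTypeSpec("cholangiocyte", {g: lfc for g in CHOLANGIOCYTE_MARKERS}),
        CellTypeSpec(LPC_NAME, lpc_markers),
        CellTypeSpec("endothelial", {g: lfc for g in ["PECAM1", "VWF", "CDH5", "ENG"]}),
        CellTypeSpec("HSC", {g: lfc for g in ["ACTA2", "COL1A1", "DCN", "PDGFRB"]}),
        CellTypeSpec("macrophage", {g: lfc for g in ["CD68", "CD163", "LYZ", "MARCO"]}),
        CellTypeSpec("T_cell", {g: lfc for g in ["CD3D", "CD3E", "IL7R", "TRAC"]}),
    ]


def _default_conditions() -> dict[str, int]:
    # one condition per simulated individual; 42 individuals total
    return {"FL": 6, "HL": 14, "CL": 5, "TL": 9, "TLA": 8}


def _default_baseline() -> dict[str, float]:
    return {
        "hepatocyte": 0.45,
        "cholangiocyte": 0.08,
        "endothelial": 0.12,
        "HSC": 0.08,
        "macrophage": 0.15,
        "T_cell": 0.12,
    }


def _default_loadings() -> dict[str, Sequence[float]]:
    # two latent factors: epithelial covariation and immune covariation
    return {
        "hepatocyte": (0.8, 0.0),
        "cholangiocyte": (0.8, 0.0),
        "macrophage": (0.0, 0.8),
        "T_cell": (0.0, 0.8),
    }


@dataclass
class CohortSimConfig:
    """Parameters of the synthetic single-cell cohort.

    Defaults follow the study conditions downstream stages are
    calibrated against: 42 individuals over five condition labels, a
    planted LPC fraction of 2.95% +/- 1.91% of the epithelial+LPC pool,
    marker log2 fold-change 3, and two latent composition factors.
    """

    n_individuals: int = 42
    conditions: Mapping[str, int] = field(default_factory=_default_conditions)
    cell_types: list[CellTypeSpec] = field(default_factory=default_cell_types)
    baseline_freqs: Mapping[str, float] | Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_baseline)
    module_loadings: Mapping[str, Sequence[float]] = field(default_factory=_default_loadings)
    freq_noise_sd: float = 0.3
    lpc_fraction_mean: float = 0.0295
    lpc_fraction_sd: float = 0.0191
    cells_per_individual: int = 250
    n_genes: int = 600
    genes: list[str] | None = None
    nb_dispersion: float = 2.0
    libsize_log_mean: float = math.log(2500.0)
    libsize_log_sd: float = 0.35
    mito_gene_count: int = 13
    mito_weight: float = 0.08
    high_mito_fraction: float = 0.02
    high_mito_boost: float = 25.0
    contamination_beta_params: tuple[float, float] = (1.5, 20.0)
    contamination_bad_beta_params: tuple[float, float] = (8.0, 4.0)
    contamination_bad_fraction: float = 0.04
    doublet_beta_params: tuple[float, float] = (1.5, 12.0)
    seed: int = 0
    lpc_name: str = LPC_NAME

    def __post_init__(self) -> None:
        if sum(self.conditions.values()) != self.n_individuals:
            raise ValueError(
                f"condition sizes sum to {sum(self.conditions.values())}, "
                f"expected n_individuals={self.n_individuals}")
        if not 0.0 < self.lpc_fraction_mean < 1.0:
            if self.lpc_name in {t.name for t in self.cell_types}:
                raise ValueError("lpc_fraction_mean must lie in (0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for cond, base in self._baseline_by_condition().items():
            total = sum(base.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(
                    f"baseline_freqs for condition {cond!r} sum to {total}, not 1")
        universe = set(self.gene_universe())
        for spec in self.cell_types:
            missing = set(spec.markers) - universe
            if missing:
                raise ValueError(
                    f"marker genes of {spec.name!r} absent from gene universe: "
                    f"{sorted(missing)}")

    # -- derived structure -------------------------------------------------

    def non_lpc_types(self) -> list[CellTypeSpec]:
        return [t for t in self.cell_types if t.name != self.lpc_name]

    def lpc_type(self) -> CellTypeSpec | None:
        for t in self.cell_types:
            if t.name == self.lpc_name:
                return t
        return None

    def _baseline_by_condition(self) -> dict[str, dict[str, float]]:
        base = dict(self.baseline_freqs)
        if base and isinstance(next(iter(base.values())), Mapping):
            return {c: dict(v) for c, v in base.items()}
        return {c: dict(base) for c in self.conditions}

    def mito_genes(self) -> list[str]:
        return [f"MT-{i + 1}" for i in range(self.mito_gene_count)]

    def gene_universe(self) -> list[str]:
        """Marker genes, regeneration set, mito genes, then filler genes."""
        if self.genes is not None:
            return list(self.genes)
        named: list[str] = []
        seen: set[str] = set()
        for spec in self.cell_types:
            for g in spec.markers:
                if g not in seen:
                    named.append(g)
                    seen.add(g)
        for g in REGENERATION_SET:
            if g not in seen:
                named.append(g)
                seen.add(g)
        mito = self.mito_genes()
        n_filler = self.n_genes - len(named) - len(mito)
        if n_filler < 0:
            raise ValueError("n_genes too small for marker + mito genes")
        filler = [f"GENE_{i + 1:04d}" for i in range(n_filler)]
        return named + mito + filler


# ---------------------------------------------------------------------------
# composition model
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    """Truncated-normal draws whose mean and sd equal the targets.

    The underlying location and scale are moment-matched so that the
    (0, 1)-truncated distribution itself has the requested mean and sd
    (plain clipping or naive truncation would bias the mean upward when
    the target mean sits within ~2 sd of zero).
    """
    if sd <= 0:
        return np.full(size, mean)
    from scipy.optimize import fsolve
    from scipy.stats import truncnorm

    def moments(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    (mu, log_sigma), _, ok, _ = fsolve(moments, [mean, np.log(sd)],
                                       full_output=True)
    if ok != 1:
        mu, log_sigma = mean, np.log(sd)
    sigma = float(np.exp(log_sigma))
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)


def _individual_table(config: CohortSimConfig) -> pd.DataFrame:
    rows = []
    for cond, n in config.conditions.items():
        for i in range(n):
            rows.append({"individual": f"{cond}_{i + 1:02d}", "condition": cond})
    return pd.DataFrame(rows)


def _type_frequencies(config: CohortSimConfig, rng: np.random.Generator
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Expected per-individual type frequencies and planted LPC fractions.

    Non-LPC frequencies are softmax(log baseline + loadings . f_i +
    noise); the LPC type is then inserted so that its share of the
    epithelial+LPC pool equals the planted per-individual fraction.
    """
    individuals = _individual_table(config)
    baselines = config._baseline_by_condition()
    types = [t.name for t in config.non_lpc_types()]
    loadings = np.zeros((len(types), 0))
    if config.module_loadings:
        n_factors = max(len(v) for v in config.module_loadings.values())
        loadings = np.zeros((len(types), n_factors))
        for j, name in enumerate(types):
            if name in config.module_loadings:
                v = np.asarray(config.module_loadings[name], dtype=float)
                loadings[j, : v.size] = v
    freqs = np.zeros((len(individuals), len(types)))
    for i, row in individuals.iterrows():
        base = baselines[row["condition"]]
        logit = np.log([base[t] for t in types])
        if loadings.shape[1]:
            f_i = rng.standard_normal(loadings.shape[1])
            logit = logit + loadings @ f_i
        logit = logit + rng.normal(0.0, config.freq_noise_sd, size=len(types))
        e = np.exp(logit - logit.max())
        freqs[i] = e / e.sum()
    freq_df = pd.DataFrame(freqs, index=individuals["individual"], columns=types)

    lpc_planted = pd.Series(0.0, index=freq_df.index, name="planted_lpc_fraction")
    if config.lpc_type() is not None:
        draws = _truncated_normal(rng, config.lpc_fraction_mean,
                                  config.lpc_fraction_sd, size=len(freq_df))
        lo, hi = 1e-4, 1.0 - 1e-4
        if (draws <= 0).any() or (draws >= 1).any():
            logger.warning("clipped %d planted LPC fractions into (0, 1)",
                           int(((draws <= 0) | (draws >= 1)).sum()))
        draws = np.clip(draws, lo, hi)
        lpc_planted[:] = draws
        epi = freq_df[["hepatocyte", "cholangiocyte"]].sum(axis=1) \
            if {"hepatocyte", "cholangiocyte"} <= set(freq_df.columns) \
            else freq_df.sum(axis=1)
        w = draws * epi / (1.0 - draws)
        freq_df[config.lpc_name] = w
        freq_df = freq_df.div(freq_df.sum(axis=1), axis=0)
    freq_df.attrs["condition"] = dict(
        zip(individuals["individual"], individuals["condition"]))
    return freq_df, lpc_planted


def simulate_frequency_table(config: CohortSimConfig, seed: int | None = None
                             ) -> pd.DataFrame:
    """Realised cluster-frequency table (types x individuals).

    Draws expected frequencies from the logistic-normal model and a
    multinomial cell count per individual; columns sum to 1.  This is
    the fast path for composition-only experiments (no expression).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    freq_df, _ = _type_frequencies(config, rng)
    counts = np.vstack([
        rng.multinomial(config.cells_per_individual, p)
        for p in freq_df.to_numpy()
    ])
    realized = counts / counts.sum(axis=1, keepdims=True)
    out = pd.DataFrame(realized, index=freq_df.index, columns=freq_df.columns).T
    out.attrs["condition"] = freq_df.attrs.get("condition", {})
    return out


# ---------------------------------------------------------------------------
# expression model
# ---------------------------------------------------------------------------

def _gene_weights(config: CohortSimConfig, rng: np.random.Generator,
                  genes: list[str]) -> np.ndarray:
    """Baseline relative expression weights per gene.

    Filler genes draw lognormal weights; named marker genes sit at the
    median filler weight (so a log2FC of 3 yields close to an 8x mean
    count ratio after renormalisation); mito genes share a fixed total
    ``mito_weight`` of the library.
    """
    weights = rng.lognormal(0.0, 1.0, size=len(genes))
    med = float(np.median(weights))
    named = {g for t in config.cell_types for g in t.markers} | set(REGENERATION_SET)
    mito = set(config.mito_genes())
    for j, g in enumerate(genes):
        if g in named:
            weights[j] = med
    nonmito_total = sum(w for j, w in enumerate(weights) if genes[j] not in mito)
    if mito:
        per_mito = config.mito_weight * nonmito_total / ((1 - config.mito_weight) * len(mito))
        for j, g in enumerate(genes):
            if g in mito:
                weights[j] = per_mito
    return weights


def simulate_cohort(config: CohortSimConfig) -> tuple[AnnData, pd.DataFrame]:
    """Simulate a single-cell cohort with planted ground truth.

    Returns
    -------
    adata
        Cells x genes sparse counts; ``obs`` carries cell_id (index),
        individual, condition, true_type, cluster (anonymised 1:1 with
        true type), mito_fraction (recomputed from counts),
        contamination_score and doublet_score; ``var`` carries is_mito
        and marker_of.
    truth
        Per-individual realised type fractions, the planted and
        realised LPC fraction of the epithelial+LPC pool, and the
        condition label.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_universe()
    gene_index = {g: j for j, g in enumerate(genes)}
    freq_df, lpc_planted = _type_frequencies(config, rng)
    type_names = list(freq_df.columns)

    # per-type expression weight profiles
    base_w = _gene_weights(config, rng, genes)
    profiles = np.zeros((len(type_names), len(genes)))
    spec_by_name = {t.name: t for t in config.cell_types}
    for ti, name in enumerate(type_names):
        w = base_w.copy()
        for g, lfc in spec_by_name[name].markers.items():
            w[gene_index[g]] *= 2.0 ** lfc
        profiles[ti] = w / w.sum()

    # draw cells
    n_ind = len(freq_df)
    type_counts = np.vstack([
        rng.multinomial(config.cells_per_individual, p)
        for p in freq_df.to_numpy()
    ])
    ind_idx = np.repeat(np.arange(n_ind), config.cells_per_individual)
    type_idx = np.concatenate([
        np.repeat(np.arange(len(type_names)), type_counts[i]) for i in range(n_ind)
    ])
    n_cells = type_idx.size

    libsize = rng.lognormal(config.libsize_log_mean, config.libsize_log_sd, size=n_cells)
    P = profiles[type_idx]

    # planted high-mito cells
    mito_cols = np.array([gene_index[g] for g in config.mito_genes()], dtype=int) \
        if config.mito_gene_count else np.array([], dtype=int)
    if mito_cols.size and config.high_mito_fraction > 0:
        bad_mito = rng.random(n_cells) < config.high_mito_fraction
        if bad_mito.any():
            P = P.copy()
            P[np.ix_(bad_mito, mito_cols)] *= config.high_mito_boost
            P[bad_mito] /= P[bad_mito].sum(axis=1, keepdims=True)

    mu = libsize[:, None] * P
    theta = config.nb_dispersion
    lam = rng.gamma(theta, mu / theta)
    counts = rng.poisson(lam)
    X = sp.csr_matrix(counts, dtype=np.int64)

    # metadata
    conditions = freq_df.attrs["condition"]
    individuals = np.asarray(freq_df.index)[ind_idx]
    cond = np.asarray([conditions[i] for i in freq_df.index])[ind_idx]
    true_type = np.asarray(type_names)[type_idx]
    cluster_of_type = {name: f"C{j:02d}" for name, j in
                       zip(type_names, rng.permutation(len(type_names)))}
    cluster = np.asarray([cluster_of_type[t] for t in true_type])

    totals = counts.sum(axis=1)
    mito_counts = counts[:, mito_cols].sum(axis=1) if mito_cols.size else np.zeros(n_cells)
    mito_fraction = np.divide(mito_counts, totals, out=np.zeros(n_cells, float),
                              where=totals > 0)

    bad = rng.random(n_cells) < config.contamination_bad_fraction
    a0, b0 = config.contamination_beta_params
    a1, b1 = config.contamination_bad_beta_params
    contamination = np.where(bad, rng.beta(a1, b1, n_cells), rng.beta(a0, b0, n_cells))
    doublet = rng.beta(*config.doublet_beta_params, size=n_cells)

    obs = pd.DataFrame({
        "individual": individuals,
        "condition": cond,
        "true_type": true_type,
        "cluster": cluster,
        "mito_fraction": mito_fraction,
        "contamination_score": contamination,
        "doublet_score": doublet,
    }, index=pd.Index([f"cell_{i + 1:06d}" for i in range(n_cells)], name="cell_id"))

    marker_of = []
    for g in genes:
        owners = [t.name for t in config.cell_types if g in t.markers]
        marker_of.append(",".join(owners))
    var = pd.DataFrame({
        "is_mito": [g in set(config.mito_genes()) for g in genes],
        "marker_of": marker_of,
    }, index=pd.Index(genes, name="gene_id"))

    adata = AnnData(X=X, obs=obs, var=var)
    adata.uns["cluster_of_type"] = cluster_of_type

    realized = type_counts / type_counts.sum(axis=1, keepdims=True)
    truth = pd.DataFrame(realized, index=freq_df.index, columns=type_names)
    if config.lpc_name in truth.columns:
        epi_cols = [c for c in ("hepatocyte", "cholangiocyte") if c in truth.columns]
        pool = truth[epi_cols].sum(axis=1) + truth[config.lpc_name]
        with np.errstate(invalid="ignore"):
            truth["realized_lpc_fraction"] = truth[config.lpc_name] / pool
        truth["planted_lpc_fraction"] = lpc_planted
    truth["condition"] = [conditions[i] for i in truth.index]
    return adata, truth


# ---------------------------------------------------------------------------
# spatial model
# ---------------------------------------------------------------------------

@dataclass
class SpatialSimConfig:
    """Parameters of the synthetic spatial cellbin map.

    Cholangiocytes form Thomas-process clusters; LPCs are displaced
    from cholangiocyte parents by an isotropic Gaussian of scale
    ``lpc_attraction_sd``; ``background_types`` are uniform.  Expected
    counts are totals over the window (micrometer-like units).
    """

    window: tuple[float, float] = (1000.0, 1000.0)
    cho_expected_parents: float = 15.0
    cho_offspring_mean: float = 20.0
    cho_cluster_spread: float = 30.0
    lpc_expected: float = 100.0
    lpc_attraction_sd: float = 20.0
    background_types: Mapping[str, float] = field(default_factory=lambda: {
        "hepatocyte": 400.0, "endothelial": 150.0, "HSC": 100.0})
    cho_name: str = "cholangiocyte"
    lpc_name: str = LPC_NAME
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.window
        if w <= 0 or h <= 0:
            raise ValueError("window area must be positive")
        if self.lpc_attraction_sd < 0:
            raise ValueError("lpc_attraction_sd must be nonnegative")
        for name, lam in {**dict(self.background_types),
                          self.lpc_name: self.lpc_expected,
                          "cho_parents": self.cho_expected_parents}.items():
            if lam < 0:
                raise ValueError(f"negative intensity for {name!r}")


def _inside_draw(rng: np.random.Generator, centers: np.ndarray, sd: float,
                 window: tuple[float, float]) -> np.ndarray:
    """Gaussian displacements resampled until inside the window."""
    w, h = window
    pts = centers + rng.normal(0.0, sd, size=centers.shape)
    for _ in range(100):
        bad = (pts[:, 0] < 0) | (pts[:, 0] > w) | (pts[:, 1] < 0) | (pts[:, 1] > h)
        if not bad.any():
            break
        pts[bad] = centers[bad] + rng.normal(0.0, sd, size=(int(bad.sum()), 2))
    np.clip(pts[:, 0], 0, w, out=pts[:, 0])
    np.clip(pts[:, 1], 0, h, out=pts[:, 1])
    return pts


def simulate_spatial(config: SpatialSimConfig) -> pd.DataFrame:
    """Simulate a cellbin centroid map (cell_id, x, y, cell_type)."""
    rng = np.random.default_rng(config.seed)
    w, h = config.window
    records: list[tuple[float, float, str]] = []

    need_parents = config.lpc_expected > 0 or config.cho_offspring_mean > 0
    n_parents = rng.poisson(config.cho_expected_parents)
    tries = 0
    while n_parents == 0 and need_parents and config.cho_expected_parents > 0:
        tries += 1
        if tries > 1000:
            raise RuntimeError("failed to draw cholangiocyte parents")
        logger.warning("zero cholangiocyte parents drawn; redrawing")
        n_parents = rng.poisson(config.cho_expected_parents)
    parents = np.column_stack([rng.uniform(0, w, n_parents),
                               rng.uniform(0, h, n_parents)])

    if n_parents:
        n_off = rng.poisson(config.cho_offspring_mean, size=n_parents)
        centers = np.repeat(parents, n_off, axis=0)
        if len(centers):
            pts = _inside_draw(rng, centers, config.cho_cluster_spread, config.window)
            records.extend((x, y, config.cho_name) for x, y in pts)

    n_lpc = rng.poisson(config.lpc_expected)
    if n_lpc:
        if n_parents == 0:
            raise RuntimeError("LPC intensity positive but no cholangiocyte parents")
        chosen = parents[rng.integers(0, n_parents, size=n_lpc)]
        pts = _inside_draw(rng, chosen, config.lpc_attraction_sd, config.window) \
            if config.lpc_attraction_sd > 0 else chosen
        records.extend((x, y, config.lpc_name) for x, y in pts)

    for name, lam in config.background_types.items():
        n = rng.poisson(lam)
        xs = rng.uniform(0, w, n)
        ys = rng.uniform(0, h, n)
        records.extend((x, y, name) for x, y in zip(xs, ys))

    cells = pd.DataFrame(records, columns=["x", "y", "cell_type"])
    cells.insert(0, "cell_id", [f"bin_{i + 1:06d}" for i in range(len(cells))])
    return cells
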