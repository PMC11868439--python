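# lpcmod

Analysis toolkit for studying **liver progenitor cell (LPC) heterogeneity**
in human liver single-cell and spatial transcriptomics data.

LPCs are rare bipotent cells able to differentiate into both hepatocytes
and cholangiocytes. Because they make up only a few percent of the
epithelial compartment and share markers with both epithelial lineages,
identifying them and quantifying their heterogeneity requires a chain of
bespoke computations. `lpcmod` implements that chain as a tested,
reusable library with a CLI, exercisable end to end on synthetic cohorts
and spatial point patterns with planted ground truth:

1. **Quality control** (`lpcmod.qc`) — cell filters on detected genes
   (strictly above 200 and below 6,000), total UMIs (above 150),
   mitochondrial percentage (below 50), ambient-contamination score
   (cells exceeding 0.4 excluded) and a 5% doublet-rate removal by
   score; gene filter at ≥ 3 expressing cells; every removal is
   attributed to a rule in an auditable report.
2. **Annotation** (`lpcmod.annotate`) — per-gene z-scores of per-cluster
   mean log-normalised expression
   (z<sub>g,c</sub> = (m<sub>g,c</sub> − mean<sub>c'</sub> m<sub>g,c'</sub>) / sd<sub>c'</sub> m<sub>g,c'</sub>),
   marker-panel argmax assignment, and the **bipotency rule**: a cluster
   is flagged as the LPC cluster iff its progenitor, hepatocyte *and*
   cholangiocyte panel mean z-scores all reach τ (default 0.5). Includes
   a Tirosh-style module score (expression-bin matched control genes)
   and per-individual LPC proportion statistics over the merged
   epithelial+LPC pool, with Wilcoxon comparisons.
3. **Cellular modules** (`lpcmod.modules`) — groups of cell clusters
   whose frequencies covary across individuals, found by Pearson
   correlation of the cluster-frequency table, correlation distance
   d = 1 − r, and agglomerative **ward.D** clustering (the
   Lance–Williams recurrence applied directly to the *unsquared*
   dissimilarities; the squared-input ward.D2 dialect is available
   behind a flag), cut at k modules; modules are characterised by
   Wilcoxon rank-sum marker tables with BH correction.
4. **Spatial colocalization** (`lpcmod.spatial`) — for each LPC on a
   segmented cellbin map, the mean Euclidean centroid distance to the
   k = 4 nearest cells of every cell type; types ranked by median
   distance; per-LPC distance profiles clustered with the same ward.D
   engine; pseudo-bulk (counts → CPM → log1p) concordance between
   populations or modalities.
5. **Synthetic data** (`lpcmod.simulate`) — negative-binomial cohorts
   with logistic-normal cell-type composition, latent-factor frequency
   covariation, a planted rare bipotent population, and Thomas-process
   spatial maps in which LPCs are attracted to cholangiocyte clusters.

## Worked example

```python
from lpcmod import (CohortSimConfig, simulate_cohort, run_qc,
                    cluster_mean_zscores, assign_cell_types,
                    identify_lpc_clusters, lpc_proportions, MarkerPanelSet)

adata, truth = simulate_cohort(CohortSimConfig(seed=1))   # 42 individuals
filtered, report = run_qc(adata)
z = cluster_mean_zscores(filtered, "cluster")
panels = MarkerPanelSet()
assignment = assign_cell_types(z, panels, min_z=0.5)
flags = identify_lpc_clusters(z, panels, tau=0.5)
labels = assignment.cell_labels(filtered.obs["cluster"])
labels[filtered.obs["cluster"].isin(flags[flags].index)] = "LPC"
props = lpc_proportions(labels, filtered.obs["individual"])
print(f"LPC clusters: {list(flags[flags].index)}")
print(f"LPC proportion: {100*props.mean:.2f}% +/- {100*props.sd:.2f}% "
      f"(n={len(props.per_individual)})")
```

prints

```
LPC clusters: ['C01']
LPC proportion: 3.27% +/- 3.26% (n=42)
```

i.e. the one planted bipotent cluster (here anonymised as `C01`) is the
only cluster passing the bipotency rule, and its recovered share of the
epithelial+LPC pool matches the planted cohort distribution (mean 2.95%,
sd 1.91% across 42 individuals) up to sampling noise.

The same stages are available from the shell:

```bash
lpcmod run --seed 1 --out demo_run          # full pipeline + report
lpcmod simulate cohort --out cohort --seed 1
lpcmod qc --in cohort --out cohort_qc
lpcmod annotate --in cohort_qc --out annot --tau 0.5
lpcmod modules --in cohort_qc --out cms --k 4 --top-n 250
lpcmod spatial --cells spatial/cells.csv --source LPC --k 4 --out coloc
```

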