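# Methods

This note documents the models behind `lpcmod`, the parameters that
matter, the numerical choices made where the design was open, and what
the synthetic-data generators do and do not emulate.

## Quality control

Cell filters are applied in a fixed, reported order: detected-gene
bounds → UMI floor → mitochondrial percentage → contamination score →
doublet-rate removal; the gene-prevalence filter runs last, on the
retained cells. Bound semantics are deliberate: the gene, UMI and mito
thresholds are strict (a cell at exactly 200 detected genes, 150 UMIs
or 50% mito counts fails), while the contamination cut removes only
scores strictly *exceeding* 0.4 and the gene filter keeps genes
detected in *at least* 3 cells. A removed cell is attributed to the
first rule that rejects it, so the report's per-rule counts plus
survivors always equal the input count.

The "5% doublet rate" is interpreted as removal of the top
`floor(0.05 × n_remaining)` cells by the supplied doublet score, with
ties broken by cell order; the score's provenance (the upstream doublet
caller) is an input, not re-implemented. Because this rule is a
quantile, it is the one filter that is not idempotent: re-filtering a
filtered bundle removes another 5%. The threshold rules are idempotent
and tested as such with the doublet rate set to zero.

Mitochondrial fraction is taken from cell metadata when present and
recomputed from `is_mito` genes otherwise; the two paths are tested for
agreement on simulated data, where the metadata value is itself derived
from the counts.

## Cluster annotation and the bipotency rule

Expression is normalised as log1p of counts scaled to 10,000 per cell
(CP10K). For each gene, per-cluster means of this quantity are
standardised across clusters with sample sd (ddof 1); zero-variance
genes map to all-zero rows. Marker panels are summarised by the mean
panel z-score per cluster; a cluster receives the argmax panel label
provided the best panel reaches `min_z` (default 0.5), with
deterministic ties broken by panel declaration order.

The LPC cluster is defined by co-elevation: progenitor AND hepatocyte
AND cholangiocyte panel means all ≥ τ. The default τ = 0.5 was chosen
so that pure lineages are never flagged at the generator's planted
effect sizes (marker log2FC 3, hundreds of cells per cluster): a pure
hepatocyte cluster reaches a hepatocyte-panel z around +1.5 but its
progenitor-panel z stays near or below 0, while the planted bipotent
cluster clears 0.5 on all three panels with a wide margin. Flags are
monotone non-increasing in τ. LPC subpopulations (LPC1 ALB/APOA1, LPC2
STMN1/NPM1/ACTB/PTMA, LPC3 S100A6/S100A4) reuse the same assignment
machinery on LPC cells only; there is no separate algorithm.

**Module score.** Genes are ranked by mean log-normalised expression
and cut into `n_bins = 24` equal-frequency bins; each set gene draws
`n_ctrl = 100` control genes from its bin with replacement, using the
supplied seed. The score is the per-cell mean over set genes minus the
mean over pooled controls. Means are computed after subtracting a
per-cell reference value (the first set gene), which is mathematically
neutral but makes the score *exactly* zero for cells with flat
expression rather than zero up to float summation order.

**LPC proportion.** Per individual, LPC cells divided by cells labelled
hepatocyte, cholangiocyte or LPC (the merged epithelial+LPC pool);
individuals with an empty pool are excluded and logged. Cohort mean and
sample sd are reported, and subpopulation proportion vectors can be
compared with the shared rank-sum engine.

## Wilcoxon rank-sum engine

Both marker testing and proportion comparisons use one two-sided
rank-sum implementation with two paths:

- **Exact** (both groups ≤ 10): the full permutation distribution of
  the rank sum is enumerated with a subset-sum dynamic program over
  doubled midranks, so ties are handled exactly, conditional on the
  observed rank pattern.
- **Approximate** (otherwise, and the vectorised per-gene path): a
  normal approximation whose null mean, variance, skewness and excess
  kurtosis are computed *exactly* from the observed midrank population
  (moments of a sample sum under sampling without replacement — the
  classical tie-corrected variance falls out as the second moment),
  with a 0.5 continuity correction and an Edgeworth expansion in the
  third and fourth cumulants. On untied data at group sizes 8–10 this
  agrees with exact enumeration to within about 5 × 10⁻⁴; a plain
  continuity-corrected normal is an order of magnitude worse. With
  heavy ties (few distinct values) the lattice of the statistic
  coarsens and agreement degrades; the exact path covers the small
  cases where that matters.

BH adjustment is delegated to `statsmodels` and property-tested for
monotonicity. Marker tables are BH-adjusted within each module-vs-rest
contrast; the top-250 set keeps adjusted p < 0.01 genes with positive
log2 fold-change (pseudocount 1 on mean CP10K), ranked by fold-change.
Ranking by fold-change among adjusted-p survivors (rather than by p) is
a documented choice.

## Cellular modules

Cluster frequencies are computed per individual (the default sample
unit) rather than per condition: four condition-level columns cannot
support stable Pearson correlations, while 42 individual columns can.
Correlation distance is d = 1 − r ∈ [0, 2]; zero-variance rows are
assigned r = 0 (logged).

The linkage is the **ward.D dialect**: the Lance–Williams recurrence
with Ward coefficients,

d(k, i∪j) = [(nᵢ+nₖ)d(k,i) + (nⱼ+nₖ)d(k,j) − nₖ d(i,j)] / (nᵢ+nⱼ+nₖ),

applied directly to the supplied, *unsquared* dissimilarities. The
squared-input variant (ward.D2: square first, report square-root
heights) is available behind a flag and cross-checked against scipy's
Ward linkage on Euclidean data; the ward.D path is cross-checked
against R's `hclust(method = "ward.D")` and an independent brute-force
agglomerator. Nearest-pair ties are broken by the lexicographically
smallest pair of cluster representatives (smallest contained leaf
index); input matrices are symmetrised exactly before clustering
because `1 − corrcoef` output is symmetric only to rounding. Cutting at
k undoes the last k−1 merges; module ids are ordered by each module's
smallest leaf index, so partitions are deterministic and nested in k.

## Spatial colocalization

The statistic is, per source cell (LPC) and target type, the **mean of
the distances to the k = 4 nearest cells of that type**, from centroid
coordinates under the Euclidean metric (unit-agnostic 2-D). The source
cell is excluded from its own type's neighbour pool — otherwise the
zero self-distance dominates. Types with fewer than k eligible cells
yield missing entries, never silent zeros; the raw k distances are kept
for audit. Aggregating the k distances by their mean (rather than
retaining all k) is a documented choice. Types are ranked by the median
entry across source cells.

Distance-profile clustering imputes missing entries with the column
median, applies log1p and per-column standardisation, and runs the same
ward.D engine on Euclidean row distances. Rows are individual LPCs and
columns are target types; a type × type summary would also be
defensible, but the per-cell reading preserves within-population
structure.

Pseudo-bulk profiles are gene-wise count sums → counts-per-million →
log1p, compared by Pearson correlation on the shared gene universe.
CPM makes the profile scale-invariant by construction.

## Synthetic data: what it emulates, and what it does not

**Cohort.** 42 individuals across five condition labels (6 FL, 14 HL,
5 CL, 9 TL, 8 TLA — fetal, healthy, cirrhotic, tumour, tumour-adjacent).
The tumour cohort's sample/individual distinction is simplified: each
simulated individual carries exactly one condition, and the condition
sizes were chosen to keep the cohort at n = 42, the size the proportion
statistics assume. Non-LPC composition is logistic-normal:
softmax(log baseline + loadings·f + ε), with standard-normal latent
factors f shared within an individual (driving planted frequency
covariation across clusters, the signal the cellular-module stage
recovers) and independent logit noise (sd 0.3). The LPC type is then
inserted so that its share of the epithelial+LPC pool equals a
per-individual draw from a truncated normal whose *post-truncation*
mean and sd are moment-matched to the planted targets (default 2.95%
and 1.91%); naive clipping of a normal at zero would inflate the
planted mean by about 0.05 percentage points at these values.

Counts are gamma-Poisson (negative binomial, shared dispersion θ = 2)
with lognormal library sizes (median 2,500 UMIs, log-sd 0.35) over a
600-gene universe: named marker genes at the median baseline weight,
13 mito genes holding ~8% of the library, lognormal filler weights.
Marker genes carry a 2^(log2FC) multiplicative bump (default log2FC 3)
in their type's expression profile; the LPC type elevates the
hepatocyte, cholangiocyte and progenitor panels simultaneously, plus a
14-gene regeneration set at log2FC 1.5. Because profiles are
renormalised, the realised mean-count ratio for a log2FC-3 marker is
slightly below 8 (~7.6 at default panel sizes). QC has work to do: 2%
of cells get a 25× mito boost, contamination scores are a Beta mixture
with a 4% high-score component, and doublet scores are Beta-distributed.
Cluster labels are the true types under anonymised ids, so annotation
accuracy is measurable against `true_type`.

Cohort sizes (250 cells/individual, 600 genes) were chosen so a full
simulate → QC → annotate → proportion pass completes in seconds while
leaving ~150 epithelial-pool cells per individual — enough that
multinomial noise in per-individual LPC proportions stays well inside
the planted between-individual sd.

Not emulated: batch effects, platform chemistry, doublet *expression*
mixing (only a score), ambient contamination of the counts themselves,
cell-cycle structure, within-type expression gradients. Passing
recovery tests therefore shows the statistics are implemented correctly
and are sensitive at realistic effect sizes — not that they are robust
to artefacts the generator does not produce.

**Spatial.** A 1000 × 1000 window (micrometre-like, arbitrary units).
Cholangiocytes form a Thomas process (Poisson parents, mean 15;
Poisson(20) offspring; Gaussian spread 30); each LPC is displaced from
a uniformly chosen parent by an isotropic Gaussian (sd 20, the
attraction scale); other types are uniform (hepatocyte 400,
endothelial 150, HSC 100 expected cells). Out-of-window displacements
are redrawn, zero-parent draws are retried with a log entry. One
consequence worth knowing: LPCs sharing a parent share their local
neighbourhood, so distance-profile columns for *bystander* types carry
clump-level correlation; the planted attraction is recovered through
the cholangiocyte column. Not emulated: tissue morphology, zonation,
exclusion/repulsion between cells, segmentation noise.

## Determinism

Every stochastic operation takes a seed or NumPy `Generator`; the
pipeline fans a single global seed out to per-stage seeds by fixed
offsets, so stages are individually reproducible and identical
config + seed gives byte-identical numeric outputs.

## Known limitations

- ward.D on non-Euclidean dissimilarities can produce height
  inversions (a known property of the dialect); Newick export floors
  negative branch lengths at zero.
- The approximate rank-sum path loses accuracy under heavy ties at
  small n (the exact path covers n ≤ 10).
- The doublet rule depends on the supplied score's calibration; only
  its quantile is used.
- Condition labels influence only baseline composition in the default
  generator; no condition-specific expression programs are planted.
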