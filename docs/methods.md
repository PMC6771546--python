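# Methods

## The problem

Graph-based clustering of single-cell RNA-seq data needs two parameters that
users otherwise pick by trial and error: the number of top principal
components `nPC` defining the similarity space, and a resolution `r` that
controls the number of groups `k`. Different `(nPC, k)` combinations produce
groupings that differ sharply in how well their groups can be told apart by
differentially expressed (DE) genes. This package sweeps the `(nPC, k)` space
for the combinations that yield *major*, well-separated cell groups, evaluates
each by DE-based metrics, and can recurse inside groups to build a multi-layer
cell ontology (e.g. T cells at the top, T-cell subtypes below).

## Pipeline

1. **QC and normalization.** Cells with fewer than 200 expressed genes or
   more than 5% mitochondrial UMI are removed (both bounds strict on the
   removal side; a cell at exactly 200 genes or exactly 5% is kept).
   Expression is log-normalized: `ln(1 + count / cell_total * 1e4)`.
   Filtering can be disabled (`filter_cells=False`) for datasets analysed
   unfiltered.
2. **Scaling.** Per gene, ordinary least squares regresses expression on the
   per-cell covariates (by default total UMI and mitochondrial fraction);
   residuals are standardized with the sample (n−1) standard deviation and
   clipped to ±10. Constant genes scale to zero.
3. **Variable genes.** Per gene the log mean of `expm1`(expression) and the
   log variance-to-mean ratio are computed; genes are binned by log mean into
   20 equal-width bins, the dispersion is z-scored within each bin, and genes
   with `0.1 < log mean < 8` and dispersion z ≥ 1 are kept. The log-scale
   convention matters: with raw-scale bins every highly expressed gene lands
   in a bin of its own and can never reach z ≥ 1.
4. **PCA.** Standard SVD of the scaled variable-gene matrix (cells centered);
   `sdev` is the singular value over √(n−1). Component signs are fixed by
   making the largest-magnitude loading positive, so results are
   reproducible. Up to `max_pcs` = 40 components are computed.
5. **Sweep bounds.** `nPC_min` is chosen by an elbow rule: the first
   component after which every subsequent relative drop in `sdev` is below
   10% (fallback: the second-to-last component, with a warning). `nPC_max` =
   `nPC_min` + 20, capped at the available components. `k_max` is the
   round-half-up average of the group counts obtained by clustering at
   resolution `r_ini` = 1.5 with `nPC_min` and with `nPC_max` components,
   floored at 2.
6. **Clustering.** A shared-nearest-neighbour graph (20 nearest neighbours
   including self, Jaccard weights over neighbour sets, weights below 1/15
   pruned) followed by seeded modularity community detection
   (Leiden, RB-configuration objective) with resolution `r`. Groups are
   relabelled by decreasing size. Identical coordinates short-circuit to a
   single group.
7. **Merge series.** For each `nPC`, an initial fine partition is found by
   raising `r` from 1.0 in steps of 0.2 until at least `k_max` groups appear
   (error past `r` = 5). The two groups with nearest centroids (unweighted
   member means, recomputed after each merge) are merged iteratively down to
   one group; ties break to the smallest id pair. The partitions with
   `k = 1..k_max` are retained and are nested by construction.
8. **Gap statistic.** For a partition into `k` groups,
   `W = Σ_r D_r / (2 n_r)` where `D_r` sums Euclidean distances over all
   ordered within-group pairs. `Gap = mean_b log W*_b − log W_obs`, with each
   of `B` reference draws sampling the same number of cells uniformly in the
   axis-aligned bounding box of the observed top-`nPC` coordinates and
   partitioned into `k` groups by seeded k-means (10 restarts). One set of
   reference draws per `nPC` is shared across `k`. The original first-local-
   optimum rule for choosing `k` from the gap curve is deliberately not used;
   only gap *increases* `M(nPC, k) = Gap(k) − Gap(k−1)` enter the selection.
9. **Candidate selection.** Entries of `M` with increase ≤ mean + 1 sd (over
   all finite entries, sample sd) are dropped; per column `k` the largest
   surviving positive increase is kept (ties to the smaller `nPC`); kept
   entries are sorted by increase descending (ties to the smaller `k`); an
   entry is accepted iff its `nPC` and `k` both strictly exceed those of
   every accepted entry, the first always accepted. If nothing survives the
   filter the single global-maximum entry is returned with a warning.
   Candidates are named `PC{nPC}K{k}`.
10. **DE genes.** One-vs-rest two-sided Wilcoxon rank-sum per gene on
    normalized expression, restricted to genes expressed in ≥ 10% of cells on
    either side with average log fold change ≥ 0.25 (natural log of
    `(mean expm1 + 1)` ratios, so only upregulated genes are reported);
    Bonferroni adjustment over the tested genes of the group; keep adjusted
    p ≤ 0.05. AUROC = Mann–Whitney U / (n_in · n_out), ties counted half.
    Groups under 3 cells are skipped with a warning.
11. **Classification error.** Per group, a binary CART tree (Gini splits) on
    the normalized expression of the union of DE genes; along its
    cost-complexity pruning path, for each `nsplit` in 5..15 the deepest
    subtree with at most that many splits supplies the training relative
    error (misclassified / minority-class count at the root — the convention
    that makes relative error × group cell fraction an absolute error).
    Set-level error is the sum over groups; the final error averages over
    `nsplit` = 5..15. The candidate with the lowest final error is the best;
    ties go to the smaller `k` (prefer coarser major groups).
12. **Performance summary.** Per candidate: median across groups of the
    number of DE genes with AUROC above 0.8 / 0.85 / 0.9, and the median
    across groups of the mean avg log fold change of the top 10 (or all, if
    fewer) AUROC > 0.8 DE genes, reported in natural log and log2.
13. **Ontology.** The sweep re-runs recursively inside chosen groups
    (default: the largest group per level, the published demonstration mode;
    `targets="all"` expands every group), recomputing variable genes, PCA and
    bounds within each subset, to `max_depth` (default 2) and only for groups
    with at least `min_cells_recurse` = 100 cells. Cell QC is not re-applied
    inside subsets. Any candidate may be pinned per node in place of the
    best, which is how a flatter or deeper ontology is obtained by manual
    inspection.

## Key parameters

| parameter | default | meaning |
| --- | --- | --- |
| `r_ini` | 1.5 | resolution for estimating `k_max` |
| `npc_span` | 20 | `nPC_max − nPC_min` |
| `r_start`/`r_step`/`r_cap` | 1.0 / 0.2 / 5.0 | resolution ladder for the initial partition |
| `gap_B` | 100 | uniform reference draws per `(nPC)` |
| `nsplit_range` | (5, 15) | tree split counts averaged into the final error |
| `min_logfc`, `min_pct`, `max_padj` | 0.25, 0.1, 0.05 | DE thresholds |
| `n_neighbors`, `snn_prune` | 20, 1/15 | SNN graph construction |
| `min_genes`, `max_mito_frac` | 200, 0.05 | cell QC |
| `min_cells_recurse` | 100 | smallest subset the sweep runs on |

All of it lives in `RunConfig`; `gap_normalization="raw_sum"` switches `W` to
the plain distance sum, and `reference_partition="merge"` partitions
reference draws with a fine k-means followed by nearest-centroid merging
instead of plain k-means, mirroring the observed-data pipeline.

## Numerical choices

- Reference-draw k-means is a Lloyd iteration vectorised across all `B`
  draws and 10 restarts at once (no installed library batches k-means over
  stacked datasets). Random-point initialisation, empty clusters reseeded to
  the farthest point, assignment-stability stopping, 15-iteration cap. The
  cap moves mean `log W*` by about 0.001 — a quarter of one draw-to-draw
  standard deviation and far below the gap increases being compared.
- Distances inside k-means drop the constant `‖x‖²` term and run in float32;
  inertia comparisons across restarts are exact because the shift is common.
- `k_max` rounding is half-up; the merge tie-break (smallest id pair), the
  column-max tie-break (smaller `nPC`) and the sort tie-break (smaller `k`)
  are fixed for determinism.
- Every stochastic stage (clustering, reference draws, trees) derives a
  per-stage child seed from `RunConfig.seed`, so a run is reproducible
  end-to-end and subtrees of an ontology can be re-run in isolation.
- In the orchestrated run, a candidate whose DE table is empty receives the
  worst classification error (1.0) with a warning instead of aborting the
  sweep; the standalone `classification_error` still raises, since without
  features the error is undefined.

## The synthetic study system

`ikap.synthetic` emulates droplet scRNA-seq of a tissue with a few discrete,
well-separated major populations, optionally containing subtypes:

- counts are gamma-Poisson (negative binomial, size 2.0) with log-normal
  per-gene baselines (log sd 1.3);
- marker genes draw baselines from a moderately expressed regime (log-normal
  median 1, sd 0.5): real annotated markers are reliably detected genes, and
  a fold change planted on a never-detected gene carries no signal;
- marker effects multiply the mean; subtype effects compose with major
  effects; marker sets are disjoint;
- each cell's expected profile is renormalized to a type-independent library
  before a log-normal library factor (sd 0.25) is applied — marker effects
  reshape the transcriptome rather than inflate the library, so total UMI
  stays a technical covariate as in real data;
- ten genes are named `MT-*` and carry 2% of expected counts, so QC runs.

Presets: `flat5` (5 × 200 cells, 40 markers at 2.5 log-units each),
`hier3x3` (majors of 360/240/200 cells with 40 markers at 2.5; the largest
split into three 120-cell subtypes with 15 markers at 1.25 — half the major
effect), `single_blob` (300 cells, no structure), `pbmc_like` (7 majors,
40–500 cells). Preset sizes are desk-scale: large enough for the sweep's
asymptotics (hundreds of cells per group, k-means references in up to ~25
dimensions), small enough that a full sweep takes about a minute.

What passing on this generator does *not* show: robustness to gradient or
trajectory structure (the method assumes discrete types), doublets, ambient
RNA, batch effects, or the heavy zero-inflation of very shallow libraries.
The generator plants independent genes; co-expression modules in real data
make the effective dimensionality lower than the gene count.

## Known limitations

- The clustering backend is Leiden on an SNN graph — the closest open
  analogue of the original host package's Louvain; partitions are not
  bit-identical to any specific host-package version, and neither are CART
  trees relative to other tree implementations. All selection rules operate
  on quantities (gap increases, relative errors) that are stable under such
  backend differences on separated data, but candidate identities near the
  filter threshold can differ.
- The gap-increase filter (mean + sd over the whole matrix) is global; on
  landscapes where a single huge increase dominates, it can filter away
  genuine secondary structure. `candidate_sd_factor` exposes the multiplier.
- Reference draws are box-uniform, the classical choice; strongly curved or
  correlated embeddings make the null conservative.
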