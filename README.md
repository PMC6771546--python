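# ikap

**Identify K mAjor cell Population groups in single-cell RNA-seq.**

Graph-based scRNA-seq clustering makes the analyst choose two parameters —
the number of top principal components (nPC) that define the cell-to-cell
similarity space, and a resolution r that determines the number of groups k.
The choice is consequential: it decides whether downstream differential
expression returns crisp cell-type markers or a muddle of subgroup noise, and
it is usually settled by trial and error.

`ikap` automates the choice. For every nPC in an automatically determined
range it builds nested partitions with k = 1..k_max by iterative
nearest-centroid merging of a fine clustering, scores each partition with a
gap statistic

&nbsp;&nbsp;&nbsp;&nbsp;Gap(nPC, k) = E[log W*] − log W,&nbsp;&nbsp;
W = Σ_r D_r / (2 n_r),

where D_r sums within-group pairwise distances and the expectation is over
uniform draws from the bounding box of the data, and tabulates the gap
*increases* M(nPC, k) = Gap(nPC, k) − Gap(nPC, k−1). Combinations whose
increase stands above mean + sd are reduced to column maxima, sorted, and
greedily accepted when both nPC and k exceed everything accepted before —
yielding a handful of candidate groupings (named like `PC9K7`). Candidates
are then ranked by a decision-tree classification error built from their DE
genes (one-vs-rest rank-sum markers; per-group CART trees; mean over
nsplit = 5..15 of Σ groups relative training error × group fraction), and the
lowest-error candidate is marked best. Applied recursively inside groups, the
same procedure yields a multi-layer cell ontology (T cells → T-cell
subtypes → …).

## Worked example

Simulate a mixture of five well-separated cell populations (200 cells and 40
marker genes at 2.5 log-units each) and sweep it:

```python
from ikap import IKAP, RunConfig
from ikap.synthetic import generate, preset

raw, truth = generate(preset("flat5", seed=1))   # 1200 genes x 1000 cells
result = IKAP(raw, RunConfig(seed=1, gap_B=30)).fit()
print(result)
print(result.summary_table().to_string(index=False))
```

```
<IkapResult: 1000 cells, candidates [PC5K5], best PC5K5>
candidate  nPC  k  gap_increase  n_de_auroc_0.8  n_de_auroc_0.85  n_de_auroc_0.9  median_top10_avg_logFC  median_top10_avg_log2FC  classification_error  is_best
    PC5K5    5  5       0.29634            40.0             40.0            37.0                2.444631                 3.526857              0.000182     True
```

The sweep determined nPC_min = 5 by the explained-standard-deviation elbow,
swept nPC 5..25 with k up to k_max = 6, and found a single candidate: 5
principal components, 5 groups — exactly the planted structure (adjusted
Rand index vs truth 1.0). Each group shows a median of 40 DE genes with
AUROC > 0.8, a median top-10 log2 fold change of 3.53, and a classification
error of 0.0002: the groups are essentially perfectly separable by their
markers.

The same object drives the recursive ontology:

```python
from ikap import build_ontology
tree = build_ontology(raw, RunConfig(seed=1, gap_B=30), max_depth=1)
```

or from the shell:

```bash
ikap simulate --preset hier3x3 --seed 0 --out sim/
ikap run sim/ --outdir out/ --seed 0          # one sweep, artifacts as TSV/JSON
ikap ontology sim/ --max-depth 1 --seed 0     # recursive, nested JSON
ikap benchmark sim/ --seed 0                  # fixed nPC x r trial grid
ikap summarize out/
```

`ikap run` writes per-candidate cell-assignment and DE-gene tables, the
gap-increase matrix, a performance summary and a JSON manifest with the
resolved configuration and seed; re-running with the same seed reproduces
every file byte for byte.

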