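# dropstab

**Stability versus quality of single-cell RNA-seq clustering under
dropouts.**

Single-cell RNA-seq matrices are sparse: a gene expressed in one cell is
often not detected in a similar cell (a *dropout*), with observed zero
rates reaching 90%. The standard clustering pipeline (PCA → kNN graph →
Leiden/Louvain community detection, as shipped by Scanpy and Seurat)
assumes similar cells stay close in space. `dropstab` is a benchmarking
framework for asking what dropouts do to that assumption, separating two
properties that are usually conflated:

- **cluster quality** — do clusters respect the global cell-type labels
  `C`? Measured by homogeneity `η = 1 − H(C|K)/H(C)`, completeness
  `γ = 1 − H(K|C)/H(K)` and the v-measure
  `V_β = (1+β)ηγ / (βη + γ)` (β = 1);
- **cluster stability** — do cell *pairs* stay co-clustered between the
  corrupted-data partition `K` and the uncorrupted-baseline partition
  `B`? Measured by the adjusted Rand index,
  `ARI = (RI − E[RI]) / (max RI − E[RI])` with
  `RI = (n_TP + n_TN)/n_pairs`.

The package provides: a seeded hierarchical gamma–negative-binomial
simulator of labeled count matrices with cell-type tree structure
(well-separated types or nested cell states); corruption operators —
expression-weighted dropout injection calibrated to an exact target
sparsity `f`, read-depth binomial thinning, and three noise models; the
clustering arms (Leiden, Louvain, K-Means and Ward agglomerative with
silhouette-selected k, and a random-within-type null) as sklearn-style
estimators; the metrics above implemented from their contingency-table
formulas; and sweep orchestration with derived per-run seeds and tidy
results. Loaders for real count matrices (MatrixMarket/CSV with a label
TSV) push public datasets through the same evaluation path.

It is aimed at method developers and analysts who want to quantify how
much of a clustering's sub-type structure survives sparsity before
building interpretation or imputation on top of it.

## Worked example

Simulate a 1,000-cell × 2,000-gene baseline with 3 well-separated cell
types, then measure Leiden stability and quality at increasing dropout
rates (each level corrupts the *same* stored baseline):

```python
import dropstab as ds

adata = ds.simulate_baseline(ds.SimulationParams(n_cells=1000, n_genes=2000, seed=101))
print("baseline zero fraction:", round(ds.zero_fraction(adata), 3))

base = ds.run_baseline(adata, "leiden", n_variability_runs=0)
print("baseline clusters:", base.n_clusters)

cfg = ds.SweepConfig(kinds=("dropout_expression",), levels=(0.1, 0.5, 0.9),
                     algorithms=("leiden",), runs_per_combination=3,
                     master_seed=101, dataset_id="S1000")
df = ds.run_sweep(adata, cfg, baselines={"leiden": base})
print(df.groupby("level")[["ari_vs_baseline", "homogeneity", "n_clusters"]]
        .mean().round(3))
```

prints

```
baseline zero fraction: 0.067
baseline clusters: 3
       ari_vs_baseline  homogeneity  n_clusters
level                                          
0.1              1.000          1.0         3.0
0.5              1.000          1.0         3.0
0.9              0.608          1.0         6.0
```

Read the contrast off the last two columns: at 90% sparsity the clusters
are still perfectly *homogeneous* (every cluster is one cell type —
quality looks fine), yet *stability* has collapsed to ARI 0.61 — the
pipeline now splits the types into shifting sub-clusters whose cell
pairings no longer agree with the baseline partition. Any downstream
analysis that treats those sub-clusters as biological sub-populations is
reading technical noise. On the nested 8-state design
(`tree=ds.preset_tree("nested8")`) the same divergence appears earlier,
because genuine sub-state structure is what dropouts erase first.

The estimators compose with sklearn:

```python
est = ds.GraphCommunityClustering(algorithm="louvain", n_neighbors=30).fit(adata.X)
labels = est.labels_
```

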