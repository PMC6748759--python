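# segstab

Identification and evaluation of **stably expressed genes (SEGs)** in
single-cell RNA-seq data.

Bulk transcriptomics defines housekeeping genes as genes with constant
expression across tissues, but at single-cell resolution many classic
housekeeping genes (e.g. *GAPDH*, *ACTB*) are bimodal and noisy.
`segstab` quantifies per-gene expression stability directly from a
genes × cells matrix of non-negative quantifications (CPM, FPKM or UMI
counts) and selects genes that are stably expressed across individual
cells — useful as control genes for scRNA-seq normalisation and data
integration.

## Model

After `log2(x+1)` transformation and removal of genes with >80% zeros,
the positive log-expression values of each gene are fitted by EM with a
two-component mixture

```
f(x) = λ · Gamma(x; α, β) + (1 − λ) · N(x; μ, σ²)
```

where the Gamma component captures the low end of the distribution and
the Gaussian the cells that express the gene; λ is the proportion of
cells in the Gamma component. A competing Gamma + Gamma family can be
fitted and compared by BIC (the Gamma–Gaussian family typically wins on
real data). Four stability features are derived per gene:

* **λ** — mixing proportion; small for unimodal, "always-on" genes,
* **σ²** — variance of the expressed (Gaussian) component,
* **ω\*** = ω · minmax(μ) — the zero fraction ω regularised by the
  min–max-scaled Gaussian mean, correcting the dropout bias against
  lowly expressed genes,
* **F** — one-way ANOVA F-statistic across predefined cell classes
  (when labels are available).

Genes are ranked in increasing order per feature, ranks are rescaled to
[0, 1], and the **stability index** of a gene is the average of
`1 − scaled rank` over the features, so the index lies in [0, 1] with
larger values meaning more stable. SEGs are genes with an index rank
percentile > 80 and a reversed rank percentile > 60 for every feature.

To evaluate any gene list, cells are clustered by k-means restricted to
the list's genes (K = number of predefined classes, repeated 10×) and
scored against the class labels with ARI, Jaccard, Fowlkes–Mallows and
Purity computed from pair counts (a, b, c, d). **Low** concordance means
the list carries little cell-type signal — i.e. it is stably expressed.

## Worked example

```python
import segstab as ss

# synthetic dataset with known ground truth: 300 genes (20% stable),
# 500 cells, 4 cell classes
ds = ss.generate(n_genes=300, n_cells=500, n_classes=4,
                 frac_stable=0.2, seed=0)

res = ss.StabilityModel(ds.matrix, ds.annotation).fit()
print(res.summary(top=5))
```

```
Gene expression stability (Gamma-Gaussian mixture + rank aggregation)
======================================================================
genes (post filter):    289    cells: 500
valid mixture fits:     289    features: lambda_, sigma2, omega_star, f_stat
stability index:     mean 0.500, median 0.438

top 5 most stable genes:
         index  lambda  sigma2  omega
gene
gene_28  0.948   0.055   0.130  0.018
gene_58  0.947   0.114   0.110  0.054
gene_7   0.946   0.034   0.156  0.050
gene_15  0.939   0.057   0.124  0.076
gene_22  0.937   0.067   0.194  0.042
```

The most stable genes have small λ (unimodal), small σ² and few zeros.
Selecting SEGs and scoring them against the predefined classes:

```python
segs = res.select_segs()                       # 49 genes
scores = res.evaluate_gene_list(segs, reps=10, seed=0)
print(scores.summary_frame().round(1))         # indices × 100
```

```
         mean   sd
ari      -0.2  0.1
jaccard  16.4  0.2
fm       28.5  0.3
purity   29.9  0.9
```

48 of the 49 selected genes are truly stable in the generating model
(precision 0.98), and k-means on them shows essentially no concordance
with the cell classes (ARI ≈ 0): the selected genes carry no cell-type
signal, which is exactly what a stable control-gene set should look like.

The same pipeline is available from the shell:

```bash
segstab simulate --genes 300 --cells 500 --classes 4 --seed 0 --out-prefix sim
segstab run --matrix sim.matrix.tsv --labels sim.labels.tsv \
            --out-dir out --seed 0 --evaluate
```

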