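# acimpute

Constrained Markov-diffusion imputation for single-cell RNA sequencing
count matrices.

## The problem

scRNA-seq count matrices are dominated by zeros. Some are biological (the
gene is truly off in that cell); many are *dropouts* — transcripts the
assay missed. Dropouts distort clustering, visualization, and trajectory
analysis. Smoothing-based imputation repairs them by averaging each cell's
profile over its nearest neighbors on a cell-similarity graph, but plain
diffusion applies the same smoothing to every gene in every cell and tends
to *oversmooth*: it erases genuine inter-cell variability, especially for
highly expressed genes whose zeros were probably real.

This package implements an expression-constrained variant of diffusion
imputation. Dropout rate falls with expression level, so an observed zero
in a highly expressed gene is more likely biological; such genes should
diffuse *less*. The method encodes this with a per-gene, per-cell exponent
on the transition probabilities. It is aimed at anyone preparing a
gene × cell count matrix for downstream clustering or trajectory analysis.

## Method

Given a filtered count matrix **X** (genes × cells):

1. **Normalize** (library size): `XN_gc = X_gc / Σ_g X_gc · median_j(Σ_g X_gj)`.
   Size factors are stored, so the transform is exactly invertible.
2. **High-variance genes**: keep genes with mean ≥ 0.01 and coefficient of
   variation (σ/μ on XN) at or above the first quartile, giving **Xh**.
3. **Markov matrix**: PCA of Xh (cells × d), adaptive Gaussian kernel
   `A_ij = exp(−(Dist(i,j)/σ_i)²)` with σ_i the distance to the k-th
   nearest neighbor (k = 5), restricted to each cell's 3k nearest
   neighbors; symmetrize `(A + Aᵀ)/2`; row-normalize to **M**.
   Raise M to the smallest power t at which successive smoothed matrices
   agree (squared Pearson R² ≥ 0.95 between `Xh·(Mᵗ)ᵀ` at t and t−1).
4. **Power exponents**: each cell's n most probable neighbors under Mᵗ
   (n = 100 above 1000 cells, else `round((N−15)/985·100)`) define a
   neighbor-mean matrix **Xa**; min–max scaling of Xa into [1, 3] gives the
   exponent matrix **P**.
5. **Constrained smoothing**: for gene g, cell c,
   `X̂_gc = Σ_k w_k XN_gk` with `w_k ∝ (Mᵗ_ck)^{P_gc}`.
   Exponent 1 is plain diffusion; exponent 3 concentrates weight on the
   most similar cells, so highly expressed genes smooth over a narrower
   neighborhood.
6. **Merge**: X̂ is mapped back to the count scale and *only observed
   zeros* are replaced — every nonzero count survives bit-exactly.

A synthetic-data generator (negative-binomial clusters with marker genes
and expression-dependent dropout) and evaluation utilities (ARI/NMI/purity,
expression–dropout correlation, per-cell correlation to a reference) make
the whole pipeline testable without external data.

## Worked example

```sh
$ acimpute simulate --genes 300 --cells 80 --clusters 3 --seed 7 --outdir demo
INFO acimpute.synthetic: calibrated dropout lam=0.28030 (expected zero fraction 0.600)
simulated 300 genes x 80 cells (59.8% observed zeros) into demo

$ acimpute impute --input demo/observed.csv --output demo/imputed.csv --seed 7
INFO acimpute.preprocess: filtered 300 -> 300 genes, 80 -> 80 cells
INFO acimpute.preprocess: selected 225 / 300 high-variance genes (CV threshold 1.31)
INFO acimpute.markov: diffusion stabilized at t=2 (R^2=0.97456)
INFO acimpute.impute: pipeline: t=2, n_neighbors=7, hvg=225, genes=300, cells=80
imputed matrix written to demo/imputed.csv (t=2, n=7)

$ acimpute evaluate --matrix demo/observed.csv --labels demo/labels.tsv
expression-dropout correlation = -0.760595
```

The simulator drew a 3-cluster dataset and zeroed entries with probability
`exp(−0.28·count)`, leaving 59.8% zeros. The pipeline chose diffusion time
t = 2 (smoothing had stabilized, R² = 0.975) and n = 7 power-matrix
neighbors for 80 cells. The evaluate call confirms the generator's premise
on this dataset: per-gene expression and dropout rate are strongly
anti-correlated within clusters (−0.76). Every data-driven choice is also
written to `demo/imputed.csv.report.json`.

The same pipeline is available as a library:

```python
import acimpute as ac

dataset = ac.make_dataset(seed=7)                       # 1500 x 300, ~60% zeros
result = ac.run_pipeline(dataset.observed, ac.ImputeConfig(seed=7))
result.imputed.final                                    # genes x cells, counts
```

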