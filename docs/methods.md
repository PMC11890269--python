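# Methods

## Model and procedure

The package treats imputation as constrained diffusion on a cell-similarity
graph. The underlying assumptions are:

- Cells of the same type form neighborhoods in expression space, so a
  cell's missing values can be estimated from similar cells.
- Dropout probability decreases with expression level. An observed zero in
  a gene that is highly expressed among a cell's neighbors is therefore
  more likely a true biological zero, and such genes should be smoothed
  over a narrower, more similar neighborhood.

The pipeline stages and their contracts:

1. **Filtering.** Genes with total expression > 0.001 and cells expressing
   > 3 genes are kept (gene pass first, then cell pass). Fewer than 16
   surviving cells is an error, because the neighbor-count rule below is
   undefined there. Filtering is idempotent.
2. **Normalization.** `XN = X / colsum · median(colsums)`. The size
   factors and median are retained so the map is inverted exactly
   (`XN · colsum / median`); tests require 1e-9 relative agreement.
3. **High-variance genes.** Mean gate (≥ 0.01 on XN) first, then CV
   (population σ/μ) at or above the first quartile of CVs *among
   mean-eligible genes*. Quartiles use linear interpolation between order
   statistics. Constant genes have CV 0 and drop out unless Q1 = 0.
4. **Graph.** PCA (genes centered; exact SVD up to 2000 cells, seeded
   randomized solver above; component signs fixed by the
   largest-magnitude loading) → adaptive Gaussian kernel with per-cell
   bandwidth σ_i = distance to the 5th nearest neighbor, evaluated on the
   15 nearest neighbors of each cell, zero elsewhere, self excluded →
   additive symmetrization → row normalization.
5. **Diffusion time.** M is raised to successive powers; at each t ≥ 2 the
   squared Pearson correlation between flattened `Xh·(Mᵗ)ᵀ` and
   `Xh·(M^{t−1})ᵀ` is computed, and the first t reaching 0.95 is kept
   (cap t_max = 12). Squared correlation is used because it is symmetric
   in the two matrices; identical constant matrices count as stabilized.
6. **Exponents.** Each cell's n top-probability neighbors under Mᵗ (self
   excluded, ties broken by ascending index) give the neighbor-mean matrix
   Xa over all genes of XN; global min–max scaling maps Xa into [1, 3].
   A constant Xa maps to all-1 (plain diffusion). n follows the piecewise
   rule: 100 for ≥ 1000 cells, else `round((N−15)/985·100)` half-up,
   clamped to ≥ 1.
7. **Smoothing and merge.** Weights `(Mᵗ_ck)^{P_gc}`, renormalized per
   row, average XN across cells; the result is denormalized and merged
   into the observed matrix at zero positions only. Observed nonzeros are
   preserved bit-exactly, so the output's nonzero pattern is a superset of
   the input's.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 5 | neighbor rank defining the kernel bandwidth σ_i |
| `neighbor_multiplier` | 3 | kernel support = 3k nearest neighbors |
| `pca_dim` | min(50, cells−1, #HVG) | embedding dimensionality |
| `t_max`, `r2_threshold` | 12, 0.95 | diffusion-time search bounds |
| `power_lo`, `power_hi` | 1, 3 | exponent range; lo = plain diffusion |
| `gene_sum_min`, `min_genes_per_cell` | 0.001, 3 | filtering thresholds |
| `hvg_mean_min`, `cv_quantile` | 0.01, 0.25 | HVG gates |
| `rescale` | `"none"` | per-gene rescaling before denormalization |
| `xa_source` | `"xn"` | matrix the exponents are derived from |

## Design choices made where the design was open

- **Rescaling** (`rescale`). A `gene-max` mode multiplies each smoothed
  gene row so its maximum matches the gene's maximum in XN, compensating
  the shrinkage of extremes under diffusion. It is *not* the default:
  on overdispersed counts the raw per-gene maximum is a sampling extreme,
  while the smoothed maximum is close to a local mean, so the ratio
  routinely inflates every imputed entry of a gene several-fold and
  measurably degrades recovery (median per-cell correlation to truth drops
  by ~0.2 on the benchmark). Plain denormalization (`none`) is the
  default; the max-matching contract of `gene-max` is still tested.
- **Exponent source** (`xa_source`). The exponent matrix must cover every
  gene of XN, but the neighbor-mean construction is naturally stated on
  the HVG matrix. The default computes neighbor means from all genes of
  XN. The alternative `xh-default-lo` scales only HVG rows and assigns
  every other gene the unconstrained exponent, for users who want
  constraint strictly limited to the genes that defined the graph.
- **R² definition.** Squared Pearson correlation of the flattened
  successive smoothings; chosen for symmetry and scale-invariance.
- **Row normalization** of the symmetrized kernel is what makes M a
  Markov matrix; the diagonal of the sparse kernel is zero, so a cell
  never votes for itself and its mass is redistributed to neighbors.
- **Tie-breaks.** Top-n neighbor selection sorts by descending transition
  probability with ascending cell index as tie-break; deterministic.
- **Degenerate bandwidths.** A cell with ≥ k coincident neighbors would
  get σ_i = 0; the bandwidth falls back to the smallest positive neighbor
  distance, and a fully duplicated neighborhood is an error naming the
  cell.

## Synthetic data

`make_dataset` emulates the two properties the method depends on, and
nothing else:

- **Cluster structure.** Per-gene baseline means are drawn log-normally
  (location log 2, scale 1 by default — a span of roughly 0.2–20, as in a
  filtered droplet dataset) and shared across clusters; a random 10% of
  genes per cluster are up-shifted ×5 as markers, so clusters differ only
  through markers. Counts are negative binomial (dispersion 2, i.e.
  variance μ + μ²/2).
- **Expression-dependent dropout.** Each entry is zeroed independently
  with probability `exp(−λ·count)`. λ is calibrated by bisection on the
  *expected* zero fraction (a closed-form, sample-free computation) so the
  default benchmark of 1500 genes × 300 cells × 3 clusters lands at 60%
  observed zeros, within the 55–70% band typical of droplet experiments.

Not emulated: library-size variation across cells, batch effects,
trajectory/pseudotime structure, and any dropout mechanism that alters
rather than zeroes a count. Consequently, passing tests show that the
method recovers cluster-structured signal destroyed by
expression-dependent zeroing; they do not certify behavior under batch
confounding or continuous topologies.

Under the entry-level dropout model, large counts are essentially never
zeroed, so per-cell Pearson correlation on the raw count scale is
insensitive to dropout damage (the observed matrix already correlates
≈ 0.99 with the truth). Recovery is therefore measured on log1p counts,
the usual scale for comparing expression profiles, where the damage and
its repair are visible (observed ≈ 0.85, imputed ≈ 0.87 on the default
benchmark).

## Numerical notes

- All matrices are dense float64, genes × cells; the benchmark sizes
  (≲ 2000 genes × ≲ 1000 cells) run in seconds on one core. The
  constrained smoother is evaluated gene-by-gene (one `cells × cells`
  exponentiation per gene) and matches a per-entry brute-force oracle to
  1e-10.
- Matrix powers are accumulated by repeated multiplication; row sums stay
  within 1e-10 of 1 for all evaluated t.
- Dense text I/O writes shortest-round-trip float representations and
  reads them with the exact (`round_trip`) parser, so write∘read is the
  identity — required for the bit-exact zero-only merge.
- `0^p = 0` for all p ≥ 1, so smoothing weights never leave the support of
  Mᵗ.

## Known limitations

- Biological zeros inside a cluster are filled like any other zero; the
  exponent mechanism attenuates but does not eliminate this (visible on
  the benchmark as imputed values at truth-zero positions).
- The neighbor-count rule is a fixed function of the cell count; it does
  not adapt to the number or balance of cell types.
- Cells and genes removed by filtering are reported as dropped, not
  imputed.
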