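"""Filtering, library-size normalization, and high-variance gene selection.

The smoothing graph downstream is only as good as the cells and genes that
enter it, so preprocessing does three things: drop genes with essentially no
expression and cells that express almost nothing, equalize sequencing depth
across cells by median library-size scaling, and pick the high-variance
genes (by coefficient of variation) on which cell-cell similarity is
computed.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import CountMatrix, HvgMatrix, NormalizedMatrix

log = logging.getLogger(__name__)

#: Downstream the neighbor-count rule is only defined for more than this
#: many cells, so filtering refuses to emit fewer.
MIN_CELLS = 15


def filter_matrix(
    raw: CountMatrix,
    gene_sum_min: float = 0.001,
    min_genes_per_cell: int = 3,
) -> CountMatrix:
    """Remove near-silent genes, then near-empty cells.

    A gene is kept when its total expression across all cells is strictly
    greater than ``gene_sum_min``; a cell is kept when, after the gene pass,
    it expresses strictly more than ``min_genes_per_cell`` genes.

    Raises
    ------
    ValueError
        If no gene survives or if 15 or fewer cells survive (the
        neighbor-count rule requires more than 15 cells).
    """
    gene_keep = raw.values.sum(axis=1) > gene_sum_min
    if not gene_keep.any():
        raise ValueError(f"no gene has total expression > {gene_sum_min}")
    sub = raw.subset(gene_idx=np.flatnonzero(gene_keep))
    cell_keep = (sub.values > 0).sum(axis=0) > min_genes_per_cell
    out = sub.subset(cell_idx=np.flatnonzero(cell_keep))
    if out.n_cells <= MIN_CELLS:
        raise ValueError(
            f"only {out.n_cells} cells remain after filtering; "
            f"more than {MIN_CELLS} are required for neighbor selection"
        )
    log.info(
        "filtered %d -> %d genes, %d -> %d cells",
        raw.n_genes, out.n_genes, raw.n_cells, out.n_cells,
    )
    return out


def normalize(counts: CountMatrix) -> NormalizedMatrix:
    """Median library-size normalization.

    Each cell's profile is divided by its total count and multiplied by the
    median total count, so all cells end up with the same library size while
    values stay on a count-like scale.  The per-cell size factors and the
    median are stored so the transform can be inverted exactly.
    """
    size_factors = counts.values.sum(axis=0)
    zero = np.flatnonzero(size_factors == 0)
    if zero.size:
        raise ValueError(
            f"cell '{counts.cell_ids[zero[0]]}' has zero total count; "
            "run filter_matrix first"
        )
    median_factor = float(np.median(size_factors))
    xn = counts.values / size_factors[None, :] * median_factor
    return NormalizedMatrix(
        xn=xn,
        size_factors=size_factors,
        median_factor=median_factor,
        gene_ids=counts.gene_ids,
        cell_ids=counts.cell_ids,
    )


def select_hvg(
    norm: NormalizedMatrix,
    mean_min: float = 0.01,
    cv_quantile: float = 0.25,
) -> HvgMatrix:
    """Select high-variance genes by coefficient of variation.

    A gene is eligible when its mean normalized expression is at least
    ``mean_min``; among eligible genes, those whose CV (population standard
    deviation divided by the mean) reaches the ``cv_quantile`` quantile of
    eligible CVs are retained.  The quantile uses linear interpolation
    between order statistics; mean and SD use the population denominator n.
    """
    means = norm.xn.mean(axis=1)
    eligible = np.flatnonzero(means >= mean_min)
    if eligible.size == 0:
        raise ValueError(f"no gene has mean normalized expression >= {mean_min}")
    sds = norm.xn[eligible].std(axis=1)  # ddof=0
    cvs = sds / means[eligible]
    threshold = float(np.quantile(cvs, cv_quantile))
    selected = eligible[cvs >= threshold]
    if selected.size == 0:  # unreachable with a finite quantile, kept as a guard
        raise ValueError("no gene passes the coefficient-of-variation filter")
    log.info(
        "selected %d / %d high-variance genes (CV threshold %.4g)",
        selected.size, norm.n_genes, threshold,
    )
    return HvgMatrix(
        xh=norm.xn[selected],
        selected_gene_indices=selected,
        gene_ids=norm.gene_ids[selected],
        cell_ids=norm.cell_ids,
    )


def denormalize(values: np.ndarray, norm: NormalizedMatrix) -> np.ndarray:
    """Invert :func:`normalize` for any matrix on the normalized scale."""
    return values * norm.size_factors[None, :] / norm.median_factor
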