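"""Constrained smoothing, rescaling, zero-only merge, and the full pipeline.

The imputed value for gene g in cell c is a weighted average of g's
normalized expression over all cells, with weights obtained by raising row
c of the stabilized transition matrix to the exponent p[g, c] and
renormalizing.  Exponent 1 recovers plain diffusion; exponents up to 3
concentrate the weights onto the most similar cells, which is how highly
expressed genes are protected from oversmoothing.  The smoothed matrix is
rescaled per gene, mapped back to the raw count scale, and merged with the
observed counts so that only observed zeros are ever replaced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Any

import numpy as np

from . import constraint, markov, preprocess
from .containers import (
    CountMatrix,
    ImputedMatrix,
    NormalizedMatrix,
    PowerMatrix,
    TransitionMatrix,
)

log = logging.getLogger(__name__)

__all__ = [
    "constrained_smooth",
    "rescale_and_denormalize",
    "merge_with_observed",
    "ImputeConfig",
    "PipelineResult",
    "run_pipeline",
]


def constrained_smooth(
    xn: NormalizedMatrix, m_stable: TransitionMatrix, p: PowerMatrix
) -> np.ndarray:
    """Diffuse the normalized matrix with per-gene, per-cell exponents.

    For gene g and cell c the smoothing weights over cells k are
    ``Mt[c, k] ** p[g, c]`` renormalized to sum to 1, and the output is the
    weighted average of ``xn[g, :]``.  Zero transition probabilities stay
    zero under any positive exponent, so the sparsity pattern of the
    weights matches the transition support.
    """
    mt = m_stable.m
    if xn.n_cells != mt.shape[0] or p.p.shape != xn.xn.shape:
        raise ValueError("dimension mismatch between xn, transition matrix, and p")
    rowsums = mt.sum(axis=1)
    if np.any(rowsums == 0):
        c = int(np.flatnonzero(rowsums == 0)[0])
        raise ValueError(f"row {c} of the transition matrix is entirely zero")
    out = np.empty_like(xn.xn)
    for g in range(xn.n_genes):
        w = mt ** p.p[g][:, None]  # exponent varies with the target cell (row)
        w /= w.sum(axis=1, keepdims=True)
        out[g] = w @ xn.xn[g]
    return out


def rescale_and_denormalize(
    xhat: np.ndarray, xn: NormalizedMatrix, rescale: str = "none"
) -> np.ndarray:
    """Optionally restore per-gene scale, then invert the normalization.

    With ``rescale="gene-max"`` every gene row whose smoothed maximum is
    positive is multiplied so its maximum over cells matches that gene's
    maximum in the normalized matrix, counteracting the shrinkage of
    extremes under diffusion.  The default ``"none"`` leaves the smoothed
    values untouched: on overdispersed counts the max-ratio factor is
    dominated by the sampling extremes of the raw data and inflates every
    imputed entry of the gene, so plain denormalization is the safer
    default.  The result is mapped back to the raw count scale with the
    stored size factors.
    """
    if rescale not in ("gene-max", "none"):
        raise ValueError(f"unknown rescale mode '{rescale}'")
    scaled = xhat
    if rescale == "gene-max":
        hat_max = xhat.max(axis=1)
        xn_max = xn.xn.max(axis=1)
        factor = np.ones_like(hat_max)
        nz = hat_max > 0
        factor[nz] = xn_max[nz] / hat_max[nz]
        scaled = xhat * factor[:, None]
    return preprocess.denormalize(scaled, xn)


def merge_with_observed(
    observed: CountMatrix, xbar: np.ndarray, xhat: np.ndarray | None = None
) -> ImputedMatrix:
    """Replace only the observed zeros with imputed values.

    Nonzero observations are carried through bit-exactly; zeros take the
    corresponding entry of the denormalized imputed matrix.
    """
    if observed.values.shape != xbar.shape:
        raise ValueError(
            f"observed shape {observed.values.shape} != imputed shape {xbar.shape}"
        )
    final = np.where(observed.values != 0, observed.values, xbar)
    return ImputedMatrix(
        final=final,
        xbar=xbar,
        xhat=xhat,
        gene_ids=observed.gene_ids,
        cell_ids=observed.cell_ids,
    )


@dataclass
class ImputeConfig:
    """Tunable parameters of the full pipeline, with field defaults.

    ``xa_source`` selects the matrix from which neighbor means (and hence
    exponents) are computed: ``"xn"`` uses all genes of the normalized
    matrix; ``"xh-default-lo"`` restricts the min-max scaling to the
    high-variance genes and assigns every other gene the unconstrained
    exponent ``power_lo``.
    """

    gene_sum_min: float = 0.001
    min_genes_per_cell: int = 3
    hvg_mean_min: float = 0.01
    cv_quantile: float = 0.25
    pca_dim: int | None = None
    k: int = 5
    neighbor_multiplier: int = 3
    t_max: int = 12
    r2_threshold: float = 0.95
    n_neighbors: int | None = None  # None: derived from the cell count
    power_lo: float = 1.0
    power_hi: float = 3.0
    rescale: str = "none"
    xa_source: str = "xn"
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class PipelineResult:
    """Everything a run produced, including the data-driven choices made."""

    imputed: ImputedMatrix
    filtered: CountMatrix
    normalized: NormalizedMatrix
    transition: TransitionMatrix
    t: int
    n_neighbors: int
    n_hvg: int
    r2_trace: list[float]
    config: ImputeConfig

    def report(self) -> dict[str, Any]:
        return {
            "t": self.t,
            "n_neighbors": self.n_neighbors,
            "n_hvg": self.n_hvg,
            "n_genes_kept": self.filtered.n_genes,
            "n_cells_kept": self.filtered.n_cells,
            "r2_trace": [float(x) for x in self.r2_trace],
            "params": self.config.to_dict(),
        }


def run_pipeline(raw: CountMatrix, config: ImputeConfig | None = None) -> PipelineResult:
    """Run the whole imputation pipeline on a raw count matrix.

    Stages: filter -> normalize -> HVG selection -> PCA -> adaptive
    affinity -> Markov matrix -> diffusion-time selection -> neighbor
    means -> power exponents -> constrained smoothing -> rescale and
    denormalize -> zero-only merge.  Deterministic for a fixed seed.
    """
    cfg = config or ImputeConfig()
    try:
        filtered = preprocess.filter_matrix(
            raw, cfg.gene_sum_min, cfg.min_genes_per_cell
        )
        norm = preprocess.normalize(filtered)
        xh = preprocess.select_hvg(norm, cfg.hvg_mean_min, cfg.cv_quantile)
        emb = markov.embed_pca(xh, cfg.pca_dim, seed=cfg.seed)
        aff = markov.adaptive_affinity(emb, cfg.k, cfg.neighbor_multiplier)
        m1 = markov.to_markov(aff)
        m_stable = markov.select_diffusion_time(m1, xh, cfg.t_max, cfg.r2_threshold)
        n = cfg.n_neighbors or constraint.neighbor_count(filtered.n_cells)
        if cfg.xa_source == "xn":
            xa = constraint.neighbor_mean(m_stable, norm, n)
            p = constraint.power_matrix(xa, cfg.power_lo, cfg.power_hi)
        elif cfg.xa_source == "xh-default-lo":
            xa_h, _ = constraint._neighbor_mean_values(m_stable.m, xh.xh, n)
            mn, mx = xa_h.min(), xa_h.max()
            p_full = np.full(norm.xn.shape, cfg.power_lo)
            if mx > mn:
                p_full[xh.selected_gene_indices] = (
                    (xa_h - mn) / (mx - mn) * (cfg.power_hi - cfg.power_lo)
                    + cfg.power_lo
                )
            p = PowerMatrix(p=p_full, lo=cfg.power_lo, hi=cfg.power_hi)
        else:
            raise ValueError(f"unknown xa_source '{cfg.xa_source}'")
        xhat = constrained_smooth(norm, m_stable, p)
        xbar = rescale_and_denormalize(xhat, norm, cfg.rescale)
        imputed = merge_with_observed(filtered, xbar, xhat=xhat)
    except ValueError as err:
        raise ValueError(f"pipeline failed: {err}") from err
    log.info(
        "pipeline: t=%d, n_neighbors=%d, hvg=%d, genes=%d, cells=%d",
        m_stable.t, n, xh.xh.shape[0], filtered.n_genes, filtered.n_cells,
    )
    return PipelineResult(
        imputed=imputed,
        filtered=filtered,
        normalized=norm,
        transition=m_stable,
        t=m_stable.t,
        n_neighbors=n,
        n_hvg=int(xh.xh.shape[0]),
        r2_trace=list(m_stable.r2_trace),
        config=cfg,
    )
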