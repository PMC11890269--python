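"""Evaluation utilities: dropout-expression correlation, clustering
agreement, and per-cell correlation to a reference.

These mirror the standard imputation benchmarks: the within-cell-type
Pearson correlation between per-gene total expression and per-gene dropout
rate (negative in real data — lowly expressed genes drop out more),
clustering agreement against known labels (ARI, NMI, purity), and per-cell
correlation of an expression matrix against a reference profile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.metrics.cluster import contingency_matrix

from .containers import CountMatrix, LabelVector

log = logging.getLogger(__name__)

__all__ = [
    "ClusteringScores",
    "expression_dropout_correlation",
    "clustering_scores",
    "correlation_to_reference",
]


@dataclass
class ClusteringScores:
    ari: float
    nmi: float
    purity: float


def expression_dropout_correlation(
    counts: CountMatrix, labels: LabelVector
) -> float:
    """Mean within-cell-type correlation between expression and dropout rate.

    For each cell type with at least 3 cells: per gene, the total
    expression over the type's cells and the fraction of zero entries are
    computed; genes constant across the type's cells are dropped; the
    Pearson correlation across the remaining genes is taken.  The unweighted
    mean over cell types is returned.  Types with a degenerate
    (zero-variance) vector pair are skipped with a warning; if every type is
    skipped the computation fails.
    """
    if len(labels) != counts.n_cells:
        raise ValueError("labels must have one entry per cell")
    results = []
    for cell_type in np.unique(labels.labels):
        cols = np.flatnonzero(labels.labels == cell_type)
        if cols.size < 3:
            warnings.warn(f"cell type '{cell_type}' has < 3 cells; skipped")
            continue
        sub = counts.values[:, cols]
        varying = sub.std(axis=1) > 0
        total = sub[varying].sum(axis=1)
        droprate = (sub[varying] == 0).mean(axis=1)
        if varying.sum() < 2 or total.std() == 0 or droprate.std() == 0:
            warnings.warn(
                f"cell type '{cell_type}' has a degenerate expression/dropout pair; skipped"
            )
            continue
        r = float(stats.pearsonr(total, droprate).statistic)
        results.append(r)
    if not results:
        raise ValueError("no cell type yielded a defined correlation")
    return float(np.mean(results))


def clustering_scores(pred: LabelVector, truth: LabelVector) -> ClusteringScores:
    """ARI, NMI (arithmetic-mean normalization), and purity.

    Purity assigns each predicted cluster its best-overlapping truth class
    and reports the fraction of cells so explained.
    """
    if len(pred) != len(truth):
        raise ValueError(f"label lengths differ: {len(pred)} vs {len(truth)}")
    if len(pred) < 2:
        raise ValueError("at least 2 cells are required")
    t, p = truth.labels, pred.labels
    ari = float(adjusted_rand_score(t, p))
    nmi = float(normalized_mutual_info_score(t, p, average_method="arithmetic"))
    # contingency rows = truth classes, columns = predicted clusters
    cont = contingency_matrix(t, p)
    purity = float(cont.max(axis=0).sum() / cont.sum())
    return ClusteringScores(ari=ari, nmi=nmi, purity=purity)


def correlation_to_reference(
    m: CountMatrix,
    reference: CountMatrix,
    method: str = "pearson",
    mapping: dict[str, str] | None = None,
) -> np.ndarray:
    """Per-cell correlation of ``m`` against a reference profile.

    Gene sets are intersected by id.  Each cell of ``m`` is matched to a
    reference column: through ``mapping`` (cell id -> reference column id)
    when given, by identical cell id otherwise, or to the single reference
    column if the reference has exactly one.  Returns one correlation per
    cell of ``m`` in order.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method '{method}'")
    shared, m_idx, r_idx = np.intersect1d(
        m.gene_ids.astype(str), reference.gene_ids.astype(str), return_indices=True
    )
    if shared.size < 3:
        raise ValueError(f"only {shared.size} shared genes; at least 3 are required")
    mv = m.values[m_idx]
    rv = reference.values[r_idx]
    ref_col = {cid: j for j, cid in enumerate(reference.cell_ids)}
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    out = np.empty(m.n_cells)
    for c, cid in enumerate(m.cell_ids):
        if mapping is not None:
            j = ref_col[mapping[cid]]
        elif reference.n_cells == 1:
            j = 0
        else:
            if cid not in ref_col:
                raise ValueError(f"cell '{cid}' has no matching reference column")
            j = ref_col[cid]
        out[c] = corr(mv[:, c], rv[:, j]).statistic
    return out
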