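"""Expression-dependent diffusion exponents.

Dropout rates fall with expression level, so an observed zero in a highly
expressed gene is more likely a genuine biological zero than a technical
miss.  The constraint encodes this: for each gene and cell, the average
expression of the cell's most probable transition neighbors is min-max
scaled into an exponent in [1, 3] that is later applied to the transition
probabilities — larger exponents concentrate smoothing weight on the most
similar cells, so highly expressed genes diffuse less.
"""

from __future__ import annotations

import numpy as np

from .containers import NeighborMeanMatrix, NormalizedMatrix, PowerMatrix, TransitionMatrix

__all__ = ["neighbor_count", "neighbor_mean", "power_matrix"]


def neighbor_count(n_cells: int) -> int:
    """Number of high-probability neighbors to average over.

    100 neighbors for datasets of 1000 or more cells; below that the count
    interpolates linearly as round((N - 15) / 985 * 100) with half-up
    rounding, clamped to at least 1.  Datasets of 15 or fewer cells are
    rejected outright — the rule is undefined there.
    """
    if n_cells <= 15:
        raise ValueError(
            f"neighbor selection requires more than 15 cells, got {n_cells}"
        )
    if n_cells >= 1000:
        return 100
    n = int(np.floor((n_cells - 15) / (1000 - 15) * 100 + 0.5))  # half-up
    return int(np.clip(n, 1, n_cells - 1))


def _top_neighbors(row: np.ndarray, cell: int, n: int) -> np.ndarray:
    """Indices of the n largest entries of ``row`` excluding ``cell``.

    Ties are broken by ascending cell index (stable sort on the negated
    row), so the result is fully deterministic.
    """
    masked = row.copy()
    masked[cell] = -np.inf
    order = np.argsort(-masked, kind="stable")
    return order[:n]


def neighbor_mean(
    m_stable: TransitionMatrix, xn: NormalizedMatrix, n: int
) -> NeighborMeanMatrix:
    """Mean expression over each cell's n most probable neighbors.

    Neighbors of cell c are the n largest entries of row c of the
    stabilized transition matrix, self excluded; the output column for c is
    the arithmetic mean of the corresponding columns of the normalized
    matrix.
    """
    xa, sets = _neighbor_mean_values(m_stable.m, xn.xn, n)
    return NeighborMeanMatrix(xa=xa, neighbor_sets=sets, n=n)


def _neighbor_mean_values(
    mt: np.ndarray, values: np.ndarray, n: int
) -> tuple[np.ndarray, list[np.ndarray]]:
    cells = mt.shape[0]
    if not 1 <= n <= cells - 1:
        raise ValueError(f"neighbor count n={n} must lie in [1, {cells - 1}]")
    xa = np.empty_like(values)
    sets: list[np.ndarray] = []
    for c in range(cells):
        nbrs = _top_neighbors(mt[c], c, n)
        sets.append(nbrs)
        xa[:, c] = values[:, nbrs].mean(axis=1)
    return xa, sets


def power_matrix(
    xa: NeighborMeanMatrix, lo: float = 1.0, hi: float = 3.0
) -> PowerMatrix:
    """Min-max scale the neighbor-mean matrix into exponents in [lo, hi].

    The minimum and maximum are taken over the entire matrix.  A constant
    matrix (no dynamic range) maps to all-``lo``, i.e. plain unconstrained
    diffusion.
    """
    if hi <= lo:
        raise ValueError(f"power range requires hi > lo, got [{lo}, {hi}]")
    mn, mx = float(xa.xa.min()), float(xa.xa.max())
    if mx == mn:
        p = np.full_like(xa.xa, lo)
    else:
        p = (xa.xa - mn) / (mx - mn) * (hi - lo) + lo
    return PowerMatrix(p=p, lo=lo, hi=hi)
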