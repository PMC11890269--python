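"""Cell-similarity graph, Markov transition matrix, and diffusion time.

Cells are embedded by PCA of the high-variance-gene matrix, connected by an
adaptive Gaussian kernel whose bandwidth per cell is the distance to its
k-th nearest neighbor, symmetrized additively, and row-normalized into a
Markov transition matrix M.  Diffusion proceeds by raising M to an integer
power t, chosen as the first step at which successive smoothed matrices
agree (squared Pearson correlation of the flattened matrices at or above a
threshold) so that smoothing stops once it has stabilized.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .containers import AffinityMatrix, Embedding, HvgMatrix, TransitionMatrix

log = logging.getLogger(__name__)

# Above this many cells the exact SVD is replaced by the seeded randomized
# solver; below it, results are deterministic regardless of the seed.
_EXACT_PCA_MAX_CELLS = 2000


def embed_pca(xh: HvgMatrix, d: int | None = None, seed: int = 0) -> Embedding:
    """Project cells onto the top ``d`` principal components of Xh.

    Genes are centered; the component sign is fixed by making the
    largest-magnitude loading of each component positive, so embeddings are
    reproducible across solvers and runs.
    """
    n_cells, n_genes = xh.n_cells, xh.xh.shape[0]
    bound = min(n_genes, n_cells - 1)
    if d is None:
        d = min(50, bound)
    if d < 2 or d > bound:
        raise ValueError(
            f"pca dimensionality d={d} must lie in [2, min(genes, cells-1)={bound}]"
        )
    solver = "full" if n_cells <= _EXACT_PCA_MAX_CELLS else "randomized"
    pca = PCA(n_components=d, svd_solver=solver, random_state=seed)
    scores = pca.fit_transform(xh.xh.T)
    # deterministic sign: largest |loading| of each component is positive
    flip = np.sign(
        pca.components_[np.arange(d), np.argmax(np.abs(pca.components_), axis=1)]
    )
    flip[flip == 0] = 1.0
    scores = scores * flip[None, :]
    return Embedding(coords=scores, d=d, cell_ids=xh.cell_ids)


def adaptive_affinity(
    emb: Embedding, k: int = 5, neighbor_multiplier: int = 3
) -> AffinityMatrix:
    """Adaptive Gaussian kernel on the kNN graph.

    For each cell i the bandwidth sigma_i is the Euclidean distance to its
    k-th nearest neighbor (self excluded).  Affinity exp(-(d/sigma_i)^2) is
    computed for the ``neighbor_multiplier * k`` nearest neighbors of i and
    is zero elsewhere; the asymmetric result is symmetrized as (A + A.T)/2.

    Cells with k or more exact duplicates would get sigma_i = 0; the
    bandwidth then falls back to the smallest positive neighbor distance,
    and if every neighbor distance is zero the cell is reported as an error.
    """
    n = emb.n_cells
    m = neighbor_multiplier * k
    if n <= m:
        raise ValueError(f"need more than {m} cells for {m}-neighbor affinities, got {n}")
    nn = NearestNeighbors(n_neighbors=m + 1).fit(emb.coords)
    dists, idx = nn.kneighbors(emb.coords)

    a = np.zeros((n, n))
    for i in range(n):
        # drop self from the neighbor list (ties may place it anywhere)
        self_pos = np.flatnonzero(idx[i] == i)
        keep = np.delete(np.arange(m + 1), self_pos[0] if self_pos.size else m)
        nbr_idx = idx[i, keep][:m]
        nbr_dist = dists[i, keep][:m]
        sigma = nbr_dist[k - 1]
        if sigma == 0:
            positive = nbr_dist[nbr_dist > 0]
            if positive.size == 0:
                raise ValueError(
                    f"cell '{emb.cell_ids[i]}' has {m} duplicate neighbors; "
                    "cannot set a kernel bandwidth"
                )
            sigma = positive.min()
        a[i, nbr_idx] = np.exp(-((nbr_dist / sigma) ** 2))
    a = (a + a.T) / 2.0
    return AffinityMatrix(a=a, cell_ids=emb.cell_ids)


def to_markov(a: AffinityMatrix) -> TransitionMatrix:
    """Row-normalize the affinity matrix into a Markov transition matrix."""
    rowsums = a.a.sum(axis=1)
    zero = np.flatnonzero(rowsums == 0)
    if zero.size:
        raise ValueError(
            f"cell '{a.cell_ids[zero[0]]}' is isolated (zero affinity row)"
        )
    return TransitionMatrix(
        m=a.a / rowsums[:, None], t=1, r2_trace=[0.0], cell_ids=a.cell_ids
    )


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation; 1 for identical constant arrays."""
    xs, ys = x.std(), y.std()
    if xs == 0 or ys == 0:
        return 1.0 if np.allclose(x, y) else 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def select_diffusion_time(
    m: TransitionMatrix,
    xh: HvgMatrix,
    t_max: int = 12,
    r2_threshold: float = 0.95,
) -> TransitionMatrix:
    """Raise M to the smallest power t >= 2 at which smoothing stabilizes.

    At each t the HVG matrix is diffused as ``S_t = Xh @ (M^t).T`` and the
    squared Pearson correlation between the flattened S_t and S_{t-1} is
    recorded; the first t at which it reaches ``r2_threshold`` is chosen
    (``t_max`` if the threshold is never met).
    """
    if t_max < 2:
        raise ValueError("t_max must be at least 2")
    base = m.m
    s_prev = xh.xh @ base.T
    power = base
    trace = [0.0]
    for t in range(2, t_max + 1):
        power = power @ base
        s = xh.xh @ power.T
        r2 = _r_squared(s.ravel(), s_prev.ravel())
        trace.append(r2)
        if r2 >= r2_threshold:
            log.info("diffusion stabilized at t=%d (R^2=%.5f)", t, r2)
            return TransitionMatrix(m=power, t=t, r2_trace=trace, cell_ids=m.cell_ids)
        s_prev = s
    log.info("diffusion did not stabilize by t_max=%d; using t=%d", t_max, t_max)
    return TransitionMatrix(m=power, t=t_max, r2_trace=trace, cell_ids=m.cell_ids)
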