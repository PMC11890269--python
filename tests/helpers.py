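"""Small constructors shared by the test modules."""

import numpy as np

import acimpute as ac


def count_matrix(values, gene_prefix="g", cell_prefix="c") -> ac.CountMatrix:
    """Build a CountMatrix with sequential identifiers."""
    v = np.asarray(values, dtype=float)
    return ac.CountMatrix(
        v,
        [f"{gene_prefix}{i}" for i in range(v.shape[0])],
        [f"{cell_prefix}{j}" for j in range(v.shape[1])],
    )


def normalized_matrix(values) -> ac.NormalizedMatrix:
    """Wrap raw values as an already-normalized matrix (unit size factors)."""
    v = np.asarray(values, dtype=float)
    return ac.NormalizedMatrix(
        xn=v,
        size_factors=np.ones(v.shape[1]),
        median_factor=1.0,
        gene_ids=[f"g{i}" for i in range(v.shape[0])],
        cell_ids=[f"c{j}" for j in range(v.shape[1])],
    )


def random_transition(n_cells: int, seed: int) -> ac.TransitionMatrix:
    """Row-stochastic matrix derived from uniform random affinities."""
    rng = np.random.default_rng(seed)
    a = rng.random((n_cells, n_cells))
    np.fill_diagonal(a, 0.0)
    return ac.TransitionMatrix(
        m=a / a.sum(axis=1, keepdims=True),
        t=1,
        r2_trace=[0.0],
        cell_ids=[f"c{j}" for j in range(n_cells)],
    )


def log1p_matrix(cm: ac.CountMatrix) -> ac.CountMatrix:
    return ac.CountMatrix(np.log1p(cm.values), cm.gene_ids, cm.cell_ids)


def align_truth(truth: ac.CountMatrix, filtered: ac.CountMatrix) -> np.ndarray:
    """Truth values restricted to the filtered matrix's genes and cells."""
    gidx = {g: i for i, g in enumerate(truth.gene_ids)}
    cidx = {c: i for i, c in enumerate(truth.cell_ids)}
    gi = [gidx[g] for g in filtered.gene_ids]
    ci = [cidx[c] for c in filtered.cell_ids]
    return truth.values[np.ix_(gi, ci)]
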