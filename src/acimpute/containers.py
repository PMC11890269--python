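"""Typed containers shared across the pipeline.

Every expression matrix in this package is oriented genes x cells.  The
containers are thin dataclasses around numpy arrays: they validate their
invariants on construction and carry the identifier metadata needed for
I/O round-trips and for the exact reverse of library-size normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CountMatrix",
    "LabelVector",
    "NormalizedMatrix",
    "HvgMatrix",
    "Embedding",
    "AffinityMatrix",
    "TransitionMatrix",
    "NeighborMeanMatrix",
    "PowerMatrix",
    "ImputedMatrix",
]


def _ids(raw, n: int, what: str) -> np.ndarray:
    ids = np.asarray([str(x) for x in raw], dtype=object)
    if ids.shape != (n,):
        raise ValueError(f"{what}: expected {n} identifiers, got {ids.shape}")
    if len(set(ids)) != n:
        dup = sorted({x for x in ids if list(ids).count(x) > 1})
        raise ValueError(f"{what}: identifiers are not unique (e.g. {dup[:3]})")
    return ids


@dataclass
class CountMatrix:
    """Non-negative gene x cell expression matrix with identifiers."""

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("count matrix must be two-dimensional (genes x cells)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("count matrix contains non-finite entries")
        if np.any(self.values < 0):
            g, c = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative expression value at gene row {g}, cell column {c}"
            )
        self.gene_ids = _ids(self.gene_ids, self.values.shape[0], "gene_ids")
        self.cell_ids = _ids(self.cell_ids, self.values.shape[1], "cell_ids")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, gene_idx=None, cell_idx=None) -> "CountMatrix":
        gi = np.arange(self.n_genes) if gene_idx is None else np.asarray(gene_idx)
        ci = np.arange(self.n_cells) if cell_idx is None else np.asarray(cell_idx)
        return CountMatrix(
            self.values[np.ix_(gi, ci)], self.gene_ids[gi], self.cell_ids[ci]
        )


@dataclass
class LabelVector:
    """Per-cell string labels aligned to a CountMatrix by cell id."""

    labels: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray([str(x) for x in self.labels], dtype=object)
        self.cell_ids = _ids(self.cell_ids, len(self.labels), "cell_ids")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class NormalizedMatrix:
    """Library-size normalized matrix plus everything needed to invert it.

    ``xn[g, c] = counts[g, c] / size_factors[c] * median_factor`` where
    ``size_factors`` are the per-cell column sums of the filtered counts and
    ``median_factor`` is their median, so the original counts are recovered
    exactly as ``xn * size_factors / median_factor``.
    """

    xn: np.ndarray
    size_factors: np.ndarray
    median_factor: float
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.xn = np.asarray(self.xn, dtype=np.float64)
        self.size_factors = np.asarray(self.size_factors, dtype=np.float64)
        if np.any(self.size_factors <= 0):
            raise ValueError("size factors must be positive")
        if self.median_factor <= 0:
            raise ValueError("median factor must be positive")
        if self.size_factors.shape != (self.xn.shape[1],):
            raise ValueError("one size factor per cell is required")
        self.gene_ids = _ids(self.gene_ids, self.xn.shape[0], "gene_ids")
        self.cell_ids = _ids(self.cell_ids, self.xn.shape[1], "cell_ids")

    @property
    def n_genes(self) -> int:
        return self.xn.shape[0]

    @property
    def n_cells(self) -> int:
        return self.xn.shape[1]


@dataclass
class HvgMatrix:
    """High-variance-gene submatrix of a NormalizedMatrix."""

    xh: np.ndarray
    selected_gene_indices: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.xh = np.asarray(self.xh, dtype=np.float64)
        self.selected_gene_indices = np.asarray(self.selected_gene_indices, dtype=int)
        if self.xh.shape[0] != len(self.selected_gene_indices):
            raise ValueError("selected index list must match the HVG matrix rows")
        self.gene_ids = _ids(self.gene_ids, self.xh.shape[0], "gene_ids")
        self.cell_ids = _ids(self.cell_ids, self.xh.shape[1], "cell_ids")

    @property
    def n_cells(self) -> int:
        return self.xh.shape[1]


@dataclass
class Embedding:
    """PCA scores of the cells, cells x d."""

    coords: np.ndarray
    d: int
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape[1] != self.d:
            raise ValueError("embedding dimensionality mismatch")
        self.cell_ids = _ids(self.cell_ids, self.coords.shape[0], "cell_ids")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


@dataclass
class AffinityMatrix:
    """Symmetric sparse-support Gaussian affinity between cells, entries in [0, 1]."""

    a: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.float64)
        n = self.a.shape[0]
        if self.a.shape != (n, n):
            raise ValueError("affinity matrix must be square")
        if np.any(self.a < 0) or np.any(self.a > 1):
            raise ValueError("affinities must lie in [0, 1]")
        if not np.allclose(self.a, self.a.T, atol=1e-12):
            raise ValueError("affinity matrix must be symmetric")
        self.cell_ids = _ids(self.cell_ids, n, "cell_ids")


@dataclass
class TransitionMatrix:
    """Row-stochastic cell x cell Markov matrix, possibly raised to power t.

    ``t`` is the diffusion time; ``r2_trace`` holds the stabilization
    diagnostic for each step (one entry per evaluated step, the first fixed
    at 0 because step 1 has no predecessor to compare with).
    """

    m: np.ndarray
    t: int
    r2_trace: list[float]
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=np.float64)
        n = self.m.shape[0]
        if self.m.shape != (n, n):
            raise ValueError("transition matrix must be square")
        if self.t < 1:
            raise ValueError("diffusion time must be >= 1")
        if len(self.r2_trace) != self.t:
            raise ValueError("r2_trace must have one entry per evaluated step")
        rowsums = self.m.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must sum to 1")
        self.cell_ids = _ids(self.cell_ids, n, "cell_ids")

    @property
    def n_cells(self) -> int:
        return self.m.shape[0]


@dataclass
class NeighborMeanMatrix:
    """Per-gene mean expression over each cell's n most probable neighbors."""

    xa: np.ndarray
    neighbor_sets: list[np.ndarray]
    n: int

    def __post_init__(self) -> None:
        self.xa = np.asarray(self.xa, dtype=np.float64)
        if len(self.neighbor_sets) != self.xa.shape[1]:
            raise ValueError("one neighbor set per cell is required")
        for c, ns in enumerate(self.neighbor_sets):
            if len(ns) != self.n:
                raise ValueError(f"neighbor set of cell {c} has {len(ns)} != n members")
            if c in ns:
                raise ValueError(f"cell {c} occurs in its own neighbor set")


@dataclass
class PowerMatrix:
    """Gene x cell diffusion exponents, min-max scaled into [lo, hi]."""

    p: np.ndarray
    lo: float = 1.0
    hi: float = 3.0

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if np.any(self.p < self.lo - 1e-12) or np.any(self.p > self.hi + 1e-12):
            raise ValueError(f"exponents must lie in [{self.lo}, {self.hi}]")


@dataclass
class ImputedMatrix:
    """Imputation output on both scales plus the zero-only merged result.

    ``xhat`` is the smoothed matrix on the normalized scale, ``xbar`` the
    rescaled and denormalized matrix on the raw count scale, and ``final``
    equals the observed counts wherever they are nonzero and ``xbar`` at the
    observed zeros.
    """

    final: np.ndarray
    xbar: np.ndarray
    xhat: np.ndarray | None
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.final = np.asarray(self.final, dtype=np.float64)
        self.xbar = np.asarray(self.xbar, dtype=np.float64)
        if np.any(self.final < 0) or np.any(self.xbar < 0):
            raise ValueError("imputed values must be non-negative")
        self.gene_ids = _ids(self.gene_ids, self.final.shape[0], "gene_ids")
        self.cell_ids = _ids(self.cell_ids, self.final.shape[1], "cell_ids")

    def as_count_matrix(self) -> CountMatrix:
        return CountMatrix(self.final, self.gene_ids, self.cell_ids)
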