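"""Cluster-structured synthetic counts with expression-dependent dropout.

The generator emulates the two features of real droplet data that the
imputation method relies on: discrete cell populations with marker genes
(negative-binomial counts around per-cluster log-normal means) and a
dropout process whose probability decays with the underlying expression
level, so lowly expressed genes lose more entries.  Dropout only ever
zeroes entries — it never alters a surviving count — which makes the truth
matrix a usable reference for recovery benchmarks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Any

import numpy as np

from .containers import CountMatrix, LabelVector

log = logging.getLogger(__name__)

__all__ = ["SyntheticDataset", "generate_truth", "apply_dropout", "calibrate_lam", "make_dataset"]

#: Fraction of genes per cluster promoted to markers (mean shifted up x5).
MARKER_FRACTION = 0.1
MARKER_SHIFT = 5.0


@dataclass
class SyntheticDataset:
    truth: CountMatrix
    observed: CountMatrix
    labels: LabelVector
    params: dict[str, Any]

    @property
    def observed_zero_fraction(self) -> float:
        return float((self.observed.values == 0).mean())


def _draw_cluster_means(
    rng: np.random.Generator, genes: int, clusters: int, mean_scale: float
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Per-cluster gene means with marker up-shifts; markers by cluster.

    Baseline means are drawn once per gene and shared across clusters, so
    clusters differ only through their marker genes — the usual structure
    of real cell populations, where most genes are housekeeping.
    """
    base = rng.lognormal(mean=np.log(mean_scale), sigma=1.0, size=genes)
    mu = np.tile(base[:, None], (1, clusters))
    n_markers = max(1, int(round(MARKER_FRACTION * genes)))
    markers: dict[int, np.ndarray] = {}
    for k in range(clusters):
        chosen = rng.choice(genes, size=n_markers, replace=False)
        mu[chosen, k] *= MARKER_SHIFT
        markers[k] = chosen
    return mu, markers


def generate_truth(
    genes: int,
    cells: int,
    clusters: int,
    mean_scale: float = 2.0,
    dispersion: float = 2.0,
    seed: int = 0,
) -> tuple[CountMatrix, LabelVector]:
    """Draw complete (pre-dropout) counts for a clustered population.

    Per-gene baseline means ~ LogNormal(log(mean_scale), 1) are shared
    across clusters; a random 10% of genes per cluster are up-shifted x5 to
    act as that cluster's markers.
    Counts are negative binomial with the cluster mean and the given
    dispersion (variance = mu + mu^2 / dispersion).  Cells are split across
    clusters as evenly as possible and then shuffled.
    """
    if clusters < 2:
        raise ValueError("at least 2 clusters are required")
    if genes < 1 or cells < clusters:
        raise ValueError(f"invalid sizes: genes={genes}, cells={cells}, clusters={clusters}")
    rng = np.random.default_rng(seed)
    mu, _ = _draw_cluster_means(rng, genes, clusters, mean_scale)
    assignment = rng.permutation(np.arange(cells) % clusters)
    mu_cells = mu[:, assignment]
    truth = rng.negative_binomial(
        dispersion, dispersion / (dispersion + mu_cells)
    ).astype(np.float64)
    gene_ids = [f"gene{g:05d}" for g in range(genes)]
    cell_ids = [f"cell{c:05d}" for c in range(cells)]
    counts = CountMatrix(truth, gene_ids, cell_ids)
    labels = LabelVector([f"cluster{k + 1}" for k in assignment], cell_ids)
    return counts, labels


def apply_dropout(truth: CountMatrix, lam: float, seed: int = 0) -> CountMatrix:
    """Zero each entry independently with probability exp(-lam * value).

    True zeros always stay zero (probability exp(0) = 1); large counts are
    almost never dropped, reproducing the inverse relationship between
    expression level and dropout rate.
    """
    if lam <= 0:
        raise ValueError("dropout strength lam must be positive")
    rng = np.random.default_rng(seed)
    drop = rng.random(truth.values.shape) < np.exp(-lam * truth.values)
    observed = np.where(drop, 0.0, truth.values)
    return CountMatrix(observed, truth.gene_ids, truth.cell_ids)


def calibrate_lam(
    truth: CountMatrix, target_zero_fraction: float, tol: float = 1e-4
) -> float:
    """Bisect the dropout strength to hit a target expected zero fraction.

    The expected zero fraction at strength lam is mean(exp(-lam * truth)),
    which decreases monotonically from 1 (lam -> 0) to the intrinsic zero
    fraction of the truth matrix (lam -> inf); bisection is exact here
    because no sampling is involved.
    """
    intrinsic = float((truth.values == 0).mean())
    if not intrinsic < target_zero_fraction < 1:
        raise ValueError(
            f"target zero fraction {target_zero_fraction} must lie strictly "
            f"between the intrinsic fraction {intrinsic:.3f} and 1"
        )

    def expected(lam: float) -> float:
        return float(np.exp(-lam * truth.values).mean())

    lo, hi = 1e-8, 1.0
    while expected(hi) > target_zero_fraction:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - defensive
            raise RuntimeError("dropout calibration failed to bracket the target")
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if expected(mid) > target_zero_fraction:
            lo = mid
        else:
            hi = mid
    lam = (lo + hi) / 2.0
    log.info("calibrated dropout lam=%.5f (expected zero fraction %.3f)", lam, expected(lam))
    return lam


def make_dataset(
    genes: int = 1500,
    cells: int = 300,
    clusters: int = 3,
    mean_scale: float = 2.0,
    dispersion: float = 2.0,
    lam: float | None = None,
    target_zero_fraction: float = 0.6,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a complete benchmark dataset (truth, observed, labels).

    When ``lam`` is not given it is calibrated by bisection so the expected
    observed zero fraction equals ``target_zero_fraction`` (default 60%, in
    the range typical of droplet scRNA-seq experiments).
    """
    seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    truth, labels = generate_truth(
        genes, cells, clusters, mean_scale, dispersion, seed=int(seeds[0])
    )
    if lam is None:
        lam = calibrate_lam(truth, target_zero_fraction)
    observed = apply_dropout(truth, lam, seed=int(seeds[1]))
    params = {
        "genes": genes,
        "cells": cells,
        "clusters": clusters,
        "mean_scale": mean_scale,
        "dispersion": dispersion,
        "lam": float(lam),
        "seed": seed,
    }
    return SyntheticDataset(truth=truth, observed=observed, labels=labels, params=params)
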