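"""Radiomic subtype discovery by consensus clustering.

Patients are clustered on z-standardized features with a Pearson-correlation
similarity; stability under repeated subsampling is summarised in a consensus
matrix whose proportion of ambiguous clustering (PAC) selects the cluster
count.

The inner clusterer defaults to k-means with a single random initialisation
per resample, run on row-standardized patient vectors — in that space
squared Euclidean distance is proportional to ``1 - r``, so this is k-means
under Pearson geometry. A deliberately *weak* inner clusterer is what makes
PAC informative: when k does not match the structure in the data, different
initialisations and subsamples land on different partitions and the
consensus entries smear into the ambiguous band. Deterministic agglomeration
(``inner="average"``: average linkage on ``1 - r``) is also available, but
it resolves a mismatched k the same way in every resample, which makes
coarse clusterings look spuriously stable and defeats PAC-based selection
of the cluster count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "ConsensusResult",
    "standardize",
    "pearson_similarity",
    "consensus_cluster",
    "select_k",
]


@dataclass
class ConsensusResult:
    consensus_matrices: dict  # k -> patients x patients co-clustering frequency
    assignments: pd.DataFrame  # patients x k columns of labels
    stability_curve: pd.Series  # k -> PAC statistic
    k_selected: int
    seed: int

    @property
    def consensus_matrix(self) -> pd.DataFrame:
        """Consensus matrix at the selected k."""
        return self.consensus_matrices[self.k_selected]

    def labels(self, k: int | None = None) -> pd.Series:
        return self.assignments[k if k is not None else self.k_selected]


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each feature column to zero mean and unit SD (n-1).

    Constant columns carry no contrast and are dropped with a warning.
    """
    matrix = pd.DataFrame(matrix)
    if matrix.shape[0] < 2:
        raise ValueError("need >=2 patients to standardize")
    sd = matrix.std(axis=0, ddof=1)
    # constant up to float round-off (e.g. a column of identical 4.2's has
    # sd ~ 1e-16, and z-scoring by it would amplify pure noise)
    tol = 1e-12 * matrix.abs().mean(axis=0).clip(lower=1.0)
    constant = sd[(sd <= tol) | sd.isna()].index.tolist()
    if len(constant) == matrix.shape[1]:
        raise ValueError("all feature columns are constant")
    if constant:
        warnings.warn(f"dropping {len(constant)} constant feature columns: {constant[:5]}")
        matrix = matrix.drop(columns=constant)
        sd = sd.drop(constant)
    return (matrix - matrix.mean(axis=0)) / sd


def pearson_similarity(matrix: pd.DataFrame) -> pd.DataFrame:
    """Patient-by-patient Pearson correlation of feature vectors."""
    matrix = pd.DataFrame(matrix)
    if matrix.shape[1] < 2:
        raise ValueError("need >=2 features per patient")
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1)
    bad = [str(p) for p in matrix.index[sd == 0]]
    if bad:
        raise ValueError(f"zero-variance patient vectors: {bad}")
    sim = np.corrcoef(values)
    return pd.DataFrame(sim, index=matrix.index, columns=matrix.index)


def _cluster_rows_average(values: np.ndarray, k: int) -> np.ndarray:
    """Average-linkage agglomeration on 1 - Pearson correlation."""
    dist = 1.0 - np.corrcoef(values)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return fcluster(linkage(squareform(dist, checks=False), method="average"),
                    k, criterion="maxclust")


def _row_standardize(values: np.ndarray) -> np.ndarray:
    """Center/scale each patient vector; Euclidean^2 here = 2m(1 - Pearson)."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd.ravel() == 0)
        raise ValueError(f"zero-variance patient vectors at rows {bad.tolist()}")
    return (values - mu) / sd


def _cluster_rows_kmeans(values: np.ndarray, k: int, random_state: int) -> np.ndarray:
    """One k-means run (single random init) under Pearson geometry."""
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=1, random_state=random_state)
    return km.fit(_row_standardize(values)).labels_


def _cut_consensus(consensus: np.ndarray, k: int) -> np.ndarray:
    dist = np.clip(1.0 - consensus, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    return fcluster(linkage(squareform(dist, checks=False), method="average"),
                    k, criterion="maxclust")


def consensus_cluster(
    matrix: pd.DataFrame,
    k_range=(2, 3, 4, 5, 6),
    n_resamples: int = 500,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    inner: str = "kmeans",
) -> ConsensusResult:
    """Consensus clustering of patients (rows) over subsampled replicates.

    For each resample, ``subsample_fraction`` of patients are drawn without
    replacement and clustered at every k; consensus(i, j) is the fraction of
    co-samples in which i and j landed in the same cluster. Final labels at
    each k cut an average-linkage tree built on ``1 - consensus``; the
    selected k minimises PAC (see :func:`select_k`).

    ``inner`` picks the per-resample clusterer: ``"kmeans"`` (default; one
    random initialisation per resample, Pearson geometry — see module
    docstring) or ``"average"`` (deterministic average linkage on 1 - r).
    """
    matrix = pd.DataFrame(matrix)
    n = matrix.shape[0]
    k_range = sorted(set(int(k) for k in k_range))
    if any(k < 2 or k > n - 1 for k in k_range):
        raise ValueError(f"k_range {k_range} outside [2, {n - 1}]")
    if not 0.5 < subsample_fraction <= 1.0:
        raise ValueError("subsample_fraction must be in (0.5, 1]")
    if inner not in ("kmeans", "average"):
        raise ValueError(f"unknown inner clusterer {inner!r}")
    rng = np.random.default_rng(seed)
    values = matrix.to_numpy(dtype=float)
    m = max(2, int(round(subsample_fraction * n)))

    co_count = {k: np.zeros((n, n)) for k in k_range}
    co_sampled = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
        co_sampled[np.ix_(idx, idx)] += 1
        sub = values[idx]
        for k in k_range:
            if inner == "kmeans":
                lab = _cluster_rows_kmeans(sub, k, int(rng.integers(2**31)))
            else:
                lab = _cluster_rows_average(sub, k)
            same = lab[:, None] == lab[None, :]
            co_count[k][np.ix_(idx, idx)] += same
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = {
            k: np.where(co_sampled > 0, co_count[k] / np.maximum(co_sampled, 1), 0.0)
            for k in k_range
        }
    for k in k_range:
        np.fill_diagonal(consensus[k], 1.0)

    assignments = {}
    pac = {}
    for k in k_range:
        assignments[k] = _cut_consensus(consensus[k], k)
        off = consensus[k][np.triu_indices(n, 1)]
        pac[k] = float(np.mean((off > 0.1) & (off < 0.9)))
    stability = pd.Series(pac).sort_index()
    result = ConsensusResult(
        consensus_matrices={
            k: pd.DataFrame(consensus[k], index=matrix.index, columns=matrix.index)
            for k in k_range
        },
        assignments=pd.DataFrame(assignments, index=matrix.index),
        stability_curve=stability,
        k_selected=0,
        seed=seed,
    )
    result.k_selected = select_k(result)
    return result


def select_k(result: ConsensusResult) -> int:
    """Cluster count minimising the proportion of ambiguous clustering.

    PAC(k) is the fraction of off-diagonal consensus entries in (0.1, 0.9);
    a stable k keeps co-clustering frequencies near 0 or 1. Ties break to
    the smallest k.
    """
    curve = result.stability_curve
    if len(curve) < 2:
        if len(curve) == 1:
            return int(curve.index[0])
        raise ValueError("stability curve needs >=2 candidate k")
    best = curve.min()
    return int(min(k for k, v in curve.items() if v == best))
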