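"""K-means clustering of the latent space and label-agreement metrics.

ARI, NMI and AMI follow their standard definitions (NMI/AMI normalized by
the arithmetic mean of the two label entropies; AMI's expected mutual
information under the hypergeometric permutation model). ACC maximizes
per-cell agreement over one-to-one cluster mappings found by the
Hungarian algorithm on the contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import (
    adjusted_mutual_info_score,
    adjusted_rand_score,
    normalized_mutual_info_score,
)

__all__ = [
    "Partition",
    "ContingencyTable",
    "kmeans_latent",
    "contingency",
    "ari",
    "nmi",
    "ami",
    "acc",
    "evaluate_all",
]


@dataclass
class Partition:
    labels: np.ndarray
    n_clusters: int

    @classmethod
    def from_labels(cls, labels) -> "Partition":
        labels = np.asarray(labels, dtype=int)
        if labels.size == 0:
            raise ValueError("empty partition")
        _, dense = np.unique(labels, return_inverse=True)
        return cls(labels=dense, n_clusters=int(dense.max()) + 1)


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_sums: np.ndarray
    col_sums: np.ndarray
    n: int


def _as_partition(p) -> Partition:
    return p if isinstance(p, Partition) else Partition.from_labels(p)


def _check_pair(pe, pt) -> tuple[Partition, Partition]:
    pe, pt = _as_partition(pe), _as_partition(pt)
    if len(pe.labels) != len(pt.labels):
        raise ValueError(
            f"partition lengths differ: {len(pe.labels)} vs {len(pt.labels)}"
        )
    return pe, pt


def kmeans_latent(Z: np.ndarray, K: int, seed: int = 0) -> Partition:
    """K-means with k-means++ init and 20 restarts, best inertia kept."""
    Z = np.asarray(Z, dtype=np.float64)
    if K < 1 or K > Z.shape[0]:
        raise ValueError(f"K={K} out of range for {Z.shape[0]} cells")
    km = KMeans(n_clusters=K, n_init=20, random_state=seed)
    return Partition(labels=km.fit_predict(Z), n_clusters=K)


def contingency(pe, pt) -> ContingencyTable:
    """counts[i, j] = number of cells with predicted i and true j."""
    pe, pt = _check_pair(pe, pt)
    counts = np.zeros((pe.n_clusters, pt.n_clusters), dtype=int)
    np.add.at(counts, (pe.labels, pt.labels), 1)
    return ContingencyTable(
        counts=counts,
        row_sums=counts.sum(axis=1),
        col_sums=counts.sum(axis=0),
        n=int(counts.sum()),
    )


def ari(pe, pt) -> float:
    """Adjusted Rand index (pair counting with expected-index correction)."""
    pe, pt = _check_pair(pe, pt)
    if len(pe.labels) < 2:
        raise ValueError("ARI needs at least 2 samples")
    return float(adjusted_rand_score(pt.labels, pe.labels))


def nmi(pe, pt, average_method: str = "arithmetic") -> float:
    """Mutual information normalized by the mean of the label entropies."""
    pe, pt = _check_pair(pe, pt)
    if len(pe.labels) < 2:
        raise ValueError("NMI needs at least 2 samples")
    return float(normalized_mutual_info_score(
        pt.labels, pe.labels, average_method=average_method
    ))


def ami(pe, pt, average_method: str = "arithmetic") -> float:
    """Chance-adjusted mutual information under the permutation model."""
    pe, pt = _check_pair(pe, pt)
    if len(pe.labels) < 2:
        raise ValueError("AMI needs at least 2 samples")
    return float(adjusted_mutual_info_score(
        pt.labels, pe.labels, average_method=average_method
    ))


def acc(pe, pt) -> float:
    """Best-map clustering accuracy via Hungarian assignment.

    The contingency table is zero-padded to square when the two
    partitions have different cluster counts.
    """
    pe, pt = _check_pair(pe, pt)
    table = contingency(pe, pt).counts
    size = max(table.shape)
    padded = np.zeros((size, size), dtype=int)
    padded[: table.shape[0], : table.shape[1]] = table
    rows, cols = linear_sum_assignment(-padded)
    return float(padded[rows, cols].sum() / len(pe.labels))


def evaluate_all(Z: np.ndarray, truth, K: int | None = None, seed: int = 0) -> dict:
    """Cluster the latent and score it against the truth labels.

    K defaults to the number of distinct truth labels (the model is
    evaluated at the true cluster number).
    """
    truth = _as_partition(truth)
    Z = np.asarray(Z)
    if len(truth.labels) != Z.shape[0]:
        raise ValueError("truth labels do not match latent row count")
    if K is None:
        K = truth.n_clusters
    pred = kmeans_latent(Z, K, seed)
    return {
        "ari": ari(pred, truth),
        "nmi": nmi(pred, truth),
        "ami": ami(pred, truth),
        "acc": acc(pred, truth),
        "K": K,
        "seed": seed,
    }
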