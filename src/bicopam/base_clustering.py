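"""Hard base clusterers: KA-initialized k-means, bubble SOM, Ward HC.

Each clusterer maps one standardized dataset to a hard K-cluster partition
encoded as a binary K x M membership matrix whose columns each sum to one.
k-means uses the deterministic Kaufman build-phase seeding, so it has no
random state; the SOM takes an explicit seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from bicopam.dataio import ExpressionDataset, PreprocessingState

logger = logging.getLogger(__name__)


@dataclass
class HardPartition:
    """Binary K x M cluster membership from one clusterer on one dataset."""

    membership: np.ndarray  # K x M, dtype uint8, columns sum to 1
    method_tag: str  # kmeans_ka | som_bubble | hc_ward
    dataset_id: str

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership)
        colsums = self.membership.sum(axis=0)
        if not np.all(colsums == 1):
            raise ValueError("every gene column must sum to exactly 1")

    @property
    def n_clusters(self) -> int:
        return self.membership.shape[0]

    @property
    def n_genes(self) -> int:
        return self.membership.shape[1]

    @property
    def labels(self) -> np.ndarray:
        return self.membership.argmax(axis=0)


def labels_to_membership(labels: np.ndarray, n_clusters: int) -> np.ndarray:
    """Binary K x M matrix from a length-M label vector."""
    labels = np.asarray(labels)
    M = labels.shape[0]
    out = np.zeros((n_clusters, M), dtype=np.uint8)
    out[labels, np.arange(M)] = 1
    return out


def _require_standardized(dataset: ExpressionDataset) -> np.ndarray:
    if dataset.state is not PreprocessingState.STANDARDIZED:
        raise ValueError(
            f"clustering requires a standardized dataset; "
            f"'{dataset.dataset_id}' is '{dataset.state.value}'"
        )
    return dataset.values


# ---------------------------------------------------------------------------
# k-means with Kaufman (build-phase) initialization


def _kaufman_seeds(X: np.ndarray, K: int) -> np.ndarray:
    """Deterministic build-phase seeding of Kaufman & Rousseeuw.

    The first seed is the most central point (minimum total distance to all
    points).  Each subsequent seed is the point i maximizing the gain
    sum_j max(D_j - d(i, j), 0) where D_j is point j's distance to its
    nearest already-chosen seed.
    """
    D = cdist(X, X)
    seeds = [int(np.argmin(D.sum(axis=1)))]
    nearest = D[seeds[0]].copy()
    while len(seeds) < K:
        gain = np.maximum(nearest[None, :] - D, 0.0).sum(axis=1)
        gain[seeds] = -np.inf
        nxt = int(np.argmax(gain))
        seeds.append(nxt)
        nearest = np.minimum(nearest, D[nxt])
    return X[seeds].copy()


def kmeans_ka(
    dataset: ExpressionDataset,
    n_clusters: int,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> HardPartition:
    """k-means with deterministic Kaufman initialization (no RNG).

    Lloyd iterations on Euclidean distance over gene rows, run until the
    maximum centroid shift drops below ``tol`` or ``max_iter`` is reached.
    A cluster emptied during iteration is reseeded at the point farthest
    from its previous centroid.
    """
    X = _require_standardized(dataset)
    M = X.shape[0]
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if M <= n_clusters:
        raise ValueError(f"need more genes ({M}) than clusters ({n_clusters})")
    centroids = _kaufman_seeds(X, n_clusters)
    labels = np.zeros(M, dtype=int)
    for _ in range(max_iter):
        D = cdist(X, centroids)
        labels = D.argmin(axis=1)
        new_centroids = centroids.copy()
        for k in range(n_clusters):
            members = labels == k
            if members.any():
                new_centroids[k] = X[members].mean(axis=0)
            else:
                far = int(np.argmax(np.linalg.norm(X - centroids[k], axis=1)))
                new_centroids[k] = X[far]
                logger.info(
                    "kmeans_ka: empty cluster %d reseeded at point %d "
                    "(dataset '%s')",
                    k,
                    far,
                    dataset.dataset_id,
                )
        shift = np.linalg.norm(new_centroids - centroids, axis=1).max()
        centroids = new_centroids
        if shift < tol:
            break
    labels = cdist(X, centroids).argmin(axis=1)
    return HardPartition(
        membership=labels_to_membership(labels, n_clusters),
        method_tag="kmeans_ka",
        dataset_id=dataset.dataset_id,
    )


# ---------------------------------------------------------------------------
# SOM with bubble neighbourhood


def square_grid(n_clusters: int) -> tuple[int, int]:
    """Most nearly square (rows, cols) factorization with rows*cols == K."""
    best = (1, n_clusters)
    for r in range(1, int(np.sqrt(n_clusters)) + 1):
        if n_clusters % r == 0:
            best = (r, n_clusters // r)
    return best


def som_bubble(
    dataset: ExpressionDataset,
    grid: tuple[int, int] = (4, 4),
    seed: int = 0,
    epochs: int = 500,
) -> HardPartition:
    """Self-organizing map with a bubble neighbourhood on a rows x cols grid.

    Batch training: each epoch assigns every gene to its best-matching unit
    and replaces each unit's codebook vector by the mean of the genes whose
    BMU lies within the (linearly shrinking) bubble radius of that unit.
    The radius starts at half the grid diagonal and decays to zero.  Weights
    are initialized from randomly chosen gene profiles (seeded), so the same
    seed gives the identical partition.  Units that attract no genes yield
    empty clusters, which downstream consensus code tolerates.
    """
    X = _require_standardized(dataset)
    rows, cols = grid
    K = rows * cols
    M = X.shape[0]
    rng = np.random.default_rng(seed)
    weights = X[rng.choice(M, size=K, replace=M < K)].copy()
    # grid coordinates of each unit, and unit-unit grid distances
    coords = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=float)
    grid_dist = cdist(coords, coords)
    radius0 = 0.5 * np.sqrt((rows - 1) ** 2 + (cols - 1) ** 2)
    for epoch in range(epochs):
        radius = radius0 * (1.0 - epoch / max(epochs - 1, 1))
        bmu = cdist(X, weights).argmin(axis=1)
        # bubble: every unit within `radius` of a sample's BMU is pulled
        # equally; in batch form each unit becomes the mean of the samples
        # whose BMU is in its bubble.
        in_bubble = grid_dist <= radius  # K x K, unit vs BMU
        counts = np.bincount(bmu, minlength=K).astype(float)
        sums = np.zeros_like(weights)
        np.add.at(sums, bmu, X)
        pooled_counts = in_bubble @ counts
        pooled_sums = in_bubble @ sums
        nonempty = pooled_counts > 0
        weights[nonempty] = pooled_sums[nonempty] / pooled_counts[nonempty, None]
    labels = cdist(X, weights).argmin(axis=1)
    return HardPartition(
        membership=labels_to_membership(labels, K),
        method_tag="som_bubble",
        dataset_id=dataset.dataset_id,
    )


# ---------------------------------------------------------------------------
# Hierarchical clustering, Ward linkage


def hc_ward(dataset: ExpressionDataset, n_clusters: int) -> HardPartition:
    """Agglomerative Ward-linkage tree on Euclidean distance, cut at K."""
    X = _require_standardized(dataset)
    if n_clusters < 1 or n_clusters > X.shape[0]:
        raise ValueError("n_clusters must be in [1, n_genes]")
    Z = linkage(X, method="ward")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust") - 1
    return HardPartition(
        membership=labels_to_membership(labels, n_clusters),
        method_tag="hc_ward",
        dataset_id=dataset.dataset_id,
    )


# ---------------------------------------------------------------------------
# Serialization


def write_partition(partition: HardPartition, path: str | Path) -> None:
    """TSV: rows = clusters, columns = genes, 0/1 entries; tags in a comment."""
    with Path(path).open("w") as fh:
        fh.write(f"# method={partition.method_tag}\tdataset={partition.dataset_id}\n")
        for row in partition.membership:
            fh.write("\t".join(str(int(v)) for v in row) + "\n")


def read_partition(path: str | Path) -> HardPartition:
    with Path(path).open() as fh:
        header = fh.readline().strip()
        fields = dict(
            item.split("=", 1) for item in header.lstrip("# ").split("\t")
        )
        rows = [
            [int(v) for v in line.split("\t")] for line in fh if line.strip()
        ]
    return HardPartition(
        membership=np.array(rows, dtype=np.uint8),
        method_tag=fields.get("method", "unknown"),
        dataset_id=fields.get("dataset", "unknown"),
    )
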