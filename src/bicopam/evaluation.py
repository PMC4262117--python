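"""Cluster scoring: per-gene MSE, tightness ranking, MSE-vs-size surface.

The compactness of cluster k in one dataset is the per-gene, per-dimension
mean squared deviation from the cluster's mean profile,

    MSE_k = (1 / (N * M_k)) * sum_{x_i in C_k} ||x_i - z_k||^2,

with N the number of conditions, M_k the cluster size, C_k the set of
z-scored member profiles and z_k their mean.  Because cluster membership
comes from the consensus (not from any single dataset), the same gene sets
are scored in every dataset and the per-dataset MSEs are averaged
uniformly.  Clusters are ranked for tightness by the largest delta at which
they retain at least ``min_genes`` genes, larger clusters first on ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bicopam.binarization import BinarizedPartition
from bicopam.dataio import ExpressionDataset, PreprocessingState


@dataclass
class ClusterMSE:
    """Per-cluster, per-delta MSE across datasets."""

    cluster_id: int
    delta: float
    per_dataset_mse: dict[str, float]
    n_genes: int

    @property
    def mean_mse(self) -> float:
        vals = list(self.per_dataset_mse.values())
        return float(np.mean(vals)) if vals else math.nan


@dataclass
class TightnessRanking:
    """Clusters ordered by (max delta retaining >= min_genes, size there)."""

    order: list[int]  # cluster indices, tightest first
    max_delta: dict[int, float]  # -1.0 if the cluster never qualifies
    count_at_max_delta: dict[int, int]
    min_genes: int = 7
    retention: pd.DataFrame | None = field(default=None, repr=False)

    def top(self, n: int = 2) -> list[int]:
        return self.order[:n]


def mse_cluster(
    partition: BinarizedPartition, dataset: ExpressionDataset, k: int
) -> float:
    """Per-gene MSE of cluster ``k`` in one standardized dataset.

    Returns NaN for an empty cluster (undefined, never zero).
    """
    if dataset.state is not PreprocessingState.STANDARDIZED:
        raise ValueError("MSE requires a standardized dataset")
    members = partition.membership[k].astype(bool)
    m_k = int(members.sum())
    if m_k == 0:
        return math.nan
    X = dataset.values[members, :]
    z = X.mean(axis=0)
    n = dataset.n_conditions
    return float(((X - z) ** 2).sum() / (n * m_k))


def mse_report(
    partitions: list[BinarizedPartition],
    datasets: list[ExpressionDataset],
) -> list[ClusterMSE]:
    """MSE of every cluster at every delta, per dataset and averaged.

    Clusters empty at a given delta are omitted (membership is shared
    across datasets, so a cluster is empty globally or not at all).
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    report = []
    for part in partitions:
        sizes = part.cluster_sizes()
        for k in range(part.n_clusters):
            if sizes[k] == 0:
                continue
            per_ds = {
                ds.dataset_id: mse_cluster(part, ds, k) for ds in datasets
            }
            report.append(
                ClusterMSE(
                    cluster_id=k,
                    delta=part.delta,
                    per_dataset_mse=per_ds,
                    n_genes=int(sizes[k]),
                )
            )
    return report


def mse_report_frame(report: list[ClusterMSE]) -> pd.DataFrame:
    """Long-format MSE table (delta, cluster, dataset, mse, mean_mse, n_genes)."""
    rows = []
    for entry in report:
        for ds_id, mse in entry.per_dataset_mse.items():
            rows.append(
                {
                    "delta": entry.delta,
                    "cluster": entry.cluster_id,
                    "dataset": ds_id,
                    "mse": mse,
                    "mean_mse": entry.mean_mse,
                    "n_genes": entry.n_genes,
                }
            )
    return pd.DataFrame(rows)


def rank_tightness(
    partitions: list[BinarizedPartition], min_genes: int = 7
) -> TightnessRanking:
    """Order clusters by how far into the delta sweep they retain genes.

    A cluster's tightness is the largest delta at which it keeps at least
    ``min_genes`` genes; clusters sharing that delta are ordered by their
    gene count there (larger first), with the cluster index as the final
    deterministic tie-break.  A cluster that never retains ``min_genes``
    genes gets max_delta = -1 and is ordered by its count at the smallest
    delta of the grid.
    """
    deltas = [p.delta for p in partitions]
    if sorted(deltas) != deltas:
        raise ValueError("partitions must be sorted by ascending delta")
    counts = np.array([p.cluster_sizes() for p in partitions])  # D x K
    K = counts.shape[1]
    max_delta: dict[int, float] = {}
    count_at: dict[int, int] = {}
    for k in range(K):
        qualifying = np.where(counts[:, k] >= min_genes)[0]
        if qualifying.size:
            d = int(qualifying.max())
            max_delta[k] = float(deltas[d])
            count_at[k] = int(counts[d, k])
        else:
            max_delta[k] = -1.0
            count_at[k] = int(counts[0, k])
    order = sorted(
        range(K), key=lambda k: (-max_delta[k], -count_at[k], k)
    )
    retention = pd.DataFrame(
        counts, index=pd.Index(deltas, name="delta"),
        columns=[f"C{k + 1}" for k in range(K)],
    )
    return TightnessRanking(
        order=order,
        max_delta=max_delta,
        count_at_max_delta=count_at,
        min_genes=min_genes,
        retention=retention,
    )


def selection_surface(report: list[ClusterMSE]) -> pd.DataFrame:
    """Per delta, per cluster: (n_genes, mean_mse) with a Pareto-front flag.

    A cluster is on the front at its delta when no other cluster at the same
    delta has at least as many genes and at most its MSE with one strict
    inequality; the trade-off (more genes, lower MSE) is left to the user.
    """
    if not report:
        raise ValueError("empty MSE report")
    rows = [
        {
            "delta": e.delta,
            "cluster": e.cluster_id,
            "n_genes": e.n_genes,
            "mean_mse": e.mean_mse,
        }
        for e in report
    ]
    df = pd.DataFrame(rows)
    flags = np.ones(len(df), dtype=bool)
    for delta, grp in df.groupby("delta"):
        g = grp[["n_genes", "mean_mse"]].to_numpy()
        for a in range(len(grp)):
            for b in range(len(grp)):
                if a == b:
                    continue
                dominates = (
                    g[b, 0] >= g[a, 0]
                    and g[b, 1] <= g[a, 1]
                    and (g[b, 0] > g[a, 0] or g[b, 1] < g[a, 1])
                )
                if dominates:
                    flags[grp.index[a]] = False
                    break
    df["pareto"] = flags
    return df


def link_stats(
    n_nodes: int,
    n_links: int,
    null_mean: float | None = None,
    null_sd: float | None = None,
) -> dict[str, float]:
    """Connectivity arithmetic for an undirected co-expression network.

    Returns the number of possible unordered node pairs C(n, 2), the
    percentage of them realized as links, and — when a null mean/SD from
    random gene groups is supplied — the z-score of the observed link count
    under a normal null.
    """
    possible = n_nodes * (n_nodes - 1) // 2
    if n_links < 0 or n_links > possible:
        raise ValueError(f"n_links must be in [0, {possible}]")
    out: dict[str, float] = {
        "possible_pairs": float(possible),
        "percent": 100.0 * n_links / possible,
    }
    if null_mean is not None and null_sd is not None:
        out["z"] = (n_links - null_mean) / null_sd
    return out
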