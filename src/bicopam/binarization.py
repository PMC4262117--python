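"""Tunable binarization of the final CoPaM: MVB, DTB(delta), IB.

DTB assigns a gene to its maximum-membership cluster only when the runner-up
membership trails the maximum by at least ``delta``; otherwise the gene is
unassigned (its column is all zeros).  ``delta = 0`` reduces to MVB (every
gene assigned to its maximum) and ``delta = 1`` to IB (only unanimous,
binary columns survive), so raising ``delta`` sweeps a nested family of
ever-tighter clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from bicopam.consensus import CoPaM

logger = logging.getLogger(__name__)


@dataclass
class BinarizedPartition:
    """Binary K x M matrix; gene columns sum to 1 (assigned) or 0 (unassigned)."""

    membership: np.ndarray
    technique: str  # MVB | DTB | IB
    delta: float

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=np.uint8)
        colsums = self.membership.sum(axis=0)
        if not np.all((colsums == 0) | (colsums == 1)):
            raise ValueError("gene columns must sum to 0 or 1")

    @property
    def n_clusters(self) -> int:
        return self.membership.shape[0]

    @property
    def n_genes(self) -> int:
        return self.membership.shape[1]

    @property
    def assigned(self) -> np.ndarray:
        """Boolean mask of assigned genes."""
        return self.membership.sum(axis=0) == 1

    def cluster_sizes(self) -> np.ndarray:
        return self.membership.sum(axis=1).astype(int)

    def gene_sets(self, gene_ids) -> dict[int, set]:
        """Cluster index -> set of member gene identifiers."""
        gene_ids = np.asarray(gene_ids, dtype=object)
        return {
            k: set(gene_ids[self.membership[k].astype(bool)])
            for k in range(self.n_clusters)
        }


def _top_two(U: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per column: argmax row (lowest index on ties), max, second max."""
    top = U.argmax(axis=0)  # argmax takes the lowest index on exact ties
    mx = U[top, np.arange(U.shape[1])]
    masked = U.copy()
    masked[top, np.arange(U.shape[1])] = -np.inf
    second = masked.max(axis=0)
    return top, mx, second


def binarize_mvb(copam: CoPaM) -> BinarizedPartition:
    """Maximum value binarization: every gene goes to its max-membership cluster.

    Exact ties are broken to the lowest cluster index (and logged), so all
    genes are assigned and MVB columns always sum to 1.
    """
    U = copam.membership
    top, mx, second = _top_two(U)
    ties = np.where(mx == second)[0]
    if ties.size:
        logger.info("binarize_mvb: %d tied gene column(s): %s", ties.size, ties[:20])
    out = np.zeros_like(U, dtype=np.uint8)
    out[top, np.arange(U.shape[1])] = 1
    return BinarizedPartition(membership=out, technique="MVB", delta=0.0)


def binarize_dtb(copam: CoPaM, delta: float) -> BinarizedPartition:
    """Difference threshold binarization at tightness ``delta``.

    A gene is assigned to its maximum-membership cluster iff
    (max - second max) >= delta; otherwise its column is all zeros.  At
    ``delta = 0`` tied maxima fall back to the MVB tie rule (lowest index);
    at ``delta > 0`` a tie means a zero gap, hence unassigned.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError(f"delta must be in [0, 1], got {delta}")
    U = copam.membership
    top, mx, second = _top_two(U)
    keep = (mx - second) >= delta if delta > 0 else np.ones(U.shape[1], bool)
    out = np.zeros_like(U, dtype=np.uint8)
    cols = np.arange(U.shape[1])[keep]
    out[top[keep], cols] = 1
    return BinarizedPartition(membership=out, technique="DTB", delta=float(delta))


def binarize_ib(copam: CoPaM) -> BinarizedPartition:
    """Intersection binarization: keep only unanimously assigned (binary) columns."""
    part = binarize_dtb(copam, 1.0)
    return BinarizedPartition(membership=part.membership, technique="IB", delta=1.0)


DEFAULT_DELTA_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))


def delta_sweep(
    copam: CoPaM, deltas=DEFAULT_DELTA_GRID
) -> list[BinarizedPartition]:
    """DTB at every delta of an ascending grid (default 0.0 to 1.0 step 0.1)."""
    deltas = list(deltas)
    if sorted(deltas) != deltas:
        raise ValueError("delta grid must be ascending")
    return [binarize_dtb(copam, d) for d in deltas]


def sweep_counts(
    partitions: list[BinarizedPartition], cluster_labels=None
) -> pd.DataFrame:
    """Per-cluster gene counts over a delta sweep (rows = delta, cols = clusters)."""
    K = partitions[0].n_clusters
    labels = (
        list(cluster_labels)
        if cluster_labels is not None
        else [f"C{i + 1}" for i in range(K)]
    )
    data = {p.delta: p.cluster_sizes() for p in partitions}
    df = pd.DataFrame.from_dict(data, orient="index", columns=labels)
    df.index.name = "delta"
    return df
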