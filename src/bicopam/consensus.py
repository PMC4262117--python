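"""Fusing relabelled partitions into fuzzy consensus partition matrices.

Partitions from different clusterers (and datasets) use arbitrary cluster
numbering, so before averaging, each partition's rows are matched to a
reference by greedy min-min matching: repeatedly fix the globally closest
(reference row, target row) pair and remove both.  The running element-wise
average of the relabelled partitions is the CoPaM; per-dataset intermediate
CoPaMs are sharpened by membership pushing before the cross-dataset fusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from bicopam.base_clustering import HardPartition

logger = logging.getLogger(__name__)

_COLSUM_TOL = 1e-9


@dataclass
class CoPaM:
    """Fuzzy K x M consensus partition matrix; every column sums to 1."""

    membership: np.ndarray
    level: str  # "intermediate" (one dataset) or "final"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=float)
        if self.membership.min() < -_COLSUM_TOL or self.membership.max() > 1 + _COLSUM_TOL:
            raise ValueError("membership values must lie in [0, 1]")
        colsums = self.membership.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=_COLSUM_TOL):
            raise ValueError("every CoPaM column must sum to 1")

    @property
    def n_clusters(self) -> int:
        return self.membership.shape[0]

    @property
    def n_genes(self) -> int:
        return self.membership.shape[1]


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, (CoPaM, HardPartition)):
        return np.asarray(x.membership, dtype=float)
    return np.asarray(x, dtype=float)


def min_min_permutation(
    reference: np.ndarray, target: np.ndarray, method: str = "greedy"
) -> np.ndarray:
    """Row correspondence between two K x M membership matrices.

    Returns ``perm`` with ``perm[i] = j`` meaning target row ``j`` plays the
    role of reference row ``i``.  ``greedy`` is the min-min scheme: the
    globally closest (reference row, target row) pair (Euclidean distance
    between membership vectors; ties to the lowest index pair) is fixed
    first, both rows removed, and so on.  ``optimal`` solves the assignment
    problem exactly (Hungarian) on squared distances.
    """
    if reference.shape != target.shape:
        raise ValueError(
            f"shape mismatch: reference {reference.shape} vs target {target.shape}"
        )
    K = reference.shape[0]
    D = cdist(reference, target)
    perm = np.full(K, -1, dtype=int)
    if method == "optimal":
        rows, cols = linear_sum_assignment(D**2)
        perm[rows] = cols
        return perm
    if method != "greedy":
        raise ValueError(f"unknown relabeling method {method!r}")
    ref_free = np.ones(K, dtype=bool)
    tgt_free = np.ones(K, dtype=bool)
    work = D.copy()
    for _ in range(K):
        sub = np.where(
            ref_free[:, None] & tgt_free[None, :], work, np.inf
        )
        # argmin scans row-major, so ties resolve to the lowest (ref, tgt) pair
        i, j = np.unravel_index(np.argmin(sub), sub.shape)
        perm[i] = j
        ref_free[i] = False
        tgt_free[j] = False
    return perm


def relabel_min_min(
    reference: CoPaM | HardPartition | np.ndarray,
    target: HardPartition,
    method: str = "greedy",
) -> HardPartition:
    """Permute the target's cluster rows to match the reference's numbering."""
    ref = _as_matrix(reference)
    tgt = _as_matrix(target)
    perm = min_min_permutation(ref, tgt, method=method)
    return HardPartition(
        membership=np.asarray(target.membership)[perm, :],
        method_tag=target.method_tag,
        dataset_id=target.dataset_id,
    )


def build_intermediate_copam(
    partitions: list[HardPartition], method: str = "greedy"
) -> CoPaM:
    """Fuse one dataset's partitions into an intermediate CoPaM.

    The first partition is the reference; each subsequent partition is
    relabelled against the running element-wise average and averaged in with
    equal weight.
    """
    if not partitions:
        raise ValueError("need at least one partition")
    shapes = {p.membership.shape for p in partitions}
    if len(shapes) > 1:
        raise ValueError(f"partitions have differing shapes: {shapes}")
    running = _as_matrix(partitions[0])
    provenance = [f"{partitions[0].dataset_id}:{partitions[0].method_tag}"]
    for n, part in enumerate(partitions[1:], start=2):
        perm = min_min_permutation(running, _as_matrix(part), method=method)
        running = running + (np.asarray(part.membership, dtype=float)[perm, :] - running) / n
        provenance.append(f"{part.dataset_id}:{part.method_tag}")
    return CoPaM(membership=running, level="intermediate", provenance=provenance)


def push_memberships(copam: CoPaM) -> CoPaM:
    """Sharpen an intermediate CoPaM towards binary values.

    Per gene column: memberships below the mean of the column's nonzero
    values are zeroed, survivors are renormalized to sum 1.  Binary columns
    are fixed points, and no column ever gains support.
    """
    if copam.level != "intermediate":
        raise ValueError("push_memberships applies to intermediate CoPaMs")
    U = copam.membership.copy()
    nonzero = U > 0
    m = np.where(nonzero, U, np.nan)
    col_mean = np.nanmean(m, axis=0)  # every column has support, sum == 1
    U[U < col_mean[None, :]] = 0.0
    U /= U.sum(axis=0, keepdims=True)
    return CoPaM(membership=U, level="intermediate", provenance=list(copam.provenance))


def build_final_copam(intermediates: list[CoPaM], method: str = "greedy") -> CoPaM:
    """Fuse pushed per-dataset CoPaMs into the final CoPaM.

    Sequential min-min relabeling against the running average, then
    equal-weight element-wise averaging, exactly as for the intermediate
    stage; the result is tagged level "final".  Dataset order matters to the
    greedy matching and is therefore taken as given (and logged).
    """
    if not intermediates:
        raise ValueError("need at least one intermediate CoPaM")
    for c in intermediates:
        if c.level != "intermediate":
            raise ValueError("inputs must be intermediate CoPaMs")
    logger.info(
        "build_final_copam: fusing %d dataset CoPaMs in the given order",
        len(intermediates),
    )
    running = intermediates[0].membership.copy()
    provenance = list(intermediates[0].provenance)
    for n, copam in enumerate(intermediates[1:], start=2):
        perm = min_min_permutation(running, copam.membership, method=method)
        running = running + (copam.membership[perm, :] - running) / n
        provenance.extend(copam.provenance)
    return CoPaM(membership=running, level="final", provenance=provenance)


# ---------------------------------------------------------------------------
# Serialization


def write_copam(copam: CoPaM, path: str | Path) -> None:
    """TSV of fuzzy values, 12-digit precision, metadata in a comment line."""
    with Path(path).open("w") as fh:
        fh.write(
            f"# level={copam.level}\tK={copam.n_clusters}\t"
            f"provenance={';'.join(copam.provenance)}\n"
        )
        for row in copam.membership:
            fh.write("\t".join(f"{v:.12f}" for v in row) + "\n")


def read_copam(path: str | Path) -> CoPaM:
    with Path(path).open() as fh:
        header = fh.readline().strip()
        fields = dict(item.split("=", 1) for item in header.lstrip("# ").split("\t"))
        rows = [[float(v) for v in line.split("\t")] for line in fh if line.strip()]
    U = np.array(rows)
    U /= U.sum(axis=0, keepdims=True)  # absorb 12-digit rounding
    prov = fields.get("provenance", "")
    return CoPaM(
        membership=U,
        level=fields.get("level", "final"),
        provenance=prov.split(";") if prov else [],
    )
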