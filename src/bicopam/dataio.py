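"""Reading, preprocessing and writing of expression matrices.

Input matrices are plain tab-delimited text: a header row of sample labels
and a first column of gene identifiers.  The preprocessing chain is fixed in
order: quantile normalization of the raw columns, median summarization of
replicate columns into conditions, then per-gene standardization to zero
mean and unit (population) standard deviation.  Each stage checks and
advances an explicit state tag so stages cannot run out of order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNASSIGNED_MARKER = "-"


class PreprocessingState(str, Enum):
    RAW = "raw"
    NORMALIZED = "normalized"
    SUMMARIZED = "summarized"
    STANDARDIZED = "standardized"


class StateError(RuntimeError):
    """Raised when a preprocessing stage is applied out of order."""


@dataclass
class ExpressionDataset:
    """One genes x conditions expression matrix.

    Attributes
    ----------
    dataset_id : str
        Short label for the dataset (``D01`` .. style).
    gene_ids : list of str
        Row identifiers, identical across all datasets in a run once
        aligned to the gene universe.
    values : ndarray, shape (n_genes, n_conditions)
        Expression values.
    condition_labels : list of str
        Column labels (samples while raw/normalized, conditions afterwards).
    state : PreprocessingState
        Where the dataset sits in the raw -> normalized -> summarized ->
        standardized chain.
    flagged_genes : list of str
        Genes whose profile was constant in this dataset and was zero-filled
        during standardization.
    time_series : bool
        Whether the conditions are ordered time-points (enables lead/lag
        analysis downstream).
    """

    dataset_id: str
    gene_ids: list[str]
    values: np.ndarray
    condition_labels: list[str]
    state: PreprocessingState = PreprocessingState.RAW
    flagged_genes: list[str] = field(default_factory=list)
    time_series: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[0] != len(self.gene_ids):
            raise ValueError(
                f"{len(self.gene_ids)} gene ids but {self.values.shape[0]} rows"
            )
        if self.values.shape[1] != len(self.condition_labels):
            raise ValueError(
                f"{len(self.condition_labels)} column labels but "
                f"{self.values.shape[1]} columns"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.condition_labels
        )

    def _require_state(self, expected: PreprocessingState, op: str) -> None:
        if self.state is not expected:
            raise StateError(
                f"{op} requires state '{expected.value}' but dataset "
                f"'{self.dataset_id}' is in state '{self.state.value}'"
            )


@dataclass
class ReplicateMap:
    """Maps each raw sample column to a condition label.

    Condition order follows first appearance in the mapping.
    """

    sample_to_condition: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sample_to_condition:
            raise ValueError("replicate map is empty")

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for cond in self.sample_to_condition.values():
            seen.setdefault(cond)
        return list(seen)

    def columns_for(self, condition: str) -> list[str]:
        return [s for s, c in self.sample_to_condition.items() if c == condition]

    def validate_against(self, sample_labels: Sequence[str]) -> None:
        missing = [s for s in sample_labels if s not in self.sample_to_condition]
        if missing:
            raise ValueError(f"samples missing from replicate map: {missing}")


# ---------------------------------------------------------------------------
# I/O


def read_expression_matrix(path: str | Path, dataset_id: str | None = None) -> ExpressionDataset:
    """Read a tab-delimited expression matrix into a raw dataset.

    The first row holds sample labels, the first column gene identifiers,
    and the body is numeric.  Gene order is preserved as in the file.
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    sample_labels = header[1:]
    n_cols = len(sample_labels)
    if n_cols == 0:
        raise ValueError(f"{path}: header row has no sample labels")
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != n_cols + 1:
            raise ValueError(
                f"{path}: line {lineno} has {len(parts) - 1} values, "
                f"expected {n_cols}"
            )
        gene_ids.append(parts[0])
        row = []
        for j, cell in enumerate(parts[1:], start=1):
            try:
                row.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at line {lineno}, "
                    f"column {j + 1}"
                ) from None
        rows.append(row)
    dupes = pd.Index(gene_ids)[pd.Index(gene_ids).duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicated gene IDs: {dupes}")
    return ExpressionDataset(
        dataset_id=dataset_id or path.stem,
        gene_ids=gene_ids,
        values=np.array(rows, dtype=float),
        condition_labels=sample_labels,
        state=PreprocessingState.RAW,
    )


def write_expression_matrix(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write the matrix as TSV (round-trips with :func:`read_expression_matrix`)."""
    dataset.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene universe list, one identifier per line."""
    with Path(path).open() as fh:
        return [line.strip() for line in fh if line.strip()]


def read_replicate_map(path: str | Path) -> ReplicateMap:
    """Read a two-column TSV (sample_label, condition_label)."""
    mapping: dict[str, str] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            sample, cond = parts
            if sample in mapping:
                raise ValueError(f"{path}: duplicate sample label {sample!r}")
            mapping[sample] = cond
    return ReplicateMap(mapping)


# ---------------------------------------------------------------------------
# Gene-universe alignment


def align_gene_universe(
    datasets: Sequence[ExpressionDataset],
    universe: Sequence[str],
    mode: str = "strict",
) -> tuple[list[ExpressionDataset], list[str]]:
    """Reorder every dataset's rows to a shared gene universe.

    Genes outside the universe are dropped.  In ``strict`` mode a universe
    gene missing from any dataset is an error; in ``intersection`` mode the
    universe is shrunk to the genes present in all datasets (keeping the
    given universe order).

    Returns the aligned datasets and the effective universe.
    """
    if mode not in ("strict", "intersection"):
        raise ValueError(f"unknown mode {mode!r}")
    universe = list(universe)
    if mode == "strict":
        for ds in datasets:
            present = set(ds.gene_ids)
            missing = [g for g in universe if g not in present]
            if missing:
                raise ValueError(
                    f"gene(s) {missing} absent from dataset '{ds.dataset_id}'"
                )
        effective = universe
    else:
        common = set(universe)
        for ds in datasets:
            common &= set(ds.gene_ids)
        effective = [g for g in universe if g in common]
        if not effective:
            raise ValueError("intersection of gene universes is empty")
    aligned = []
    for ds in datasets:
        index = {g: i for i, g in enumerate(ds.gene_ids)}
        order = [index[g] for g in effective]
        aligned.append(
            replace(ds, gene_ids=list(effective), values=ds.values[order, :])
        )
    return aligned, effective


# ---------------------------------------------------------------------------
# Preprocessing stages


def quantile_normalize(dataset: ExpressionDataset) -> ExpressionDataset:
    """Quantile-normalize columns to a common reference distribution.

    The reference is the row-wise mean of the rank-ordered columns; within a
    column, tied values receive the mean of the reference values over the
    ranks they span (Bolstad-style tie handling).  Within-column ranks are
    preserved, so afterwards every column holds the identical value multiset
    up to tie-averaging.
    """
    dataset._require_state(PreprocessingState.RAW, "quantile_normalize")
    X = dataset.values
    if X.shape[1] < 2:
        logger.warning(
            "quantile_normalize: dataset '%s' has a single column; no-op",
            dataset.dataset_id,
        )
        return replace(dataset, state=PreprocessingState.NORMALIZED)
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X, dtype=float)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # ties span several ranks; give them the mean of the spanned values
        assigned = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
        out[:, j] = assigned
    return replace(dataset, values=out, state=PreprocessingState.NORMALIZED)


def summarize_replicates(
    dataset: ExpressionDataset, rep_map: ReplicateMap | None
) -> ExpressionDataset:
    """Collapse replicate columns into one median column per condition.

    ``rep_map=None`` treats every column as its own condition (singleton
    groups), which leaves the matrix unchanged apart from the state tag.
    """
    dataset._require_state(PreprocessingState.NORMALIZED, "summarize_replicates")
    if rep_map is None:
        return replace(dataset, state=PreprocessingState.SUMMARIZED)
    rep_map.validate_against(dataset.condition_labels)
    col_idx = {s: i for i, s in enumerate(dataset.condition_labels)}
    conditions = rep_map.conditions
    out = np.empty((dataset.n_genes, len(conditions)))
    for k, cond in enumerate(conditions):
        cols = [col_idx[s] for s in rep_map.columns_for(cond) if s in col_idx]
        if not cols:
            raise ValueError(f"condition {cond!r} has no columns in the matrix")
        out[:, k] = np.median(dataset.values[:, cols], axis=1)
    return replace(
        dataset,
        values=out,
        condition_labels=conditions,
        state=PreprocessingState.SUMMARIZED,
    )


def standardize_genes(dataset: ExpressionDataset) -> ExpressionDataset:
    """Scale every gene row to zero mean and unit population SD.

    Constant rows cannot be scaled; they are set to all-zero and recorded in
    ``flagged_genes`` so the gene universe stays aligned across datasets.
    """
    dataset._require_state(PreprocessingState.SUMMARIZED, "standardize_genes")
    X = dataset.values
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)  # population (divide-by-N) convention
    constant = sd[:, 0] < 1e-12
    sd[constant, :] = 1.0
    out = (X - mean) / sd
    out[constant, :] = 0.0
    flagged = [g for g, c in zip(dataset.gene_ids, constant) if c]
    if flagged:
        logger.info(
            "standardize_genes: dataset '%s': %d constant gene(s) zero-filled",
            dataset.dataset_id,
            len(flagged),
        )
    return replace(
        dataset,
        values=out,
        flagged_genes=flagged,
        state=PreprocessingState.STANDARDIZED,
    )


def preprocess(
    dataset: ExpressionDataset, rep_map: ReplicateMap | None = None
) -> ExpressionDataset:
    """Run the full fixed-order chain: quantile -> median-summarize -> z-score."""
    out = quantile_normalize(dataset)
    out = summarize_replicates(out, rep_map)
    out = standardize_genes(out)
    logger.info(
        "preprocess: dataset '%s' -> %d genes x %d conditions",
        out.dataset_id,
        out.n_genes,
        out.n_conditions,
    )
    return out


# ---------------------------------------------------------------------------
# Membership tables


def write_membership_table(
    partitions: Iterable,  # Iterable[BinarizedPartition]
    gene_ids: Sequence[str],
    path: str | Path,
    cluster_labels: Sequence[str] | None = None,
) -> None:
    """Write per-delta cluster assignments: one row per gene, one column per delta.

    Cells hold the assigned cluster label, or ``-`` for unassigned genes.
    """
    partitions = list(partitions)
    columns = {}
    for part in partitions:
        K = part.membership.shape[0]
        labels = (
            list(cluster_labels)
            if cluster_labels is not None
            else [f"C{i + 1}" for i in range(K)]
        )
        assigned = part.membership.argmax(axis=0)
        any_hit = part.membership.sum(axis=0) > 0
        col = [labels[a] if hit else UNASSIGNED_MARKER for a, hit in zip(assigned, any_hit)]
        columns[f"delta={part.delta:g}"] = col
    pd.DataFrame(columns, index=list(gene_ids)).to_csv(
        path, sep="\t", index_label="gene"
    )


def read_membership_table(path: str | Path) -> pd.DataFrame:
    """Read a membership table back (gene index, one column per delta)."""
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str)
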