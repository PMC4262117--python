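"""Cluster average profiles, anti-phase quantification and lead/lag.

Two consistently co-expressed modules are "anti-phase" when their mean
expression profiles are strongly negatively correlated in (nearly) every
dataset with no lead or lag.  Profiles are unweighted means of the member
genes' z-scored rows; anti-correlation is Pearson's r per dataset, counted
against a configurable set of thresholds; the lag is the offset maximizing
the absolute cross-correlation of the two profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from bicopam.binarization import BinarizedPartition
from bicopam.dataio import ExpressionDataset, PreprocessingState

DEFAULT_THRESHOLDS = (-0.75, -0.7, -0.6)


@dataclass
class ClusterProfile:
    """Mean z-scored profile of one cluster in one dataset."""

    cluster_id: int
    delta: float
    dataset_id: str
    profile: np.ndarray


@dataclass
class AntiPhaseSummary:
    """Anti-correlation of a cluster pair across datasets."""

    pair: tuple[int, int]
    per_dataset_r: dict[str, float]  # NaN where undefined (N < 3)
    counts_below: dict[float, int]
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    outlier_datasets: list[str] = field(default_factory=list)
    per_dataset_lag: dict[str, int | None] = field(default_factory=dict)

    @property
    def n_datasets(self) -> int:
        return sum(1 for r in self.per_dataset_r.values() if not np.isnan(r))

    @property
    def modal_lag(self) -> int | None:
        lags = [l for l in self.per_dataset_lag.values() if l is not None]
        if not lags:
            return None
        vals, counts = np.unique(lags, return_counts=True)
        best = counts.max()
        candidates = vals[counts == best]
        return int(candidates[np.argmin(np.abs(candidates))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dataset": list(self.per_dataset_r),
                "pearson_r": list(self.per_dataset_r.values()),
                "lag": [self.per_dataset_lag.get(d) for d in self.per_dataset_r],
            }
        )


def cluster_profile(
    partition: BinarizedPartition, dataset: ExpressionDataset, k: int
) -> np.ndarray | None:
    """Unweighted mean of the member genes' rows; None for an empty cluster."""
    if dataset.state is not PreprocessingState.STANDARDIZED:
        raise ValueError("profiles require standardized datasets")
    members = partition.membership[k].astype(bool)
    if not members.any():
        return None
    return dataset.values[members, :].mean(axis=0)


def cluster_profiles(
    partition: BinarizedPartition, datasets: list[ExpressionDataset]
) -> list[ClusterProfile]:
    """Profiles of every non-empty cluster in every dataset."""
    out = []
    for ds in datasets:
        for k in range(partition.n_clusters):
            prof = cluster_profile(partition, ds, k)
            if prof is not None:
                out.append(
                    ClusterProfile(
                        cluster_id=k,
                        delta=partition.delta,
                        dataset_id=ds.dataset_id,
                        profile=prof,
                    )
                )
    return out


def lead_lag(
    profile_a: np.ndarray, profile_b: np.ndarray, max_lag: int | None = None
) -> int:
    """Offset of b relative to a maximizing |Pearson r| over the overlap.

    Positive lag means the second profile lags the first (b at time n + lag
    matches a at time n); 0 means synchronous.  Ties prefer the lag closest
    to zero (negative first on exact magnitude ties).  ``max_lag`` defaults
    to floor(N/4) and must stay below N/2 so the overlap keeps >= 2 points.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be equal-length vectors")
    n = a.size
    if max_lag is None:
        max_lag = n // 4
    if max_lag >= n / 2:
        raise ValueError("max_lag must be < N/2")
    best_lag, best_r = 0, -np.inf
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), l)):
        if lag >= 0:
            x, y = a[: n - lag], b[lag:]
        else:
            x, y = a[-lag:], b[: n + lag]
        if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
            continue
        r = abs(np.corrcoef(x, y)[0, 1])
        if r > best_r + 1e-12:
            best_lag, best_r = lag, r
    return best_lag


def antiphase_summary(
    profiles_a: dict[str, np.ndarray],
    profiles_b: dict[str, np.ndarray],
    pair: tuple[int, int] = (0, 1),
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    time_series: dict[str, bool] | None = None,
    max_lag: dict[str, int] | None = None,
) -> AntiPhaseSummary:
    """Per-dataset Pearson r between two clusters' mean profiles.

    ``profiles_a``/``profiles_b`` map dataset id -> profile vector for each
    cluster of the pair (the two clusters may come from partitions at
    different delta values).  Datasets with fewer than three conditions get
    an undefined (NaN) r and are excluded from the threshold counts.
    Datasets whose r exceeds the weakest (largest) threshold are flagged as
    outliers.  For time-series datasets the best lead/lag offset is
    reported as well.
    """
    common = [d for d in profiles_a if d in profiles_b]
    per_r: dict[str, float] = {}
    per_lag: dict[str, int | None] = {}
    for ds_id in common:
        a, b = profiles_a[ds_id], profiles_b[ds_id]
        if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
            per_r[ds_id] = np.nan
            per_lag[ds_id] = None
            continue
        per_r[ds_id] = float(pearsonr(a, b).statistic)
        is_ts = True if time_series is None else time_series.get(ds_id, False)
        if is_ts and a.size >= 4:
            ml = None if max_lag is None else max_lag.get(ds_id)
            per_lag[ds_id] = lead_lag(a, b, ml)
        else:
            per_lag[ds_id] = None
    counts = {
        t: int(sum(1 for r in per_r.values() if not np.isnan(r) and r < t))
        for t in thresholds
    }
    weakest = max(thresholds)
    outliers = [
        d for d, r in per_r.items() if not np.isnan(r) and r >= weakest
    ]
    return AntiPhaseSummary(
        pair=pair,
        per_dataset_r=per_r,
        counts_below=counts,
        thresholds=tuple(thresholds),
        outlier_datasets=outliers,
        per_dataset_lag=per_lag,
    )


def plot_profile_grid(
    profiles_a: dict[str, np.ndarray],
    profiles_b: dict[str, np.ndarray],
    path,
    labels: tuple[str, str] = ("cluster 1", "cluster 2"),
) -> None:
    """Optional figure: one row per dataset, both cluster mean profiles.

    Requires matplotlib (an optional dependency); all quantitative outputs
    are TSV, so nothing downstream depends on this figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ids = [d for d in profiles_a if d in profiles_b]
    fig, axes = plt.subplots(
        len(ids), 1, figsize=(6, 1.6 * len(ids)), squeeze=False, sharex=False
    )
    for ax, ds_id in zip(axes[:, 0], ids):
        ax.plot(profiles_a[ds_id], label=labels[0])
        ax.plot(profiles_b[ds_id], label=labels[1])
        ax.set_ylabel(ds_id, rotation=0, labelpad=20, fontsize=8)
        ax.tick_params(labelsize=6)
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
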