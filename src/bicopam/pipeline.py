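"""End-to-end orchestration: preprocess, cluster, fuse, sweep, evaluate.

The run order is fixed: every dataset is preprocessed, clustered by each
configured method, the per-dataset partitions are fused into pushed
intermediate CoPaMs, those are fused (in config order — the greedy
relabeling is order-dependent, so the order is logged and recorded in the
manifest) into the final CoPaM, which is swept over the delta grid,
scored with the MSE metric, tightness-ranked, and finally the two tightest
clusters are checked for anti-phase behaviour across all datasets.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from bicopam import dataio
from bicopam.base_clustering import (
    HardPartition,
    hc_ward,
    kmeans_ka,
    som_bubble,
    square_grid,
)
from bicopam.binarization import (
    BinarizedPartition,
    DEFAULT_DELTA_GRID,
    delta_sweep,
    sweep_counts,
)
from bicopam.consensus import CoPaM, build_final_copam, build_intermediate_copam, push_memberships
from bicopam.dataio import ExpressionDataset, ReplicateMap
from bicopam.evaluation import (
    TightnessRanking,
    mse_report,
    mse_report_frame,
    rank_tightness,
    selection_surface,
)
from bicopam.profile_analysis import (
    AntiPhaseSummary,
    DEFAULT_THRESHOLDS,
    antiphase_summary,
    cluster_profile,
)
from bicopam.synthetic_data import jaccard

logger = logging.getLogger(__name__)

ALL_METHODS = ("kmeans_ka", "som_bubble", "hc_ward")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    n_clusters: int = 16
    methods: tuple[str, ...] = ALL_METHODS
    delta_grid: tuple[float, ...] = DEFAULT_DELTA_GRID
    min_genes: int = 7
    antiphase_thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    antiphase_delta: float = 0.3
    som_seed: int = 0
    som_epochs: int = 500
    relabel_method: str = "greedy"
    dataset_paths: tuple[str, ...] = ()
    replicate_map_paths: tuple[str, ...] = ()
    gene_universe_path: str | None = None
    universe_mode: str = "strict"
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if not self.methods:
            raise ValueError("need at least one clustering method")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        grid = list(self.delta_grid)
        if sorted(grid) != grid or grid[0] < 0 or grid[-1] > 1:
            raise ValueError("delta_grid must be ascending within [0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("methods", "delta_grid", "antiphase_thresholds",
                    "dataset_paths", "replicate_map_paths"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PipelineResult:
    """Everything a run produces, in memory."""

    config: RunConfig
    gene_ids: list[str]
    datasets: list[ExpressionDataset]
    final_copam: CoPaM
    sweep: list[BinarizedPartition]
    counts: pd.DataFrame
    mse: list
    ranking: TightnessRanking
    surface: pd.DataFrame
    antiphase: AntiPhaseSummary | None
    manifest: dict


def cluster_dataset(
    dataset: ExpressionDataset, config: RunConfig
) -> list[HardPartition]:
    """Run every configured clusterer on one standardized dataset."""
    parts = []
    for method in config.methods:
        if method == "kmeans_ka":
            parts.append(kmeans_ka(dataset, config.n_clusters))
        elif method == "som_bubble":
            parts.append(
                som_bubble(
                    dataset,
                    grid=square_grid(config.n_clusters),
                    seed=config.som_seed,
                    epochs=config.som_epochs,
                )
            )
        elif method == "hc_ward":
            parts.append(hc_ward(dataset, config.n_clusters))
    return parts


def consensus_from_datasets(
    datasets: list[ExpressionDataset], config: RunConfig
) -> CoPaM:
    """Cluster each dataset with each method and fuse into the final CoPaM."""
    intermediates = []
    for ds in datasets:
        parts = cluster_dataset(ds, config)
        copam = build_intermediate_copam(parts, method=config.relabel_method)
        intermediates.append(push_memberships(copam))
        logger.info(
            "consensus: dataset '%s': %d partitions fused and pushed",
            ds.dataset_id,
            len(parts),
        )
    return build_final_copam(intermediates, method=config.relabel_method)


def partition_at(sweep: list[BinarizedPartition], delta: float) -> BinarizedPartition:
    """The sweep's partition at a given delta (exact up to 1e-9)."""
    for p in sweep:
        if abs(p.delta - delta) < 1e-9:
            return p
    raise KeyError(f"no partition at delta={delta} in the sweep")




def top_pair_antiphase(
    sweep: list[BinarizedPartition],
    ranking: TightnessRanking,
    datasets: list[ExpressionDataset],
    config: RunConfig,
    deltas: tuple[float, float] | None = None,
) -> AntiPhaseSummary | None:
    """Anti-phase summary for the two tightest clusters.

    Each cluster's membership may be taken at its own delta (``deltas``);
    by default both use ``config.antiphase_delta``.  Returns None when
    either cluster is empty in the selected partition.
    """
    if len(ranking.order) < 2:
        return None
    ka, kb = ranking.top(2)
    da, db = deltas if deltas is not None else (
        config.antiphase_delta, config.antiphase_delta
    )
    part_a = partition_at(sweep, da)
    part_b = partition_at(sweep, db)
    profiles_a, profiles_b = {}, {}
    for ds in datasets:
        pa = cluster_profile(part_a, ds, ka)
        pb = cluster_profile(part_b, ds, kb)
        if pa is None or pb is None:
            return None
        profiles_a[ds.dataset_id] = pa
        profiles_b[ds.dataset_id] = pb
    return antiphase_summary(
        profiles_a,
        profiles_b,
        pair=(ka, kb),
        thresholds=config.antiphase_thresholds,
        time_series={ds.dataset_id: ds.time_series for ds in datasets},
    )


def run_pipeline(
    config: RunConfig,
    datasets: list[ExpressionDataset] | None = None,
    replicate_maps: dict[str, ReplicateMap] | None = None,
    preprocessed: bool = False,
) -> PipelineResult:
    """Execute the whole pipeline; optionally write a run directory.

    ``datasets`` may be passed in memory (raw, unless ``preprocessed``);
    otherwise they are read from ``config.dataset_paths``.  When
    ``config.output_dir`` is set, all quantitative outputs are written
    there as TSV along with a JSON manifest.
    """
    stage = "load"
    try:
        if datasets is None:
            if not config.dataset_paths:
                raise ValueError("no datasets given (paths or in-memory)")
            datasets = [dataio.read_expression_matrix(p) for p in config.dataset_paths]
            if config.replicate_map_paths:
                replicate_maps = {
                    ds.dataset_id: dataio.read_replicate_map(p)
                    for ds, p in zip(datasets, config.replicate_map_paths)
                }
        if config.gene_universe_path:
            universe = dataio.read_gene_list(config.gene_universe_path)
            datasets, _ = dataio.align_gene_universe(
                datasets, universe, mode=config.universe_mode
            )
        gene_ids = list(datasets[0].gene_ids)
        for ds in datasets[1:]:
            if ds.gene_ids != gene_ids:
                raise ValueError(
                    f"dataset '{ds.dataset_id}' gene order differs; align first"
                )

        stage = "preprocess"
        if not preprocessed:
            datasets = [
                dataio.preprocess(
                    ds, (replicate_maps or {}).get(ds.dataset_id)
                )
                for ds in datasets
            ]

        stage = "consensus"
        final = consensus_from_datasets(datasets, config)

        stage = "binarize"
        sweep = delta_sweep(final, config.delta_grid)
        counts = sweep_counts(sweep)

        stage = "evaluate"
        report = mse_report(sweep, datasets)
        ranking = rank_tightness(sweep, min_genes=config.min_genes)
        surface = selection_surface(report)

        stage = "antiphase"
        anti = top_pair_antiphase(sweep, ranking, datasets, config)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage '{stage}': {exc}"
        ) from exc

    manifest = {
        "config": _jsonable(asdict(config)),
        "dataset_order": [ds.dataset_id for ds in datasets],
        "n_genes": len(gene_ids),
        "config_hash": _config_hash(config),
        "package_version": _version(),
    }
    result = PipelineResult(
        config=config,
        gene_ids=gene_ids,
        datasets=datasets,
        final_copam=final,
        sweep=sweep,
        counts=counts,
        mse=report,
        ranking=ranking,
        surface=surface,
        antiphase=anti,
        manifest=manifest,
    )
    if config.output_dir:
        write_run_directory(result, Path(config.output_dir))
    return result


def write_run_directory(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    dataio.write_membership_table(
        result.sweep, result.gene_ids, out / "memberships.tsv"
    )
    result.counts.to_csv(out / "cluster_counts.tsv", sep="\t")
    mse_report_frame(result.mse).to_csv(out / "mse_report.tsv", sep="\t", index=False)
    rank_rows = [
        {
            "rank": i + 1,
            "cluster": f"C{k + 1}",
            "max_delta": result.ranking.max_delta[k],
            "n_genes_at_max_delta": result.ranking.count_at_max_delta[k],
        }
        for i, k in enumerate(result.ranking.order)
    ]
    pd.DataFrame(rank_rows).to_csv(out / "tightness_ranking.tsv", sep="\t", index=False)
    result.surface.to_csv(out / "selection_surface.tsv", sep="\t", index=False)
    if result.antiphase is not None:
        result.antiphase.to_frame().to_csv(
            out / "antiphase.tsv", sep="\t", index=False
        )
        with (out / "antiphase_summary.json").open("w") as fh:
            json.dump(
                {
                    "pair": [f"C{k + 1}" for k in result.antiphase.pair],
                    "counts_below": {
                        str(t): c
                        for t, c in result.antiphase.counts_below.items()
                    },
                    "outliers": result.antiphase.outlier_datasets,
                    "modal_lag": result.antiphase.modal_lag,
                },
                fh,
                indent=2,
            )
    with (out / "manifest.json").open("w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)


@dataclass
class KSweepReport:
    """Tightness rankings and top-cluster stability over several K values."""

    k_values: list[int]
    rankings: dict[int, TightnessRanking]
    top_gene_sets: dict[int, set]
    pairwise_jaccard: pd.DataFrame
    results: dict[int, PipelineResult] = field(default=None, repr=False)


def k_sweep(
    config: RunConfig,
    k_values: list[int],
    datasets: list[ExpressionDataset],
    preprocessed: bool = False,
    gene_set_delta: float | None = None,
) -> KSweepReport:
    """Re-run the pipeline at several K and compare the top cluster.

    The top-ranked cluster's gene set is taken at ``gene_set_delta``
    (default: the config's anti-phase delta) and compared across K values
    by pairwise Jaccard index.
    """
    if len(k_values) < 2:
        raise ValueError("k_sweep needs at least two K values")
    delta = gene_set_delta if gene_set_delta is not None else config.antiphase_delta
    if not preprocessed:
        datasets = [dataio.preprocess(ds) for ds in datasets]
        preprocessed = True
    rankings, top_sets, results = {}, {}, {}
    for k in k_values:
        cfg = RunConfig(**{**asdict(config), "n_clusters": k, "output_dir": None})
        res = run_pipeline(cfg, datasets=datasets, preprocessed=True)
        top = res.ranking.top(1)[0]
        part = partition_at(res.sweep, delta)
        top_sets[k] = part.gene_sets(res.gene_ids)[top]
        rankings[k] = res.ranking
        results[k] = res
    mat = pd.DataFrame(
        [
            [jaccard(top_sets[a], top_sets[b]) for b in k_values]
            for a in k_values
        ],
        index=k_values,
        columns=k_values,
    )
    return KSweepReport(
        k_values=list(k_values),
        rankings=rankings,
        top_gene_sets=top_sets,
        pairwise_jaccard=mat,
        results=results,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(_jsonable(asdict(config)), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _version() -> str:
    from bicopam import __version__

    return __version__
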