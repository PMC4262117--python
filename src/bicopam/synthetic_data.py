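"""Synthetic multi-dataset expression collections with planted structure.

The generator emulates a collection of microarray-style series over one
gene universe: each dataset has its own number of conditions, two planted
gene modules whose latent templates are negated copies of each other (hence
strongly anti-correlated with zero lag in every dataset), optional
confounder modules that are coherent in only a random half of the datasets,
and a bulk of background genes redrawn independently per dataset so they
carry no cross-dataset consistency.  Matrices are emitted raw on a positive
scale so the full preprocessing chain (quantile normalization, replicate
summarization, z-scoring) has real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from bicopam.binarization import BinarizedPartition
from bicopam.dataio import ExpressionDataset, PreprocessingState, ReplicateMap


@dataclass
class GeneratorConfig:
    """Study-condition knobs for the synthetic collection.

    Defaults mirror the structure the analysis is designed for: ten
    datasets over 1000 genes with 4-49 conditions each, two anti-phase
    modules of 160 and 50 genes (template anticorrelation -0.95 before
    measurement noise), two half-consistent confounder modules of 30 genes,
    and per-gene measurement noise of SD 0.4 on the unit-SD template scale.
    """

    n_genes: int = 1000
    n_datasets: int = 10
    conditions_range: tuple[int, int] = (4, 49)
    module_sizes: tuple[int, int] = (160, 50)
    module_anticorrelation: float = -0.95
    gene_noise_sd: float = 0.4
    n_confounder_modules: int = 2
    confounder_size: int = 30
    replicates_per_condition: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        planted = sum(self.module_sizes) + self.n_confounder_modules * self.confounder_size
        if planted > self.n_genes:
            raise ValueError(
                f"planted genes ({planted}) exceed the universe ({self.n_genes})"
            )
        if self.gene_noise_sd <= 0:
            raise ValueError("gene_noise_sd must be > 0")
        if not -1.0 <= self.module_anticorrelation < 0.0:
            raise ValueError("module_anticorrelation must be in [-1, 0)")
        if self.replicates_per_condition < 1:
            raise ValueError("replicates_per_condition must be >= 1")
        lo, hi = self.conditions_range
        if lo < 4 or hi < lo:
            raise ValueError("conditions_range must satisfy 4 <= lo <= hi")


@dataclass
class GroundTruth:
    """Planted gene-to-module assignment and per-dataset latent templates."""

    modules: dict[str, list[str]]  # module_a, module_b, confounder_i
    background: list[str]
    templates: dict[str, dict[str, np.ndarray]]  # dataset -> module -> template
    confounder_active: dict[str, list[str]] = field(default_factory=dict)
    replicate_maps: dict[str, ReplicateMap] = field(default_factory=dict)

    def module_of(self, gene: str) -> str:
        for name, genes in self.modules.items():
            if gene in genes:
                return name
        return "background"


def _smooth_template(rng: np.random.Generator, n: int) -> np.ndarray:
    """Band-limited random profile: a few Fourier harmonics, z-scored."""
    t = np.zeros(n)
    x = np.arange(n) / n
    for h in range(1, 4):
        amp = rng.normal(0, 1.0 / h)
        phase = rng.uniform(0, 2 * np.pi)
        t += amp * np.sin(2 * np.pi * h * x + phase)
    sd = t.std()
    if sd < 1e-6:  # pathologically flat draw; fall back to one clean cycle
        t = np.sin(2 * np.pi * x)
        sd = t.std()
    return (t - t.mean()) / sd


# mild exponent keeps the monotone distortion of downstream quantile
# normalization + z-scoring small so the planted anticorrelation survives
_RAW_SCALE = 0.25
_RAW_OFFSET = 7.0


def generate_collection(
    config: GeneratorConfig,
) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Generate the raw datasets plus the planted ground truth.

    Module B's latent template is ``-(template A)`` plus a small template
    perturbation sized so the two templates correlate at roughly
    ``module_anticorrelation``; gene rows add i.i.d. N(0, gene_noise_sd^2)
    noise on top of their module template.  Confounder module i is coherent
    in a seeded random half of the datasets and background-like elsewhere.
    The same seed reproduces the collection bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    g1, g2 = config.module_sizes
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    modules: dict[str, list[str]] = {
        "module_a": gene_ids[:g1],
        "module_b": gene_ids[g1 : g1 + g2],
    }
    pos = g1 + g2
    for c in range(config.n_confounder_modules):
        modules[f"confounder_{c + 1}"] = gene_ids[pos : pos + config.confounder_size]
        pos += config.confounder_size
    background = gene_ids[pos:]

    dataset_ids = [f"D{i + 1:02d}" for i in range(config.n_datasets)]
    confounder_active = {
        name: sorted(
            rng.choice(
                dataset_ids, size=config.n_datasets // 2, replace=False
            ).tolist()
        )
        for name in modules
        if name.startswith("confounder")
    }
    # template perturbation scale s gives corr(t, -(t+s*e)) ~ -1/sqrt(1+s^2)
    r = abs(config.module_anticorrelation)
    s = np.sqrt(max(1.0 / r**2 - 1.0, 0.0))

    datasets = []
    templates: dict[str, dict[str, np.ndarray]] = {}
    replicate_maps: dict[str, ReplicateMap] = {}
    lo, hi = config.conditions_range
    for ds_id in dataset_ids:
        n_cond = int(rng.integers(lo, hi + 1))
        t_a = _smooth_template(rng, n_cond)
        t_b = -(t_a + s * _smooth_template(rng, n_cond))
        t_b = (t_b - t_b.mean()) / t_b.std()
        ds_templates = {"module_a": t_a, "module_b": t_b}
        signal = np.empty((config.n_genes, n_cond))
        signal[: g1, :] = t_a
        signal[g1 : g1 + g2, :] = t_b
        p = g1 + g2
        for c in range(config.n_confounder_modules):
            name = f"confounder_{c + 1}"
            if ds_id in confounder_active[name]:
                t_c = _smooth_template(rng, n_cond)
                ds_templates[name] = t_c
                signal[p : p + config.confounder_size, :] = t_c
            else:
                ds_templates[name] = np.zeros(n_cond)
                signal[p : p + config.confounder_size, :] = 0.0
            p += config.confounder_size
        signal[p:, :] = 0.0  # background: pure noise below
        noise_sd = np.full((config.n_genes, 1), config.gene_noise_sd)
        noise_sd[p:, :] = 1.0  # background variability on the template scale
        signal = signal + rng.normal(0, 1.0, signal.shape) * noise_sd
        # expand conditions into replicate columns with measurement noise
        reps = config.replicates_per_condition
        cond_labels = [f"c{j + 1:02d}" for j in range(n_cond)]
        if reps > 1:
            sample_labels = [
                f"{c}_r{r_ + 1}" for c in cond_labels for r_ in range(reps)
            ]
            expanded = np.repeat(signal, reps, axis=1)
            expanded = expanded + rng.normal(
                0, 0.5 * config.gene_noise_sd, expanded.shape
            )
            rep_map = ReplicateMap(
                {
                    f"{c}_r{r_ + 1}": c
                    for c in cond_labels
                    for r_ in range(reps)
                }
            )
        else:
            sample_labels = cond_labels
            expanded = signal
            rep_map = ReplicateMap({c: c for c in cond_labels})
        raw = np.exp(_RAW_SCALE * expanded + _RAW_OFFSET)
        datasets.append(
            ExpressionDataset(
                dataset_id=ds_id,
                gene_ids=list(gene_ids),
                values=raw,
                condition_labels=sample_labels,
                state=PreprocessingState.RAW,
                time_series=True,
            )
        )
        templates[ds_id] = ds_templates
        replicate_maps[ds_id] = rep_map

    truth = GroundTruth(
        modules=modules,
        background=background,
        templates=templates,
        confounder_active=confounder_active,
        replicate_maps=replicate_maps,
    )
    return datasets, truth


def jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def score_recovery(
    truth: GroundTruth,
    partition: BinarizedPartition,
    gene_ids: list[str],
    modules: tuple[str, ...] = ("module_a", "module_b"),
) -> dict[str, float]:
    """Best-cluster Jaccard overlap with each planted module.

    For each module, the maximum over clusters of
    Jaccard(module genes, cluster genes).  An empty partition scores 0.
    """
    cluster_sets = partition.gene_sets(gene_ids)
    out = {}
    for name in modules:
        target = set(truth.modules[name])
        out[name] = max(
            (jaccard(target, genes) for genes in cluster_sets.values()),
            default=0.0,
        )
    return out


def write_collection(
    datasets: list[ExpressionDataset],
    truth: GroundTruth,
    out_dir: str | Path,
) -> None:
    """Write TSV matrices, replicate maps, the gene list and the ground truth."""
    from bicopam.dataio import write_expression_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ds in datasets:
        write_expression_matrix(ds, out / f"{ds.dataset_id}.tsv")
        rep_map = truth.replicate_maps.get(ds.dataset_id)
        if rep_map is not None:
            with (out / f"{ds.dataset_id}.replicates.tsv").open("w") as fh:
                for s, c in rep_map.sample_to_condition.items():
                    fh.write(f"{s}\t{c}\n")
    with (out / "genes.txt").open("w") as fh:
        fh.write("\n".join(datasets[0].gene_ids) + "\n")
    rows = [
        {"gene": g, "module": truth.module_of(g)} for g in datasets[0].gene_ids
    ]
    pd.DataFrame(rows).to_csv(out / "ground_truth.tsv", sep="\t", index=False)
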