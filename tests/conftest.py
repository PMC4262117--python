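import numpy as np
import pytest

from bicopam.consensus import CoPaM
from bicopam.dataio import ExpressionDataset, PreprocessingState
from bicopam.pipeline import RunConfig, run_pipeline
from bicopam.synthetic_data import GeneratorConfig, generate_collection


def make_standardized(values, dataset_id="T", gene_ids=None):
    """Wrap a matrix as a standardized dataset after population z-scoring."""
    values = np.asarray(values, dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (values - mean) / sd
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(values.shape[0])]
    return ExpressionDataset(
        dataset_id=dataset_id,
        gene_ids=gene_ids,
        values=z,
        condition_labels=[f"c{j + 1}" for j in range(values.shape[1])],
        state=PreprocessingState.STANDARDIZED,
    )


def random_copam(rng, n_clusters=16, n_genes=200, level="final"):
    """Column-stochastic fuzzy membership matrix with random support."""
    U = rng.dirichlet(np.full(n_clusters, 0.3), size=n_genes).T
    return CoPaM(membership=U, level=level)


def blob_dataset(rng, centers, per_blob, noise=0.05, n_dims=6):
    """Tight Gaussian blobs around given center directions; standardized."""
    rows = []
    for c in centers:
        base = np.asarray(c, dtype=float)
        for _ in range(per_blob):
            rows.append(base + rng.normal(0, noise, n_dims))
    return make_standardized(np.array(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_collection():
    """The generator's default study conditions (seed 0)."""
    cfg = GeneratorConfig(seed=0)
    datasets, truth = generate_collection(cfg)
    return cfg, datasets, truth


@pytest.fixture(scope="session")
def default_run(default_collection):
    """End-to-end pipeline result on the default synthetic collection."""
    _, datasets, truth = default_collection
    result = run_pipeline(
        RunConfig(), datasets=datasets, replicate_maps=truth.replicate_maps
    )
    return result, truth


@pytest.fixture(scope="session")
def small_collection():
    """A light collection for fast integration-style tests."""
    cfg = GeneratorConfig(
        n_genes=120,
        n_datasets=4,
        conditions_range=(8, 12),
        module_sizes=(25, 15),
        n_confounder_modules=1,
        confounder_size=10,
        seed=7,
    )
    datasets, truth = generate_collection(cfg)
    return cfg, datasets, truth
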