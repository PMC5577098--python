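import numpy as np
import pytest

from pathvote import ExpressionDataset, GeneSet, GeneSetCollection, SimulationConfig, simulate


def make_dataset(values, labels, positive_label="pos", gene_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(g)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n)]
    return ExpressionDataset(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        labels=dict(zip(sample_ids, labels)),
        positive_label=positive_label,
    )


@pytest.fixture
def separable_dataset():
    """Two classes split cleanly by gene g0 (means +-5, sd 0.1); g1-g2 are noise."""
    rng = np.random.default_rng(42)
    n_per = 15
    g0 = np.concatenate([rng.normal(5, 0.1, n_per), rng.normal(-5, 0.1, n_per)])
    noise = rng.normal(0, 1, (2, 2 * n_per))
    values = np.vstack([g0, noise])
    labels = ["pos"] * n_per + ["neg"] * n_per
    return make_dataset(values, labels)


@pytest.fixture
def null_dataset():
    """Pure noise, balanced 30/30."""
    rng = np.random.default_rng(7)
    values = rng.normal(0, 1, (20, 60))
    labels = ["pos"] * 30 + ["neg"] * 30
    return make_dataset(values, labels)


@pytest.fixture
def small_cohort():
    """Simulated cohort with 3 informative of 12 pathways; used by optimizer tests."""
    cfg = SimulationConfig(
        n_genes=400,
        n_pathways=12,
        pathway_size_range=(5, 15),
        n_informative_pathways=3,
        n_pos=30,
        n_neg=30,
        seed=11,
    )
    return simulate(cfg)


@pytest.fixture
def toy_collection():
    return GeneSetCollection.from_sets(
        [
            GeneSet("pwA", "pathway A", ("g1", "g2", "g3")),
            GeneSet("pwB", "pathway B", ("g4", "g6")),
            GeneSet("pwC", "pathway C", ("g2", "g5")),
        ]
    )
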