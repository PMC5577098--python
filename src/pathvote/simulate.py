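"""Seeded generator for two-class expression data with pathway-structured signal.

The generator emulates the kind of dataset the method targets: a normalized
(log-like) expression matrix over a few thousand genes, a pathway collection
whose member sets may overlap, and a binary phenotype (by default named
``pCR``/``RD`` after chemotherapy response classes). A configurable subset of
pathways is *informative*: every gene of such a pathway receives a mean shift
of ``effect_size`` noise-SDs in positive-class samples. Genes of one pathway
share an equicorrelated noise factor with correlation ``rho``; background
pathways draw their genes from the pool not used by any informative pathway,
so ground truth is well defined by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import DataError, ExpressionDataset, GeneSet, GeneSetCollection
from ._seeds import rng as _rng

__all__ = ["SimulationConfig", "simulate", "split_dataset", "simulate_split"]


class ConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic two-class cohort.

    Defaults are the desk-scale recovery regime exercised throughout the test
    suite: 2000 genes, 50 pathways of 10-40 genes, 5 informative pathways with
    a 2-SD class shift, within-pathway correlation 0.3, and a balanced 60/60
    cohort.
    """

    n_genes: int = 2000
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (10, 40)
    n_informative_pathways: int = 5
    effect_size: float = 2.0  # mean shift in units of noise_sd
    within_pathway_correlation: float = 0.3
    n_pos: int = 60
    n_neg: int = 60
    noise_sd: float = 1.0
    seed: int = 0
    positive_label: str = "pCR"
    negative_label: str = "RD"
    baseline_mean: float = 6.0  # per-gene baseline, log2-intensity-like
    baseline_sd: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi):
            raise ConfigError(f"invalid pathway_size_range {self.pathway_size_range}")
        if hi > self.n_genes:
            raise ConfigError("largest pathway size exceeds number of genes")
        if not (0 <= self.n_informative_pathways <= self.n_pathways):
            raise ConfigError("n_informative_pathways must be within [0, n_pathways]")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if not (0 <= self.within_pathway_correlation < 1):
            raise ConfigError("within_pathway_correlation must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if min(self.n_pos, self.n_neg) < 2:
            raise ConfigError("need >= 2 samples per class")
        if self.positive_label == self.negative_label:
            raise ConfigError("class labels must differ")


def simulate(config: SimulationConfig) -> tuple[ExpressionDataset, GeneSetCollection, frozenset[str]]:
    """Generate (dataset, pathway collection, ground-truth informative IDs).

    Identical config (including seed) gives bit-identical output.
    """
    cfg = config
    gen = _rng(cfg.seed, "simulate")
    gene_ids = tuple(f"G{i:05d}" for i in range(cfg.n_genes))
    n = cfg.n_pos + cfg.n_neg
    sample_ids = tuple(f"S{i:04d}" for i in range(n))
    labels = {
        s: (cfg.positive_label if i < cfg.n_pos else cfg.negative_label)
        for i, s in enumerate(sample_ids)
    }

    lo, hi = cfg.pathway_size_range
    sizes = gen.integers(lo, hi + 1, size=cfg.n_pathways)
    informative_idx = set(
        int(i) for i in gen.choice(cfg.n_pathways, size=cfg.n_informative_pathways, replace=False)
    )

    members: list[np.ndarray | None] = [None] * cfg.n_pathways
    # informative pathways draw from the full gene pool (and may overlap each other)
    for i in sorted(informative_idx):
        members[i] = np.sort(gen.choice(cfg.n_genes, size=int(sizes[i]), replace=False))
    signal_genes = (
        np.unique(np.concatenate([members[i] for i in sorted(informative_idx)]))
        if informative_idx
        else np.empty(0, dtype=int)
    )
    # background pathways draw only from non-signal genes, so no background
    # pathway carries any class separation
    background_pool = np.setdiff1d(np.arange(cfg.n_genes), signal_genes)
    for i in range(cfg.n_pathways):
        if members[i] is None:
            if len(background_pool) < sizes[i]:
                raise ConfigError(
                    "not enough non-informative genes to populate background pathways; "
                    "increase n_genes or shrink pathways"
                )
            members[i] = np.sort(gen.choice(background_pool, size=int(sizes[i]), replace=False))

    # equicorrelated noise: each gene follows the latent factor of the first
    # pathway (in collection order) that contains it
    eps = gen.standard_normal((cfg.n_genes, n))
    factors = gen.standard_normal((cfg.n_pathways, n))
    baseline = cfg.baseline_mean + cfg.baseline_sd * gen.standard_normal(cfg.n_genes)

    home = np.full(cfg.n_genes, -1, dtype=int)
    for p in range(cfg.n_pathways):
        sel = members[p][home[members[p]] < 0]
        home[sel] = p

    rho = cfg.within_pathway_correlation
    noise = eps.copy()
    factored = home >= 0
    if rho > 0 and factored.any():
        noise[factored] = np.sqrt(rho) * factors[home[factored]] + np.sqrt(1 - rho) * eps[factored]
    values = baseline[:, None] + cfg.noise_sd * noise
    if len(signal_genes):
        values[np.ix_(signal_genes, np.arange(cfg.n_pos))] += cfg.effect_size * cfg.noise_sd

    dataset = ExpressionDataset(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        labels=labels,
        positive_label=cfg.positive_label,
    )
    sets = []
    for p in range(cfg.n_pathways):
        pid = f"PW{p:03d}"
        kind = "informative" if p in informative_idx else "background"
        sets.append(
            GeneSet(
                pathway_id=pid,
                name=f"simulated {kind} pathway {p}",
                genes=tuple(gene_ids[g] for g in members[p]),
            )
        )
    collection = GeneSetCollection.from_sets(sets)
    truth = frozenset(f"PW{p:03d}" for p in sorted(informative_idx))
    return dataset, collection, truth


def split_dataset(
    dataset: ExpressionDataset, train_fraction: float, seed: int
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Stratified random split preserving the class ratio on both sides."""
    if not (0 < train_fraction < 1):
        raise ConfigError("train_fraction must be in (0, 1)")
    if dataset.labels is None:
        raise DataError("split requires a labelled dataset")
    gen = _rng(seed, "split")
    train_idx: list[int] = []
    test_idx: list[int] = []
    label_arr = dataset.label_array()
    for cls in sorted(set(label_arr)):
        cls_idx = np.flatnonzero(label_arr == cls)
        n_train = int(round(train_fraction * len(cls_idx)))
        if n_train < 2 or len(cls_idx) - n_train < 2:
            raise DataError(
                f"class {cls!r} would have fewer than 2 samples on one side of the split"
            )
        perm = gen.permutation(cls_idx)
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    return dataset.subset_samples(sorted(train_idx)), dataset.subset_samples(sorted(test_idx))


def simulate_split(
    config: SimulationConfig, train_fraction: float = 0.5
) -> tuple[ExpressionDataset, ExpressionDataset, GeneSetCollection, frozenset[str]]:
    """Simulate a cohort and split it into disjoint train/test halves."""
    dataset, collection, truth = simulate(config)
    train, test = split_dataset(dataset, train_fraction, seed=config.seed)
    return train, test, collection, truth
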