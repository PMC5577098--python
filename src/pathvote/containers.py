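"""In-memory containers for the pipeline: expression matrices and gene sets.

An :class:`ExpressionDataset` is a genes x samples real matrix with two-class
phenotype labels (e.g. pCR vs. RD chemotherapy response); a
:class:`GeneSetCollection` maps pathway identifiers to ordered gene lists
(the GMT content). Both validate their invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = ["DataError", "ExpressionDataset", "GeneSet", "GeneSetCollection"]


class DataError(ValueError):
    """Raised when an input violates a container invariant."""


def _first_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


@dataclass(frozen=True)
class ExpressionDataset:
    """Genes x samples expression matrix, optionally carrying two-class labels.

    ``values[i, j]`` is the expression of ``gene_ids[i]`` in ``sample_ids[j]``
    (log-like scale assumed, not enforced). ``labels`` maps every sample to one
    of exactly two phenotype labels; ``positive_label`` designates the class
    treated as "positive" in confusion-matrix metrics.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    labels: Mapping[str, str] | None = None
    positive_label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise DataError(f"expression matrix must be 2-D, got shape {values.shape}")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"matrix shape {values.shape} does not match {len(self.gene_ids)} genes "
                f"x {len(self.sample_ids)} samples"
            )
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise DataError(f"duplicate gene ID {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise DataError(f"duplicate sample ID {dup!r}")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise DataError(
                f"non-finite expression value for gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if self.labels is not None:
            labels = dict(self.labels)
            object.__setattr__(self, "labels", labels)
            missing = [s for s in self.sample_ids if s not in labels]
            if missing:
                raise DataError(f"sample {missing[0]!r} has no phenotype label")
            classes = sorted({labels[s] for s in self.sample_ids})
            if len(classes) != 2:
                raise DataError(f"expected exactly 2 classes, found {classes}")
            if self.positive_label is None:
                raise DataError("labelled dataset requires a positive_label")
            if self.positive_label not in classes:
                raise DataError(
                    f"positive_label {self.positive_label!r} not among classes {classes}"
                )
            counts = self.class_counts()
            for cls, n in counts.items():
                if n < 2:
                    raise DataError(f"class {cls!r} has only {n} sample(s); need >= 2")
        elif self.positive_label is not None:
            raise DataError("positive_label given but no labels")

    # -- basic geometry -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    # -- labels ---------------------------------------------------------

    @property
    def negative_label(self) -> str:
        self._require_labels()
        classes = {self.labels[s] for s in self.sample_ids}
        (neg,) = classes - {self.positive_label}
        return neg

    def _require_labels(self) -> None:
        if self.labels is None:
            raise DataError("dataset carries no labels")

    def label_array(self) -> np.ndarray:
        """Labels in sample order as an object array."""
        self._require_labels()
        return np.array([self.labels[s] for s in self.sample_ids], dtype=object)

    def y(self) -> np.ndarray:
        """Boolean vector in sample order: True where the sample is positive."""
        self._require_labels()
        return np.array([self.labels[s] == self.positive_label for s in self.sample_ids])

    def class_counts(self) -> dict[str, int]:
        self._require_labels()
        counts: dict[str, int] = {}
        for s in self.sample_ids:
            counts[self.labels[s]] = counts.get(self.labels[s], 0) + 1
        return counts

    def with_labels(self, labels: Mapping[str, str], positive_label: str) -> "ExpressionDataset":
        return replace(self, labels=dict(labels), positive_label=positive_label)

    # -- subsetting -----------------------------------------------------

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        """Row indices for ``genes``; raises naming the first missing gene."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        idx = []
        for g in genes:
            if g not in lookup:
                raise DataError(f"gene {g!r} not present in expression matrix")
            idx.append(lookup[g])
        return np.asarray(idx, dtype=int)

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionDataset":
        """New dataset restricted to the given sample positions (order kept)."""
        idx = np.asarray(indices, dtype=int)
        sample_ids = tuple(self.sample_ids[i] for i in idx)
        labels = None
        if self.labels is not None:
            labels = {s: self.labels[s] for s in sample_ids}
        return ExpressionDataset(
            gene_ids=self.gene_ids,
            sample_ids=sample_ids,
            values=self.values[:, idx],
            labels=labels,
            positive_label=self.positive_label,
        )

    def feature_matrix(self, genes: Sequence[str]) -> np.ndarray:
        """Samples x features matrix for the given genes (SVM orientation)."""
        return self.values[self.gene_index(genes), :].T


@dataclass(frozen=True)
class GeneSet:
    pathway_id: str
    name: str
    genes: tuple[str, ...]  # ordered, deduplicated

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(self.genes) == 0:
            raise DataError(f"pathway {self.pathway_id!r} has an empty gene set")
        if len(set(self.genes)) != len(self.genes):
            raise DataError(f"pathway {self.pathway_id!r} has duplicated genes")


@dataclass
class GeneSetCollection:
    """Ordered pathway_id -> GeneSet map (insertion order = file order)."""

    entries: dict[str, GeneSet] = field(default_factory=dict)

    @classmethod
    def from_sets(cls, sets: Sequence[GeneSet]) -> "GeneSetCollection":
        entries: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.pathway_id in entries:
                raise DataError(f"duplicate pathway ID {gs.pathway_id!r}")
            entries[gs.pathway_id] = gs
        return cls(entries=entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.entries.values())

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.entries

    def __getitem__(self, pathway_id: str) -> GeneSet:
        return self.entries[pathway_id]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.entries.keys())
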