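"""Disagreement diversity between base classifiers.

Two classifiers' outputs on a labelled set are reduced to binary correctness
vectors y_i (1 where classifier h_i classified the sample correctly). Their
pairwise diversity is the disagreement measure

    D_{i,k} = (N10 + N01) / (N11 + N10 + N01 + N00),

the fraction of samples on which exactly one of the two was correct — the
normalised Hamming distance between correctness vectors. A symmetric NxN
diversity matrix over the top learners, averaged over repeated balanced
resamples, feeds the ensemble optimisation; a learner's *overall diversity*
OD[i] = sum_j (D[i,j] + D[j,i]) aggregates its row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import DataError

__all__ = [
    "CorrectnessVector",
    "DiversityMatrix",
    "disagreement",
    "diversity_matrix",
    "overall_diversity",
]


@dataclass(frozen=True)
class CorrectnessVector:
    """Binary per-sample correctness of one classifier over a labelled set."""

    values: np.ndarray
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.uint8)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise DataError("correctness vector must be 1-D")
        if not np.isin(values, (0, 1)).all():
            raise DataError("correctness entries must be 0 or 1")
        if self.sample_ids and len(self.sample_ids) != len(values):
            raise DataError("sample_ids length does not match values")


@dataclass(frozen=True)
class DiversityMatrix:
    """Symmetric pairwise disagreement matrix over an ordered learner list."""

    matrix: np.ndarray
    learner_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "learner_ids", tuple(self.learner_ids))
        n = len(self.learner_ids)
        if m.shape != (n, n):
            raise DataError(f"diversity matrix shape {m.shape} does not match {n} learners")
        if not np.allclose(m, m.T, atol=1e-12):
            raise DataError("diversity matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise DataError("diversity matrix diagonal must be zero")
        if m.min() < -1e-12 or m.max() > 1 + 1e-12:
            raise DataError("diversity entries must lie in [0, 1]")

    def submatrix(self, ids: Sequence[str]) -> "DiversityMatrix":
        pos = {pid: i for i, pid in enumerate(self.learner_ids)}
        idx = np.array([pos[p] for p in ids], dtype=int)
        return DiversityMatrix(matrix=self.matrix[np.ix_(idx, idx)], learner_ids=tuple(ids))

    def value(self, id_a: str, id_b: str) -> float:
        pos = {pid: i for i, pid in enumerate(self.learner_ids)}
        return float(self.matrix[pos[id_a], pos[id_b]])


def _as_values(v) -> np.ndarray:
    if isinstance(v, CorrectnessVector):
        return v.values
    return np.asarray(v, dtype=np.uint8)


def disagreement(y_i, y_k) -> float:
    """Disagreement measure between two binary correctness vectors.

    Equals (N10 + N01)/n, i.e. Hamming distance divided by length; symmetric,
    bounded in [0, 1].
    """
    a, b = _as_values(y_i), _as_values(y_k)
    if len(a) != len(b):
        raise DataError(f"correctness vectors differ in length: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise DataError("correctness vectors must be non-empty")
    if isinstance(y_i, CorrectnessVector) and isinstance(y_k, CorrectnessVector):
        if y_i.sample_ids and y_k.sample_ids and y_i.sample_ids != y_k.sample_ids:
            raise DataError("correctness vectors are not aligned on the same samples")
    return float(np.mean(a != b))


def diversity_matrix(
    vectors_per_repeat: Sequence[Sequence], learner_ids: Sequence[str] | None = None
) -> DiversityMatrix:
    """Average pairwise disagreement over repeats.

    ``vectors_per_repeat[r]`` is the list of aligned correctness vectors (one
    per learner) observed in repeat r — typically one balanced resample. With
    a single repeat this is the plain pairwise matrix.
    """
    if len(vectors_per_repeat) == 0:
        raise DataError("need at least one repeat")
    n_learners = len(vectors_per_repeat[0])
    if n_learners < 2:
        raise DataError("need at least two learners")
    acc = np.zeros((n_learners, n_learners))
    for repeat in vectors_per_repeat:
        if len(repeat) != n_learners:
            raise DataError("inconsistent learner count across repeats")
        try:
            C = np.stack([_as_values(v) for v in repeat])
        except ValueError as exc:
            raise DataError(f"inconsistent correctness vector lengths: {exc}") from exc
        acc += (C[:, None, :] != C[None, :, :]).mean(axis=2)
    acc /= len(vectors_per_repeat)
    np.fill_diagonal(acc, 0.0)
    if learner_ids is None:
        learner_ids = tuple(f"h{i}" for i in range(n_learners))
    return DiversityMatrix(matrix=acc, learner_ids=tuple(learner_ids))


def overall_diversity(D: DiversityMatrix) -> np.ndarray:
    """OD[i] = sum_j (D[i,j] + D[j,i]), the literal double sum.

    For a symmetric matrix this is twice the row sum; the zero diagonal
    contributes nothing either way.
    """
    m = D.matrix
    return m.sum(axis=1) + m.sum(axis=0)
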