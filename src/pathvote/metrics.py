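"""Confusion-matrix metrics and the balanced repeated test harness.

The five reported metrics are

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F-score     = 2 TP / (2 TP + FP + FN)

computed per evaluation run against the designated positive label. A metric
whose denominator is zero in a run is flagged undefined (NaN) and excluded
from the across-run mean/SD rather than coerced to zero. The test harness
scores the already-fitted ensemble on repeated class-balanced subsamples of
the held-out set — the model is never refitted on test data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from ._seeds import rng as _rng
from .containers import DataError, ExpressionDataset
from .learners import CVProtocol, balanced_subsample_indices

if TYPE_CHECKING:  # pragma: no cover
    from .optimizer import EnsembleModel

logger = logging.getLogger(__name__)

__all__ = [
    "METRIC_NAMES",
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "compute_metrics",
    "evaluate_on_test",
]

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "specificity", "f_score")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise DataError("confusion counts must be non-negative")
        if self.total < 1:
            raise DataError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Per-run metric values with across-run means and standard deviations.

    Undefined per-run values are stored as NaN and skipped in the summaries;
    ``mean``/``sd`` are NaN only if a metric was undefined in every run.
    """

    per_run: tuple[dict[str, float], ...]
    mean: dict[str, float]
    sd: dict[str, float]

    @property
    def n_runs(self) -> int:
        return len(self.per_run)

    def to_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "mean": {k: _none_if_nan(v) for k, v in self.mean.items()},
            "sd": {k: _none_if_nan(v) for k, v in self.sd.items()},
            "per_run": [
                {k: _none_if_nan(v) for k, v in run.items()} for run in self.per_run
            ],
        }


def _none_if_nan(v: float) -> float | None:
    return None if (v is None or (isinstance(v, float) and np.isnan(v))) else float(v)


def confusion(predicted: Sequence, truth: Sequence, positive_label) -> ConfusionCounts:
    """Count TP/TN/FP/FN of aligned predicted and true labels."""
    predicted = np.asarray(predicted, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if predicted.shape != truth.shape:
        raise DataError(f"predicted ({predicted.shape}) and truth ({truth.shape}) are not aligned")
    if predicted.size == 0:
        raise DataError("cannot compute a confusion table on zero samples")
    pred_pos = predicted == positive_label
    true_pos = truth == positive_label
    return ConfusionCounts(
        tp=int(np.sum(pred_pos & true_pos)),
        tn=int(np.sum(~pred_pos & ~true_pos)),
        fp=int(np.sum(pred_pos & ~true_pos)),
        fn=int(np.sum(~pred_pos & true_pos)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else np.nan


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """The five metrics for one run; zero-denominator metrics come back NaN."""
    out = {
        "accuracy": (c.tp + c.tn) / c.total,
        "precision": _ratio(c.tp, c.tp + c.fp),
        "sensitivity": _ratio(c.tp, c.tp + c.fn),
        "specificity": _ratio(c.tn, c.tn + c.fp),
        "f_score": _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    }
    for name, v in out.items():
        if np.isnan(v):
            logger.debug("metric %s undefined (zero denominator): %r", name, c)
    return out


def summarize_runs(per_run: Sequence[dict[str, float]]) -> MetricsReport:
    """Across-run mean/SD, excluding undefined (NaN) values per metric."""
    if not per_run:
        raise DataError("no evaluation runs to summarise")
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for name in METRIC_NAMES:
        vals = np.array([run[name] for run in per_run], dtype=float)
        defined = vals[~np.isnan(vals)]
        if len(defined) == 0:
            mean[name] = np.nan
            sd[name] = np.nan
        else:
            mean[name] = float(defined.mean())
            sd[name] = float(defined.std(ddof=1)) if len(defined) > 1 else 0.0
    return MetricsReport(per_run=tuple(dict(r) for r in per_run), mean=mean, sd=sd)


def evaluate_on_test(
    model: "EnsembleModel", test: ExpressionDataset, protocol: CVProtocol
) -> MetricsReport:
    """Score a fitted ensemble on repeated balanced subsamples of the test set.

    Each run draws a seeded class-balanced subsample of the held-out samples,
    the (already-fitted) ensemble predicts, and the five metrics are recorded;
    the report carries per-run values plus mean and SD over runs.
    """
    y = test.y()
    per_run = []
    for run in range(protocol.n_runs):
        if protocol.balance:
            gen = _rng(protocol.seed, "test-resample", run)
            idx = balanced_subsample_indices(y, gen)
        else:
            idx = np.arange(test.n_samples)
        sub = test.subset_samples(idx)
        predicted = model.predict(sub)
        c = confusion(predicted, sub.label_array(), test.positive_label)
        per_run.append(compute_metrics(c))
    return summarize_runs(per_run)
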