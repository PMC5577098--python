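"""Pathway-restricted SVM base classifiers and their balanced CV evaluation.

One base classifier per DE pathway: an RBF-kernel soft-margin SVM (C=1,
gamma = 1/n_features, i.e. the classical library defaults) on features
standardised with training-fold statistics. Each learner is scored by
repeated balanced cross-validation: every run draws a class-balanced
subsample (all minority-class samples plus an equal-size random draw from
the majority class), splits it into stratified folds, and pools the held-out
accuracy; the learner's score is the mean over runs.

The balanced subsample and the fold partition of a run are derived from the
run index alone, so all learners see identical resamples. That keeps their
held-out correctness vectors aligned sample-for-sample — which is what the
pairwise diversity computation needs — while leaving every ranking
reproducible from the master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._seeds import derive_int, rng as _rng
from .containers import DataError, ExpressionDataset
from .de import DEPathway
from .diversity import CorrectnessVector

logger = logging.getLogger(__name__)

__all__ = [
    "CVProtocol",
    "RunPlan",
    "BaseLearnerRecord",
    "make_classifier",
    "train_svm",
    "balanced_subsample_indices",
    "balanced_subsample",
    "build_run_plans",
    "evaluate_learner_cv",
    "evaluate_all_learners",
    "rank_and_select",
]


@dataclass(frozen=True)
class CVProtocol:
    """Repeated balanced k-fold CV protocol (default 100 runs x 5 folds)."""

    n_runs: int = 100
    n_folds: int = 5
    balance: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise DataError("n_folds must be >= 2")
        if self.n_runs < 1:
            raise DataError("n_runs must be >= 1")


@dataclass(frozen=True)
class RunPlan:
    """One CV run: which samples were drawn and their fold assignment.

    ``subsample`` holds dataset sample positions; ``folds[j]`` is the fold in
    which ``subsample[j]`` is held out (each drawn sample is held out exactly
    once per run).
    """

    run_index: int
    subsample: np.ndarray
    folds: np.ndarray


@dataclass
class BaseLearnerRecord:
    """A trained pathway SVM plus its CV score and correctness bookkeeping."""

    pathway_id: str
    name: str
    feature_genes: tuple[str, ...]
    mean_cv_accuracy: float
    run_accuracies: np.ndarray
    correctness: CorrectnessVector
    # per run: boolean "predicted positive" for each sample of the run's
    # subsample (held-out predictions); consumed by diversity and by the
    # cached ensemble evaluation
    run_predictions: list[np.ndarray] = field(repr=False, default_factory=list)
    classifier: Pipeline | None = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not self.feature_genes:
            raise DataError(f"learner {self.pathway_id!r} has no feature genes")
        if not (0.0 <= self.mean_cv_accuracy <= 1.0):
            raise DataError("mean_cv_accuracy must lie in [0, 1]")


def make_classifier(kernel: str = "rbf") -> Pipeline:
    """Standardiser + soft-margin SVM with library-default parameters.

    ``gamma="auto"`` is 1/n_features, the classical libsvm default width.
    """
    if kernel not in ("rbf", "linear"):
        raise DataError(f"unsupported kernel {kernel!r}")
    return make_pipeline(StandardScaler(), SVC(C=1.0, kernel=kernel, gamma="auto"))


def train_svm(X: np.ndarray, y: Sequence, kernel: str = "rbf") -> Pipeline:
    """Fit the base SVM on a samples x features matrix."""
    y = np.asarray(y)
    if len(set(y.tolist())) < 2:
        raise DataError("training data contains a single class")
    clf = make_classifier(kernel)
    clf.fit(X, y)
    return clf


def balanced_subsample_indices(y: np.ndarray, gen: np.random.Generator) -> np.ndarray:
    """All minority-class positions plus an equal-size draw from the majority.

    Returned sorted (dataset order), so an already balanced input maps to the
    identity. ``y`` is the boolean positive-class indicator.
    """
    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    if len(pos) == len(neg):
        return np.arange(len(y))
    minority, majority = (pos, neg) if len(pos) < len(neg) else (neg, pos)
    drawn = gen.choice(majority, size=len(minority), replace=False)
    return np.sort(np.concatenate([minority, drawn]))


def balanced_subsample(dataset: ExpressionDataset, seed: int) -> ExpressionDataset:
    """Seeded class-balanced subsample of a labelled dataset."""
    gen = _rng(seed, "balance")
    idx = balanced_subsample_indices(dataset.y(), gen)
    return dataset.subset_samples(idx)


def _stratified_folds(
    y_sub: np.ndarray, n_folds: int, seed: int, max_attempts: int = 100
) -> np.ndarray:
    """Fold label per sample; every fold's training side must keep both classes."""
    n = len(y_sub)
    for attempt in range(max_attempts):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=(seed + attempt) % 2**31)
        folds = np.empty(n, dtype=int)
        try:
            for f, (_, test_idx) in enumerate(skf.split(np.zeros((n, 1)), y_sub)):
                folds[test_idx] = f
        except ValueError as exc:  # fewer members than folds
            raise DataError(f"cannot build {n_folds} stratified folds: {exc}") from exc
        ok = all(len(set(y_sub[folds != f].tolist())) == 2 for f in range(n_folds))
        if ok:
            return folds
    raise DataError("could not build folds with both classes in every training split")


def build_run_plans(dataset: ExpressionDataset, protocol: CVProtocol) -> list[RunPlan]:
    """Balanced subsample + stratified fold partition for every CV run.

    Plans depend only on the protocol seed and the run index, never on which
    learner is being evaluated, so correctness vectors align across learners.
    """
    y = dataset.y()
    plans = []
    for run in range(protocol.n_runs):
        if protocol.balance:
            gen = _rng(protocol.seed, "resample", run)
            sub = balanced_subsample_indices(y, gen)
        else:
            sub = np.arange(len(y))
        folds = _stratified_folds(y[sub], protocol.n_folds, derive_int(protocol.seed, "folds", run))
        plans.append(RunPlan(run_index=run, subsample=sub, folds=folds))
    return plans


def heldout_predictions(
    dataset: ExpressionDataset,
    feature_genes: Sequence[str],
    plan: RunPlan,
    kernel: str = "rbf",
) -> np.ndarray:
    """Held-out boolean (predicted-positive) vector for one run's subsample."""
    X = dataset.feature_matrix(feature_genes)[plan.subsample]
    y_sub = dataset.y()[plan.subsample]
    pred = np.empty(len(y_sub), dtype=bool)
    for f in np.unique(plan.folds):
        train_mask = plan.folds != f
        clf = train_svm(X[train_mask], y_sub[train_mask], kernel=kernel)
        pred[~train_mask] = clf.predict(X[~train_mask])
    return pred


def evaluate_learner_cv(
    dataset: ExpressionDataset,
    feature_genes: Sequence[str],
    protocol: CVProtocol,
    plans: list[RunPlan] | None = None,
    kernel: str = "rbf",
    pathway_id: str = "",
    name: str = "",
) -> BaseLearnerRecord:
    """Score one pathway learner by repeated balanced CV.

    The record's aggregate correctness vector covers the full training set:
    a sample counts as correctly classified when it was correct in the strict
    majority of the runs in which it was held out (ties, and samples never
    drawn, count as incorrect).
    """
    if plans is None:
        plans = build_run_plans(dataset, protocol)
    y = dataset.y()
    n = len(y)
    run_acc = np.empty(len(plans))
    run_preds: list[np.ndarray] = []
    correct_count = np.zeros(n, dtype=int)
    seen_count = np.zeros(n, dtype=int)
    for r, plan in enumerate(plans):
        pred = heldout_predictions(dataset, feature_genes, plan, kernel=kernel)
        correct = pred == y[plan.subsample]
        run_acc[r] = correct.mean()
        run_preds.append(pred)
        correct_count[plan.subsample] += correct
        seen_count[plan.subsample] += 1
    agg = (2 * correct_count > seen_count).astype(np.uint8)
    record = BaseLearnerRecord(
        pathway_id=pathway_id,
        name=name,
        feature_genes=tuple(feature_genes),
        mean_cv_accuracy=float(run_acc.mean()),
        run_accuracies=run_acc,
        correctness=CorrectnessVector(values=agg, sample_ids=dataset.sample_ids),
        run_predictions=run_preds,
    )
    return record


def evaluate_all_learners(
    dataset: ExpressionDataset,
    de_pathways: Sequence[DEPathway],
    protocol: CVProtocol,
    kernel: str = "rbf",
    plans: list[RunPlan] | None = None,
) -> list[BaseLearnerRecord]:
    """Evaluate every DE pathway against the same run plans."""
    if plans is None:
        plans = build_run_plans(dataset, protocol)
    records = []
    for dp in de_pathways:
        rec = evaluate_learner_cv(
            dataset,
            dp.feature_genes,
            protocol,
            plans=plans,
            kernel=kernel,
            pathway_id=dp.pathway_id,
            name=dp.name,
        )
        records.append(rec)
    return records


def rank_and_select(records: Sequence[BaseLearnerRecord], top_n: int = 35) -> list[BaseLearnerRecord]:
    """Sort by mean CV accuracy (descending, ties by pathway ID) and keep top N."""
    if top_n < 1:
        raise DataError("top_n must be >= 1")
    if not records:
        raise DataError("no base learners to rank")
    ranked = sorted(records, key=lambda r: (-r.mean_cv_accuracy, r.pathway_id))
    if len(ranked) < top_n:
        logger.warning("only %d learners available for top_n=%d; keeping all", len(ranked), top_n)
    return ranked[:top_n]
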