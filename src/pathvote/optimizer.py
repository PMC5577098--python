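"""Two-stage diversity-driven ensemble selection and majority voting.

Starting from the accuracy-ranked top-N pathway learners S, the optimiser:

1. computes overall diversity OD for each learner and reorders S as S*
   (OD descending, ties keeping accuracy rank);
2. *preliminary optimisation*: grows the ensemble along S* one learner at a
   time, scoring every prefix by the same repeated balanced CV used for the
   base learners with majority-vote predictions, and keeps the smallest
   prefix size m achieving the best mean accuracy (S' = first m of S*);
3. *second optimisation*: repeatedly takes the surviving pair with the
   lowest diversity below the threshold theta and compares four candidates —
   keep both (S1), drop the later learner (S2), drop the earlier one (S3),
   drop both (S4) — by the identical CV; the most accurate candidate wins,
   with ties resolved by the priority S4 > S3 > S2 > S1 (prefer smaller
   ensembles). Each pair is resolved at most once.

The surviving learners S'' vote by simple majority; an even-split tie is
broken by the vote of the member with the highest base CV accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._seeds import derive_int, rng as _rng
from .config import RunConfig
from .containers import DataError, ExpressionDataset, GeneSetCollection
from .de import map_pathways_to_de, screen_de_genes
from .diversity import DiversityMatrix, diversity_matrix, overall_diversity
from .learners import (
    BaseLearnerRecord,
    CVProtocol,
    RunPlan,
    balanced_subsample_indices,
    build_run_plans,
    evaluate_all_learners,
    heldout_predictions,
    rank_and_select,
    train_svm,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionTrace",
    "EnsembleModel",
    "RemovalRecord",
    "reorder_by_od",
    "majority_vote",
    "evaluate_ensemble_cv",
    "preliminary_optimize",
    "prune_ensemble",
    "diversity_from_records",
    "fit_ensemble",
    "predict",
]

#: candidate options for one low-diversity pair, in tie priority order
_OPTION_PRIORITY = ("S4", "S3", "S2", "S1")

#: accuracies closer than this are treated as equal when applying the
#: S4 > S3 > S2 > S1 priority (CV means under a shared seed stream are
#: bit-identical for identical ensembles, so this only absorbs float noise)
ACCURACY_TIE_EPS = 1e-6


@dataclass(frozen=True)
class RemovalRecord:
    """Audit entry for one low-diversity pair decision during pruning."""

    pair: tuple[str, str]
    diversity: float
    option: str  # chosen among S1..S4
    accuracies: dict[str, float]  # option -> CV mean accuracy (absent if infeasible)

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "diversity": self.diversity,
            "option": self.option,
            "accuracies": dict(sorted(self.accuracies.items())),
        }


@dataclass(frozen=True)
class SelectionTrace:
    """Complete record of the two-stage selection."""

    S: tuple[str, ...]  # accuracy order (top N)
    S_star: tuple[str, ...]  # OD-descending order
    prefix_accuracies: tuple[tuple[int, float], ...]
    m: int
    S_prime: tuple[str, ...]
    removed_pairs: tuple[RemovalRecord, ...]
    S_doubleprime: tuple[str, ...]
    theta: float

    def __post_init__(self) -> None:
        if set(self.S_star) != set(self.S):
            raise DataError("S* must be a permutation of S")
        if self.S_prime != self.S_star[: self.m]:
            raise DataError("S' must be the first m learners of S*")
        if not set(self.S_doubleprime) <= set(self.S_prime):
            raise DataError("S'' must be a subset of S'")
        if not (1 <= len(self.S_doubleprime) <= self.m):
            raise DataError("S'' size must lie in [1, m]")

    def to_dict(self) -> dict:
        return {
            "S": list(self.S),
            "S_star": list(self.S_star),
            "prefix_accuracies": [[size, acc] for size, acc in self.prefix_accuracies],
            "m": self.m,
            "S_prime": list(self.S_prime),
            "removed_pairs": [r.to_dict() for r in self.removed_pairs],
            "S_doubleprime": list(self.S_doubleprime),
            "theta": self.theta,
        }


@dataclass
class EnsembleModel:
    """Final majority-vote ensemble of pathway SVMs plus its selection trace."""

    learners: list[BaseLearnerRecord]
    positive_label: str
    negative_label: str
    trace: SelectionTrace
    kernel: str = "rbf"
    diversity: DiversityMatrix | None = None
    overall_diversity: dict[str, float] | None = None

    def predict(self, test: ExpressionDataset) -> np.ndarray:
        return predict(self, test)


def reorder_by_od(records: Sequence[BaseLearnerRecord], od: np.ndarray) -> list[BaseLearnerRecord]:
    """Stable sort by overall diversity descending; ties keep accuracy rank."""
    if len(od) != len(records):
        raise DataError("OD vector is not aligned with the learner list")
    order = np.argsort(-np.asarray(od, dtype=float), kind="stable")
    return [records[i] for i in order]


def majority_vote(votes: Sequence, tie_break_weights: Sequence[float] | None = None):
    """Majority label among T votes; an exact even-split tie follows the vote
    of the member with the highest weight (base CV accuracy)."""
    votes = list(votes)
    T = len(votes)
    if T == 0:
        raise DataError("majority vote needs at least one vote")
    counts: dict = {}
    for v in votes:
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.values())
    leaders = [v for v, c in counts.items() if c == best]
    if len(leaders) == 1:
        return leaders[0]
    if tie_break_weights is None:
        raise DataError("tied vote requires tie_break_weights")
    return votes[int(np.argmax(np.asarray(tie_break_weights, dtype=float)))]


def _vote_matrix(pred_rows: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Vectorised majority vote over a members x samples boolean matrix."""
    T = pred_rows.shape[0]
    pos = pred_rows.sum(axis=0)
    out = pos * 2 > T
    tie = pos * 2 == T
    if tie.any():
        out[tie] = pred_rows[int(np.argmax(weights))][tie]
    return out


def evaluate_ensemble_cv(
    dataset: ExpressionDataset,
    members: Sequence[BaseLearnerRecord],
    protocol: CVProtocol,
    plans: list[RunPlan] | None = None,
    kernel: str = "rbf",
    use_cache: bool = True,
) -> float:
    """Mean repeated-CV accuracy of the majority-vote ensemble.

    With ``use_cache=True`` (default) the per-learner held-out fold
    predictions already computed during base-learner evaluation are reused
    and only the vote is recomputed — a pure optimisation: the fold plans are
    shared and one member's fold fit never depends on the other members, so
    the result equals naive re-evaluation (asserted in the test suite).
    """
    if not members:
        raise DataError("ensemble has no members")
    if plans is None:
        plans = build_run_plans(dataset, protocol)
    weights = np.array([rec.mean_cv_accuracy for rec in members])
    y = dataset.y()
    accs = np.empty(len(plans))
    for r, plan in enumerate(plans):
        if use_cache and all(len(rec.run_predictions) > r for rec in members):
            P = np.stack([rec.run_predictions[r] for rec in members])
        else:
            P = np.stack(
                [heldout_predictions(dataset, rec.feature_genes, plan, kernel=kernel) for rec in members]
            )
        voted = _vote_matrix(P, weights)
        accs[r] = np.mean(voted == y[plan.subsample])
    return float(accs.mean())


def preliminary_optimize(
    s_star: Sequence[BaseLearnerRecord],
    dataset: ExpressionDataset,
    protocol: CVProtocol,
    plans: list[RunPlan] | None = None,
    kernel: str = "rbf",
    min_prefix: int = 1,
    use_cache: bool = True,
) -> tuple[int, list[tuple[int, float]]]:
    """Sweep ensemble prefixes of S* and return (m, accuracy curve).

    m is the smallest prefix size achieving the maximum mean accuracy.
    """
    if not s_star:
        raise DataError("S* is empty")
    if plans is None:
        plans = build_run_plans(dataset, protocol)
    min_prefix = max(1, min_prefix)
    curve: list[tuple[int, float]] = []
    for size in range(min_prefix, len(s_star) + 1):
        acc = evaluate_ensemble_cv(
            dataset, s_star[:size], protocol, plans=plans, kernel=kernel, use_cache=use_cache
        )
        curve.append((size, acc))
    best = max(acc for _, acc in curve)
    m = next(size for size, acc in curve if acc == best)
    return m, curve


def prune_ensemble(
    s_prime: Sequence[BaseLearnerRecord],
    D: DiversityMatrix,
    theta: float,
    dataset: ExpressionDataset,
    protocol: CVProtocol,
    plans: list[RunPlan] | None = None,
    kernel: str = "rbf",
    use_cache: bool = True,
) -> tuple[list[BaseLearnerRecord], list[RemovalRecord]]:
    """Second optimisation: resolve every surviving pair with diversity < theta.

    Pairs are processed most-redundant first (ascending D, lexicographic tie
    break) and each pair is resolved at most once. For each pair the four
    candidates S1 (keep both), S2 (drop the later member), S3 (drop the
    earlier member) and S4 (drop both, infeasible if it would empty the
    ensemble) are scored by the shared-seed CV; the best accuracy wins and
    ties within ``ACCURACY_TIE_EPS`` fall to the priority S4 > S3 > S2 > S1.
    """
    if not (0 <= theta <= 1):
        raise DataError(f"theta must lie in [0, 1], got {theta}")
    if plans is None:
        plans = build_run_plans(dataset, protocol)
    survivors = list(s_prime)
    resolved: set[frozenset[str]] = set()
    removed: list[RemovalRecord] = []

    def _eval(members: Sequence[BaseLearnerRecord]) -> float:
        return evaluate_ensemble_cv(
            dataset, members, protocol, plans=plans, kernel=kernel, use_cache=use_cache
        )

    while True:
        candidates = []
        for a in range(len(survivors)):
            for b in range(a + 1, len(survivors)):
                id_a, id_b = survivors[a].pathway_id, survivors[b].pathway_id
                key = frozenset((id_a, id_b))
                if key in resolved:
                    continue
                d = D.value(id_a, id_b)
                if d < theta:
                    candidates.append((d, tuple(sorted((id_a, id_b))), a, b))
        if not candidates:
            break
        d, _, a, b = min(candidates)
        rec_i, rec_k = survivors[a], survivors[b]  # i earlier in S' order
        options: dict[str, list[BaseLearnerRecord]] = {
            "S1": survivors,
            "S2": [r for r in survivors if r is not rec_k],
            "S3": [r for r in survivors if r is not rec_i],
        }
        s4 = [r for r in survivors if r is not rec_i and r is not rec_k]
        if s4:  # never reduce the ensemble below one member
            options["S4"] = s4
        accs = {opt: _eval(members) for opt, members in options.items()}
        best = max(accs.values())
        choice = next(opt for opt in _OPTION_PRIORITY if opt in accs and accs[opt] >= best - ACCURACY_TIE_EPS)
        removed.append(
            RemovalRecord(
                pair=(rec_i.pathway_id, rec_k.pathway_id),
                diversity=d,
                option=choice,
                accuracies=accs,
            )
        )
        resolved.add(frozenset((rec_i.pathway_id, rec_k.pathway_id)))
        survivors = options[choice]
        logger.info(
            "pruning pair (%s, %s) D=%.4f -> %s; %d survivors",
            rec_i.pathway_id,
            rec_k.pathway_id,
            d,
            choice,
            len(survivors),
        )
    return list(survivors), removed


def diversity_from_records(
    records: Sequence[BaseLearnerRecord],
    plans: Sequence[RunPlan],
    y: np.ndarray,
) -> DiversityMatrix:
    """Pairwise disagreement averaged over the CV runs.

    In each run every learner's held-out predictions cover the same balanced
    subsample, giving aligned per-run correctness vectors; Eq. (1) is applied
    per run and the matrix is the mean over runs.
    """
    repeats = []
    for r, plan in enumerate(plans):
        truth = y[plan.subsample]
        repeats.append([(rec.run_predictions[r] == truth).astype(np.uint8) for rec in records])
    return diversity_matrix(repeats, learner_ids=[rec.pathway_id for rec in records])


def fit_ensemble(
    train: ExpressionDataset,
    pathways: GeneSetCollection,
    config: RunConfig | None = None,
) -> EnsembleModel:
    """End-to-end fit: DE screen -> base learners -> diversity -> two-stage
    selection -> final refit of survivors on a balanced subsample."""
    cfg = config or RunConfig()
    de = screen_de_genes(train, alpha=cfg.alpha, method=cfg.de_method, adjust=cfg.adjust_p)
    logger.info("DE screen: %d of %d genes at alpha=%g", int(de.is_de.sum()), train.n_genes, cfg.alpha)
    de_pathways = map_pathways_to_de(pathways, de)
    logger.info("%d DE pathways of %d input pathways", len(de_pathways), len(pathways))

    protocol = CVProtocol(
        n_runs=cfg.n_runs, n_folds=cfg.n_folds, balance=True, seed=derive_int(cfg.seed, "cv")
    )
    plans = build_run_plans(train, protocol)
    records = evaluate_all_learners(train, de_pathways, protocol, kernel=cfg.kernel, plans=plans)
    S = rank_and_select(records, top_n=cfg.top_n)
    logger.info("top-%d accuracy range: %.4f .. %.4f", len(S), S[-1].mean_cv_accuracy, S[0].mean_cv_accuracy)

    y = train.y()
    if len(S) >= 2:
        D = diversity_from_records(S, plans, y)
        od = overall_diversity(D)
    else:
        D = DiversityMatrix(matrix=np.zeros((1, 1)), learner_ids=(S[0].pathway_id,))
        od = np.zeros(1)
    s_star = reorder_by_od(S, od)

    m, curve = preliminary_optimize(
        s_star, train, protocol, plans=plans, kernel=cfg.kernel, min_prefix=cfg.min_prefix
    )
    s_prime = s_star[:m]
    logger.info("preliminary optimisation: m=%d, best CV accuracy %.4f", m, max(a for _, a in curve))
    if len(s_prime) >= 2:
        survivors, removed = prune_ensemble(
            s_prime, D, cfg.theta, train, protocol, plans=plans, kernel=cfg.kernel
        )
    else:
        survivors, removed = list(s_prime), []
    logger.info("second optimisation: %d of %d learners survive", len(survivors), m)

    # final refit of each survivor on one seeded balanced subsample of the
    # full training set
    gen = _rng(cfg.seed, "final-fit")
    idx = balanced_subsample_indices(y, gen)
    for rec in survivors:
        X = train.feature_matrix(rec.feature_genes)[idx]
        rec.classifier = train_svm(X, y[idx], kernel=cfg.kernel)

    trace = SelectionTrace(
        S=tuple(r.pathway_id for r in S),
        S_star=tuple(r.pathway_id for r in s_star),
        prefix_accuracies=tuple(curve),
        m=m,
        S_prime=tuple(r.pathway_id for r in s_prime),
        removed_pairs=tuple(removed),
        S_doubleprime=tuple(r.pathway_id for r in survivors),
        theta=cfg.theta,
    )
    od_map = {rec.pathway_id: float(v) for rec, v in zip(S, od)}
    return EnsembleModel(
        learners=survivors,
        positive_label=train.positive_label,
        negative_label=train.negative_label,
        trace=trace,
        kernel=cfg.kernel,
        diversity=D,
        overall_diversity=od_map,
    )


def predict(model: EnsembleModel, test: ExpressionDataset) -> np.ndarray:
    """Per-sample majority-vote labels of the fitted ensemble on a test set."""
    preds = []
    for rec in model.learners:
        if rec.classifier is None:
            raise DataError(f"learner {rec.pathway_id!r} has not been fitted")
        try:
            X = test.feature_matrix(rec.feature_genes)
        except DataError as exc:
            raise DataError(f"{exc} (required by pathway {rec.pathway_id!r})") from exc
        preds.append(np.asarray(rec.classifier.predict(X), dtype=bool))
    P = np.stack(preds)
    weights = np.array([rec.mean_cv_accuracy for rec in model.learners])
    voted = _vote_matrix(P, weights)
    return np.where(voted, model.positive_label, model.negative_label)
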