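import json

import numpy as np
import pytest

from pathvote import (
    CVProtocol,
    DiversityMatrix,
    RunConfig,
    SimulationConfig,
    evaluate_ensemble_cv,
    evaluate_learner_cv,
    fit_ensemble,
    majority_vote,
    predict,
    preliminary_optimize,
    prune_ensemble,
    reorder_by_od,
    simulate,
)
from pathvote.containers import DataError
from pathvote.learners import BaseLearnerRecord, build_run_plans, evaluate_all_learners
from pathvote.optimizer import diversity_from_records

from conftest import make_dataset


def _rec(pid, acc):
    return BaseLearnerRecord(
        pathway_id=pid,
        name=pid,
        feature_genes=("g",),
        mean_cv_accuracy=acc,
        run_accuracies=np.array([acc]),
        correctness=None,
    )


class TestReorderByOd:
    def test_descending_od(self):
        recs = [_rec("A", 0.9), _rec("B", 0.8), _rec("C", 0.7)]
        out = reorder_by_od(recs, np.array([1.2, 1.6, 2.0]))
        assert [r.pathway_id for r in out] == ["C", "B", "A"]

    def test_ties_keep_accuracy_rank(self):
        recs = [_rec("A", 0.9), _rec("B", 0.8), _rec("C", 0.7)]
        out = reorder_by_od(recs, np.array([1.0, 1.0, 1.0]))
        assert [r.pathway_id for r in out] == ["A", "B", "C"]

    def test_singleton(self):
        recs = [_rec("A", 0.9)]
        assert reorder_by_od(recs, np.zeros(1)) == recs


class TestMajorityVote:
    def test_odd_majority(self):
        assert majority_vote(["pos", "pos", "neg"]) == "pos"

    def test_even_tie_follows_best_member(self):
        votes = ["pos", "pos", "neg", "neg"]
        weights = [0.7, 0.8, 0.9, 0.6]  # best member voted neg
        assert majority_vote(votes, weights) == "neg"

    def test_zero_votes_rejected(self):
        with pytest.raises(DataError):
            majority_vote([])

    @pytest.mark.parametrize("T", [1, 3, 5, 7])
    def test_correct_iff_floor_half_plus_one(self, T):
        """Exhaustive: the vote is correct exactly when at least
        floor(T/2 + 1) members are correct."""
        threshold = int(np.floor(T / 2 + 1))
        for pattern in range(2**T):
            correctness = [(pattern >> i) & 1 for i in range(T)]
            votes = ["true" if c else "wrong" for c in correctness]
            outcome = majority_vote(votes, tie_break_weights=[0.5] * T)
            assert (outcome == "true") == (sum(correctness) >= threshold)


class TestEvaluateEnsembleCV:
    def test_single_member_equals_learner_cv(self, small_cohort):
        ds, coll, truth = small_cohort
        protocol = CVProtocol(n_runs=3, seed=5)
        plans = build_run_plans(ds, protocol)
        genes = coll[sorted(truth)[0]].genes[:4]
        rec = evaluate_learner_cv(ds, genes, protocol, plans=plans, pathway_id="pw")
        acc = evaluate_ensemble_cv(ds, [rec], protocol, plans=plans)
        assert acc == rec.mean_cv_accuracy

    def test_identical_members_match_single(self, small_cohort):
        ds, coll, truth = small_cohort
        protocol = CVProtocol(n_runs=3, seed=5)
        plans = build_run_plans(ds, protocol)
        genes = coll[sorted(truth)[0]].genes[:4]
        rec = evaluate_learner_cv(ds, genes, protocol, plans=plans, pathway_id="pw")
        acc3 = evaluate_ensemble_cv(ds, [rec, rec, rec], protocol, plans=plans)
        assert acc3 == rec.mean_cv_accuracy

    def test_separable_data_scores_one(self, separable_dataset):
        protocol = CVProtocol(n_runs=2, seed=1)
        plans = build_run_plans(separable_dataset, protocol)
        rec = evaluate_learner_cv(separable_dataset, ["g0"], protocol, plans=plans, pathway_id="pw")
        assert evaluate_ensemble_cv(separable_dataset, [rec], protocol, plans=plans) == 1.0

    def test_cached_equals_naive_refit(self, small_cohort):
        """The prediction cache is a pure optimisation: votes over cached
        per-fold predictions must equal full re-evaluation."""
        ds, coll, truth = small_cohort
        protocol = CVProtocol(n_runs=3, seed=2)
        plans = build_run_plans(ds, protocol)
        recs = [
            evaluate_learner_cv(ds, coll[pid].genes[:5], protocol, plans=plans, pathway_id=pid)
            for pid in list(coll.ids)[:4]
        ]
        cached = evaluate_ensemble_cv(ds, recs, protocol, plans=plans, use_cache=True)
        naive = evaluate_ensemble_cv(ds, recs, protocol, plans=plans, use_cache=False)
        assert cached == naive


class TestPreliminaryOptimize:
    def test_perfect_learner_first_gives_m_one(self, separable_dataset):
        protocol = CVProtocol(n_runs=3, seed=3)
        plans = build_run_plans(separable_dataset, protocol)
        perfect = evaluate_learner_cv(separable_dataset, ["g0"], protocol, plans=plans, pathway_id="perfect")
        noise1 = evaluate_learner_cv(separable_dataset, ["g1"], protocol, plans=plans, pathway_id="noise1")
        noise2 = evaluate_learner_cv(separable_dataset, ["g2"], protocol, plans=plans, pathway_id="noise2")
        m, curve = preliminary_optimize([perfect, noise1, noise2], separable_dataset, protocol, plans=plans)
        assert m == 1
        assert curve[0] == (1, 1.0)

    def test_flat_curve_picks_smallest_prefix(self, separable_dataset):
        protocol = CVProtocol(n_runs=2, seed=3)
        plans = build_run_plans(separable_dataset, protocol)
        rec = evaluate_learner_cv(separable_dataset, ["g0"], protocol, plans=plans, pathway_id="p")
        m, curve = preliminary_optimize([rec, rec, rec], separable_dataset, protocol, plans=plans)
        assert m == 1
        assert all(acc == curve[0][1] for _, acc in curve)

    def test_min_prefix_restricts_sweep(self, small_cohort):
        ds, coll, _ = small_cohort
        protocol = CVProtocol(n_runs=2, seed=4)
        plans = build_run_plans(ds, protocol)
        recs = [
            evaluate_learner_cv(ds, coll[pid].genes[:5], protocol, plans=plans, pathway_id=pid)
            for pid in list(coll.ids)[:5]
        ]
        m, curve = preliminary_optimize(recs, ds, protocol, plans=plans, min_prefix=3)
        assert curve[0][0] == 3
        assert m >= 3


class TestPruneEnsemble:
    def _records(self, ds, coll, protocol, plans, ids):
        return [
            evaluate_learner_cv(ds, coll[pid].genes[:5], protocol, plans=plans, pathway_id=pid)
            for pid in ids
        ]

    def test_nothing_qualifies_when_all_diverse(self, small_cohort):
        ds, coll, _ = small_cohort
        protocol = CVProtocol(n_runs=2, seed=6)
        plans = build_run_plans(ds, protocol)
        recs = self._records(ds, coll, protocol, plans, list(coll.ids)[:3])
        m = np.array([[0, 0.4, 0.5], [0.4, 0, 0.45], [0.5, 0.45, 0]])
        D = DiversityMatrix(matrix=m, learner_ids=tuple(r.pathway_id for r in recs))
        survivors, removed = prune_ensemble(recs, D, 0.15, ds, protocol, plans=plans)
        assert survivors == recs
        assert removed == []

    def test_duplicate_learners_are_pruned(self, separable_dataset):
        """Two exact copies of a perfect learner add nothing: the zero-diversity
        pair is removed by the S4-first priority without hurting accuracy."""
        protocol = CVProtocol(n_runs=3, seed=7)
        plans = build_run_plans(separable_dataset, protocol)
        base = evaluate_learner_cv(separable_dataset, ["g0"], protocol, plans=plans, pathway_id="base")
        dup1 = evaluate_learner_cv(separable_dataset, ["g0"], protocol, plans=plans, pathway_id="dup1")
        dup2 = evaluate_learner_cv(separable_dataset, ["g0"], protocol, plans=plans, pathway_id="dup2")
        members = [base, dup1, dup2]
        D = diversity_from_records(members, plans, separable_dataset.y())
        assert D.matrix.max() == 0.0
        survivors, removed = prune_ensemble(members, D, 0.15, separable_dataset, protocol, plans=plans)
        assert len(survivors) == 1
        assert removed[0].option == "S4"

    def test_invalid_theta_rejected(self, small_cohort):
        ds, coll, _ = small_cohort
        protocol = CVProtocol(n_runs=2, seed=6)
        plans = build_run_plans(ds, protocol)
        recs = self._records(ds, coll, protocol, plans, list(coll.ids)[:2])
        D = DiversityMatrix(matrix=np.zeros((2, 2)), learner_ids=tuple(r.pathway_id for r in recs))
        with pytest.raises(DataError, match="theta"):
            prune_ensemble(recs, D, 1.5, ds, protocol, plans=plans)


class TestFitEnsembleAndPredict:
    def _fit(self, seed=11, **kwargs):
        cfg = SimulationConfig(
            n_genes=400, n_pathways=12, pathway_size_range=(5, 15),
            n_informative_pathways=3, n_pos=30, n_neg=30, seed=seed,
        )
        ds, coll, truth = simulate(cfg)
        rc = RunConfig(n_runs=4, top_n=8, seed=seed, **kwargs)
        return ds, coll, truth, fit_ensemble(ds, coll, rc)

    def test_trace_invariants(self):
        ds, coll, truth, model = self._fit()
        tr = model.trace
        assert set(tr.S_star) == set(tr.S)
        assert tr.S_prime == tr.S_star[: tr.m]
        assert set(tr.S_doubleprime) <= set(tr.S_prime)
        assert 1 <= len(tr.S_doubleprime) <= tr.m
        # post-pruning: every surviving pair is diverse or explicitly retained
        retained = {frozenset(r.pair) for r in tr.removed_pairs if r.option == "S1"}
        for i, a in enumerate(tr.S_doubleprime):
            for b in tr.S_doubleprime[i + 1 :]:
                assert model.diversity.value(a, b) >= tr.theta or frozenset((a, b)) in retained

    def test_same_seed_reproduces_trace_bytes(self):
        _, _, _, m1 = self._fit()
        _, _, _, m2 = self._fit()
        assert json.dumps(m1.trace.to_dict(), sort_keys=True) == json.dumps(
            m2.trace.to_dict(), sort_keys=True
        )

    def test_predict_resubstitution_on_separable_cohort(self):
        ds, coll, truth, model = self._fit()
        # strong-signal cohort: training-set predictions recover most labels
        labels = predict(model, ds)
        acc = float(np.mean(labels == ds.label_array()))
        assert acc > 0.8

    def test_predict_invariant_to_test_column_order(self):
        ds, coll, truth, model = self._fit()
        perm = np.random.default_rng(0).permutation(ds.n_samples)
        shuffled = ds.subset_samples(perm)
        a = dict(zip(ds.sample_ids, predict(model, ds)))
        b = dict(zip(shuffled.sample_ids, predict(model, shuffled)))
        assert a == b

    def test_predict_missing_feature_gene_names_gene_and_pathway(self):
        ds, coll, truth, model = self._fit()
        genes_needed = model.learners[0].feature_genes
        keep = [i for i, g in enumerate(ds.gene_ids) if g != genes_needed[0]]
        from pathvote import ExpressionDataset

        crippled = ExpressionDataset(
            gene_ids=tuple(ds.gene_ids[i] for i in keep),
            sample_ids=ds.sample_ids,
            values=ds.values[keep],
            labels=ds.labels,
            positive_label=ds.positive_label,
        )
        with pytest.raises(DataError, match=genes_needed[0]):
            predict(model, crippled)

    def test_single_member_ensemble_matches_member_svm(self, separable_dataset):
        protocol = CVProtocol(n_runs=2, seed=1)
        plans = build_run_plans(separable_dataset, protocol)
        rec = evaluate_learner_cv(separable_dataset, ["g0"], protocol, plans=plans, pathway_id="pw")
        from pathvote.learners import train_svm

        X = separable_dataset.feature_matrix(["g0"])
        rec.classifier = train_svm(X, separable_dataset.y())
        from pathvote.optimizer import EnsembleModel, SelectionTrace

        trace = SelectionTrace(
            S=("pw",), S_star=("pw",), prefix_accuracies=((1, 1.0),), m=1,
            S_prime=("pw",), removed_pairs=(), S_doubleprime=("pw",), theta=0.15,
        )
        model = EnsembleModel(
            learners=[rec], positive_label="pos", negative_label="neg", trace=trace,
        )
        single = rec.classifier.predict(X)
        voted = predict(model, separable_dataset)
        assert np.array_equal(voted == "pos", single)
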