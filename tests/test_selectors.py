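import numpy as np
import pytest

from igisplus import (
    ClassifierSpec,
    LabeledExpressionMatrix,
    choose_best_prefix,
    cohens_d,
    igis_original,
    igis_plus,
    make_folds,
    select_first_gene,
)
from igisplus.selectors import SelectionResult, StepRecord

from conftest import perfect_gene_data

KNN = ClassifierSpec("knn")


def noisy_informative_data(m=24, n_noise=4, effect=1.2, seed=3):
    """Gene 0 separates classes imperfectly; the rest is noise."""
    rng = np.random.default_rng(seed)
    labels = np.repeat([0, 1], m // 2)
    values = rng.standard_normal((m, n_noise + 1))
    values[:, 0] = labels * effect + rng.standard_normal(m)
    return LabeledExpressionMatrix(
        values, [f"g{i}" for i in range(n_noise + 1)], labels
    )


def early_stop_fixture():
    """A dataset on which the original algorithm provably stops early.

    One moderately informative gene among noise, at a sample size small
    enough that some candidate passes the training t-test yet significantly
    hurts validation. Frozen seed; behaviour is deterministic.
    """
    rng = np.random.default_rng(49)
    labels = np.repeat([0, 1], 12)
    values = rng.standard_normal((24, 40))
    values[:, 0] = labels * 1.2 + rng.standard_normal(24)
    data = LabeledExpressionMatrix(values, [f"g{i}" for i in range(40)], labels)
    folds = make_folds(labels, 4, seed=49)
    return data, folds


class TestFirstGene:
    def test_label_identical_gene_wins(self, rng):
        labels = np.repeat([0, 1], 10)
        values = rng.standard_normal((20, 6))
        values[:, 3] = labels
        data = LabeledExpressionMatrix(values, list("abcdef"), labels)
        assert select_first_gene(data, None, KNN) == 3

    def test_accuracy_tie_broken_by_mutual_information(self):
        labels = np.repeat([0, 1], 6)
        # genes 0 and 1 both classify perfectly; gene 0's duplicate-free copy
        # and gene 1 identical to labels: MI ties too -> smaller index
        values = np.column_stack([labels * 2.0, labels * 1.0, labels * 0.0 + 0.5])
        data = LabeledExpressionMatrix(values, list("abc"), labels)
        assert select_first_gene(data, None, KNN) == 0

    def test_planted_gene_found_across_seeds(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            labels = np.repeat([0, 1], 20)
            values = rng.standard_normal((40, 101))
            values[:, 50] = labels * 4.0 + rng.standard_normal(40)
            data = LabeledExpressionMatrix(
                values, [f"g{i}" for i in range(101)], labels
            )
            if select_first_gene(data, None, KNN) == 50:
                hits += 1
        assert hits >= 19


class TestIgisPlus:
    def test_perfect_gene_stops_immediately(self):
        data = perfect_gene_data()
        folds = make_folds(data.labels, 4, seed=0)
        res = igis_plus(data, None, KNN, folds)
        assert res.selected == [0]
        assert res.stop_reason == "perfect_accuracy"
        assert res.wrapper_evaluations == 1

    def test_exact_duplicates_stop_as_redundant(self, rng):
        labels = np.repeat([0, 1], 12)
        g0 = labels * 1.0 + rng.normal(0, 0.8, 24)
        data = LabeledExpressionMatrix(
            np.column_stack([g0] * 5), [f"g{i}" for i in range(5)], labels
        )
        folds = make_folds(labels, 4, seed=0)
        res = igis_plus(data, None, KNN, folds)
        assert res.stop_reason == "all_jmi_negative"
        assert res.selected == [0]
        # the redundant copies were never wrapper-evaluated
        assert res.wrapper_evaluations == 1

    def test_noise_dataset_exhausts_all_genes(self, rng):
        labels = np.repeat([0, 1], 15)
        data = LabeledExpressionMatrix(
            rng.standard_normal((30, 20)), [f"g{i}" for i in range(20)], labels
        )
        folds = make_folds(labels, 4, seed=1)
        res = igis_plus(data, None, KNN, folds)
        assert res.stop_reason == "exhausted_all_genes"
        assert res.wrapper_evaluations <= 20

    def test_pure_noise_selects_few_genes(self):
        sizes = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            labels = np.repeat([0, 1], 15)
            data = LabeledExpressionMatrix(
                rng.standard_normal((30, 25)),
                [f"g{i}" for i in range(25)],
                labels,
            )
            folds = make_folds(labels, 4, seed=seed)
            sizes.append(len(igis_plus(data, None, KNN, folds).selected))
        assert np.mean(sizes) <= 3

    def test_acceptance_monotonicity_reassertable_from_log(self):
        data = noisy_informative_data(m=40, n_noise=30, seed=7)
        folds = make_folds(data.labels, 4, seed=7)
        res = igis_plus(data, None, KNN, folds)
        accepted = res.accepted_steps()
        for prev, step in zip(accepted, accepted[1:]):
            assert cohens_d(step.train_acc, prev.train_acc) >= 0.40
            assert cohens_d(step.val_acc, prev.val_acc) >= 0.15

    def test_each_candidate_drawn_once(self):
        data = noisy_informative_data(m=30, n_noise=14, seed=5)
        folds = make_folds(data.labels, 4, seed=5)
        res = igis_plus(data, None, KNN, folds)
        genes = [s.gene for s in res.step_log]
        assert len(genes) == len(set(genes))
        assert len(res.selected) == len(set(res.selected))
        assert res.wrapper_evaluations <= data.n_genes
        assert set(res.selected) <= set(genes)

    def test_deterministic(self):
        data = noisy_informative_data(m=30, n_noise=10, seed=2)
        folds = make_folds(data.labels, 4, seed=2)
        a = igis_plus(data, None, KNN, folds)
        b = igis_plus(data, None, KNN, folds)
        assert a.selected == b.selected
        assert a.stop_reason == b.stop_reason
        assert a.wrapper_evaluations == b.wrapper_evaluations


class TestIgisOriginal:
    def test_perfect_gene_small_subset(self):
        # imbalanced classes keep the separating gene's three-state view
        # informative, so it also maximizes mutual information
        rng = np.random.default_rng(0)
        labels = np.array([0] * 8 + [1] * 16)
        values = rng.standard_normal((24, 7))
        values[:, 0] = labels * 10.0 + rng.normal(0, 0.1, 24)
        data = LabeledExpressionMatrix(
            values, [f"g{i}" for i in range(7)], labels
        )
        folds = make_folds(data.labels, 4, seed=0)
        res = igis_original(data, None, KNN, folds)
        assert res.selected[0] == 0
        # candidates cannot improve on perfection: nothing else accepted
        assert res.selected == [0]

    def test_identical_accuracies_accept_nothing(self, rng):
        # every gene a duplicate: all paired differences are zero -> p = 0.5
        labels = np.repeat([0, 1], 12)
        g0 = labels * 1.0 + rng.normal(0, 0.8, 24)
        data = LabeledExpressionMatrix(
            np.column_stack([g0] * 4), [f"g{i}" for i in range(4)], labels
        )
        folds = make_folds(labels, 4, seed=0)
        res = igis_original(data, None, KNN, folds)
        assert res.selected == [0]
        assert res.stop_reason == "exhausted_all_genes"

    def test_early_stop_contrast_with_improved_algorithm(self):
        data, folds = early_stop_fixture()
        orig = igis_original(data, None, KNN, folds)
        plus = igis_plus(data, None, KNN, folds)
        assert orig.stop_reason == "igis_early_stop"
        assert plus.stop_reason != "igis_early_stop"
        assert plus.wrapper_evaluations > orig.wrapper_evaluations


class TestChooseBestPrefix:
    @staticmethod
    def _result_from_val_means(means):
        steps = [
            StepRecord(
                gene=i,
                gene_id=f"g{i}",
                score=None,
                train_acc=np.full(4, m),
                val_acc=np.full(4, m),
                accepted=True,
                reason="accepted",
            )
            for i, m in enumerate(means)
        ]
        return SelectionResult(
            selected=list(range(len(means))),
            step_log=steps,
            stop_reason="exhausted_all_genes",
            wrapper_evaluations=len(means),
            best_train_acc=steps[-1].train_acc,
            best_val_acc=steps[-1].val_acc,
        )

    def test_interior_maximum(self):
        res = self._result_from_val_means([0.8, 0.9, 0.85])
        assert choose_best_prefix(res) == [0, 1]

    def test_monotone_increasing_keeps_all(self):
        res = self._result_from_val_means([0.7, 0.8, 0.9])
        assert choose_best_prefix(res) == [0, 1, 2]

    def test_tie_prefers_fewer_genes(self):
        res = self._result_from_val_means([0.7, 0.9, 0.9])
        assert choose_best_prefix(res) == [0, 1]
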