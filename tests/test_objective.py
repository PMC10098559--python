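"""Wrapper cost: binarization, splits, deterministic k-NN, exhaustive oracle."""

import itertools

import numpy as np
import pytest

import nirselect as ns
from nirselect.exceptions import ParameterError, SplitError
from nirselect.objective import (
    CostEvaluator,
    CostSpec,
    FeatureMask,
    SplitFixture,
    binarize,
    evaluate_cost,
    exhaustive_oracle,
    knn_accuracy,
    make_split,
    wrapper_cost,
)


def _table(values, labels):
    values = np.asarray(values, dtype=float)
    return ns.FeatureTable(values, list(labels),
                           [(f"F{i}", "x") for i in range(values.shape[1])])


class TestBinarize:
    def test_all_above_threshold(self):
        assert binarize(np.full(4, 0.7)).bits == (1, 1, 1, 1)

    def test_all_below_threshold_empty(self):
        m = binarize(np.full(4, 0.3))
        assert m.n_selected == 0

    def test_tie_excluded_by_strict_inequality(self):
        assert binarize(np.array([0.2, 0.9, 0.5])).bits == (0, 1, 0)


class TestMakeSplit:
    def test_stratified_counts_two_class(self, separable_table):
        split = make_split(separable_table, CostSpec())
        assert len(split.test_indices) == 8  # 0.2 of 40
        y = np.asarray(separable_table.labels)
        assert sum(y[list(split.test_indices)] == "A") == 4

    def test_stratified_counts_four_class(self):
        rng = np.random.default_rng(0)
        tab = _table(rng.normal(size=(60, 3)),
                     [c for c in "ABCD" for _ in range(15)])
        split = make_split(tab, CostSpec())
        assert len(split.test_indices) == 12
        y = np.asarray(tab.labels)
        for c in "ABCD":
            assert sum(y[list(split.test_indices)] == c) == 3

    def test_deterministic_and_disjoint(self, separable_table):
        s1 = make_split(separable_table, CostSpec(), seed=9)
        s2 = make_split(separable_table, CostSpec(), seed=9)
        assert s1 == s2
        assert not set(s1.train_indices) & set(s1.test_indices)
        assert len(s1.train_indices) + len(s1.test_indices) == 40

    def test_small_class_rejected(self):
        tab = _table(np.random.default_rng(0).normal(size=(5, 2)),
                     ["A", "A", "A", "A", "B"])
        with pytest.raises(SplitError):
            make_split(tab, CostSpec())


class TestKnnAccuracy:
    def test_separable_classes_classified_perfectly(self, separable_table):
        split = make_split(separable_table, CostSpec())
        mask = FeatureMask.from_indices([0], separable_table.n_features)
        assert knn_accuracy(separable_table, mask, split, k=5) == 1.0

    def test_k1_duplicate_returns_training_label(self):
        values = [[0.0], [1.0], [2.0], [3.0], [0.0], [3.0]]
        tab = _table(values, ["A", "A", "B", "B", "A", "B"])
        split = SplitFixture(train_indices=(0, 1, 2, 3), test_indices=(4, 5))
        mask = FeatureMask.all_ones(1)
        assert knn_accuracy(tab, mask, split, k=1) == 1.0

    def test_three_nn_matches_brute_force_on_toy_set(self):
        # 6 training points in 2-D plus a borderline test point; compare the
        # vote to exhaustive enumeration of all pairwise distances
        train = np.array([[0.0, 0.0], [0.1, 0.4], [0.3, 0.1],
                          [1.0, 1.0], [0.9, 0.7], [0.6, 0.95]])
        test = np.array([[0.5, 0.5]])
        y = ["A", "A", "A", "B", "B", "B"]
        tab = _table(np.vstack([train, test]), y + ["A"])
        split = SplitFixture(train_indices=tuple(range(6)), test_indices=(6,))
        # brute-force oracle
        d = np.sqrt(((train - test) ** 2).sum(axis=1))
        nearest3 = np.argsort(d, kind="stable")[:3]
        votes = [y[i] for i in nearest3]
        expected = max(sorted(set(votes)), key=votes.count)
        acc = knn_accuracy(tab, FeatureMask.all_ones(2), split, k=3)
        assert acc == (1.0 if expected == "A" else 0.0)

    def test_k_exceeding_train_size_rejected(self, separable_table):
        split = make_split(separable_table, CostSpec())
        with pytest.raises(ParameterError):
            CostEvaluator(separable_table, split, CostSpec(k=100))

    def test_agrees_with_sklearn_on_tie_free_data(self):
        sklearn = pytest.importorskip("sklearn.neighbors")
        rng = np.random.default_rng(8)
        values = rng.normal(size=(30, 4))
        labels = ["A"] * 15 + ["B"] * 15
        values[:15, 0] += 1.5
        tab = _table(values, labels)
        split = make_split(tab, CostSpec(), seed=1)
        mask = FeatureMask.all_ones(4)
        mine = knn_accuracy(tab, mask, split, k=5)
        clf = sklearn.KNeighborsClassifier(n_neighbors=5)
        tr, te = list(split.train_indices), list(split.test_indices)
        clf.fit(values[tr], np.asarray(labels)[tr])
        ref = clf.score(values[te], np.asarray(labels)[te])
        assert mine == pytest.approx(ref)


class TestEvaluateCost:
    def test_perfect_accuracy_full_mask(self, separable_table):
        split = make_split(separable_table, CostSpec())
        j, acc, n_sel = evaluate_cost(FeatureMask.all_ones(8),
                                      separable_table, split, CostSpec())
        assert acc == 1.0
        assert j == pytest.approx(0.01)
        assert n_sel == 8

    def test_printed_full_feature_cost_arithmetic(self):
        # the reported subject-one full-feature accuracy of 91.67% with all
        # 180 features gives J = 0.99 * 0.0833 + 0.01
        j = wrapper_cost(0.9167, 180, 180)
        assert j == pytest.approx(0.99 * (1 - 0.9167) + 0.01, abs=1e-12)
        assert j == pytest.approx(0.0925, abs=5e-4)

    def test_empty_mask_policy_cost(self, separable_table):
        split = make_split(separable_table, CostSpec())
        j, acc, n_sel = evaluate_cost(FeatureMask(bits=(0,) * 8),
                                      separable_table, split, CostSpec())
        assert (j, acc, n_sel) == (1.0, 0.0, 0)

    def test_strictly_increasing_in_subset_size(self):
        for n in range(1, 180):
            assert wrapper_cost(0.9, n + 1, 180) > wrapper_cost(0.9, n, 180)

    def test_non_increasing_in_accuracy(self):
        assert wrapper_cost(0.9, 10, 180) < wrapper_cost(0.8, 10, 180)

    def test_pure_function_bitwise_repeatable(self, separable_table):
        split = make_split(separable_table, CostSpec())
        mask = FeatureMask.from_indices([0, 3, 5], 8)
        results = {evaluate_cost(mask, separable_table, split, CostSpec())
                   for _ in range(5)}
        assert len(results) == 1


class TestExhaustiveOracle:
    def test_enumerates_all_nonempty_masks_d3(self):
        rng = np.random.default_rng(2)
        tab = _table(rng.normal(size=(12, 3)), ["A"] * 6 + ["B"] * 6)
        split = make_split(tab, CostSpec(k=3), seed=0)
        spec = CostSpec(k=3)
        best_mask, best_j = exhaustive_oracle(tab, split, spec)
        # independent enumeration
        evaluator = CostEvaluator(tab, split, spec)
        seen = []
        for bits in itertools.product((0, 1), repeat=3):
            if any(bits):
                j, _, n = evaluator.cost(FeatureMask(bits=bits))
                seen.append((j, n, bits))
        assert len(seen) == 7
        assert min(seen) == (best_j, best_mask.n_selected, best_mask.bits)

    def test_single_perfect_feature_wins_by_size(self, separable_table):
        split = make_split(separable_table, CostSpec())
        best_mask, best_j = exhaustive_oracle(separable_table, split, CostSpec())
        assert best_mask.bits == (1, 0, 0, 0, 0, 0, 0, 0)
        assert best_j == pytest.approx(0.01 / 8)

    def test_equal_cost_tie_breaks_lexicographically(self):
        rng = np.random.default_rng(3)
        col = rng.normal(size=(20, 1))
        col[:10] += 4.0
        noise = rng.normal(size=(20, 1)) * 1e-3
        # columns 1 and 2 identical -> identical costs for {1} and {2}
        values = np.hstack([noise, col, col])
        tab = _table(values, ["A"] * 10 + ["B"] * 10)
        split = make_split(tab, CostSpec(), seed=0)
        best_mask, _ = exhaustive_oracle(tab, split, CostSpec())
        # (0,0,1) precedes (0,1,0) in bit-tuple lexicographic order
        assert best_mask.bits == (0, 0, 1)

    def test_combinatorial_guard(self):
        tab = _table(np.random.default_rng(0).normal(size=(10, 13)),
                     ["A"] * 5 + ["B"] * 5)
        split = make_split(tab, CostSpec(k=3), seed=0)
        with pytest.raises(ParameterError):
            exhaustive_oracle(tab, split, CostSpec(k=3))
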