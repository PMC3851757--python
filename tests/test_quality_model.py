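import hashlib
import json
from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ephysqc.quality_model import (
    CVResult,
    SVMConfig,
    WrapperResult,
    canonical_name,
    cross_dataset_eval,
    enumerate_feature_sets,
    loo_cv,
    merge_classes,
    model_from_dict,
    model_to_dict,
    prediction_correlation,
    repeated_kfold_cv,
    standardize,
    subset_rank,
    top10_group,
    train_svm,
    two_fold_loo,
    vote_predict,
    wrapper_search,
)

FAST = SVMConfig(C=8.0, max_iter=2000)  # desk-scale test config


def blobs(n_per_class, centers, spread=0.5, seed=0, n_features=None):
    """Well-separated Gaussian blobs; labels are -1/0/+1 style codes."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for label, center in centers.items():
        c = np.asarray(center, dtype=float)
        if n_features is not None and c.size < n_features:
            c = np.concatenate([c, np.zeros(n_features - c.size)])
        X.append(c + spread * rng.standard_normal((n_per_class, c.size)))
        y.extend([label] * n_per_class)
    X = np.vstack(X)
    y = np.asarray(y)
    perm = rng.permutation(len(y))
    return X[perm], y[perm]


class TestStandardize:
    def test_basic_column(self):
        X = np.array([[1.0], [2.0], [3.0]])
        s = standardize(X)
        Z = s.apply(X)
        assert np.mean(Z) == pytest.approx(0.0)
        assert np.std(Z) == pytest.approx(1.0)  # population convention

    def test_constant_column_passthrough(self):
        X = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        s = standardize(X)
        Z = s.apply(X)
        assert np.allclose(Z[:, 0], 0.0)
        assert s.scale[0] == 1.0

    def test_fit_apply_consistency(self):
        rng = np.random.default_rng(0)
        X = rng.normal(3, 2, size=(50, 4))
        Z = standardize(X).apply(X)
        assert np.allclose(Z.mean(axis=0), 0.0)
        assert np.allclose(Z.std(axis=0), 1.0)


class TestSubsets:
    def test_total_enumeration(self):
        assert sum(1 for _ in enumerate_feature_sets(16)) == 65535

    def test_size_counts(self):
        for size in (1, 6, 16):
            n = sum(1 for _ in enumerate_feature_sets(16, [size]))
            assert n == comb(16, size)

    def test_rank_matches_enumeration_order(self):
        for size in (1, 2, 3):
            for rank, fs in enumerate(combinations(range(6), size)):
                assert subset_rank(fs, 6) == rank

    def test_canonical_name(self):
        assert canonical_name((0,), 16) == "1-0"
        assert canonical_name(tuple(range(16)), 16) == "16-0"
        last6 = tuple(range(10, 16))
        assert canonical_name(last6, 16) == f"6-{comb(16, 6) - 1}"


class TestTrainPredict:
    def test_separable_blobs_perfect_training(self):
        X, y = blobs(30, {-1: [0, 0], 1: [5, 5]})
        model = train_svm(X, y, FAST)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_three_class_separable(self):
        X, y = blobs(25, {-1: [0, 0, 0], 0: [6, 0, 0], 1: [0, 6, 0]})
        model = train_svm(X, y, FAST)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_single_class_constant_model(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        model = train_svm(X, np.ones(10), FAST)
        assert np.all(model.predict(X) == 1)

    def test_feature_subset_used(self):
        # only feature 2 is informative; training on it alone succeeds
        X, y = blobs(30, {-1: [0], 1: [6]})
        Xfull = np.hstack([np.random.default_rng(1).normal(size=(60, 2)), X])
        model = train_svm(Xfull, y, FAST, feature_set=(2,))
        assert np.mean(model.predict(Xfull) == y) == 1.0

    def test_model_json_roundtrip(self):
        X, y = blobs(20, {-1: [0, 0], 0: [5, 0], 1: [0, 5]})
        model = train_svm(X, y, FAST)
        d = json.loads(json.dumps(model_to_dict(model)))
        back = model_from_dict(d)
        assert np.array_equal(back.predict(X), model.predict(X))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SVMConfig(C=0)
        with pytest.raises(ValueError):
            SVMConfig(max_iter=0)


class TestRepeatedKFold:
    def test_separable_perfect(self):
        X, y = blobs(20, {-1: [0, 0], 1: [6, 6]})
        res = repeated_kfold_cv(X, y, k=10, repeats=3, config=FAST, seed=0)
        assert res.mean == 1.0

    def test_permutation_null_near_chance(self):
        rng = np.random.default_rng(10)
        n = 120
        X = rng.standard_normal((n, 4))
        y = np.repeat([-1, 1], n // 2)
        y = y[rng.permutation(n)]  # labels independent of features
        res = repeated_kfold_cv(X, y, k=10, repeats=5, config=FAST, seed=3)
        assert abs(res.mean - 0.5) <= 0.05  # proportional chance for 60/60

    def test_seed_determinism(self):
        X, y = blobs(15, {-1: [0, 0], 1: [2, 2]}, spread=1.5)
        a = repeated_kfold_cv(X, y, k=5, repeats=4, config=FAST, seed=9)
        b = repeated_kfold_cv(X, y, k=5, repeats=4, config=FAST, seed=9)
        assert np.array_equal(a.fraction_correct, b.fraction_correct)

    def test_n_smaller_than_k_errors(self):
        X, y = blobs(3, {-1: [0], 1: [5]})
        with pytest.raises(ValueError):
            repeated_kfold_cv(X, y, k=10, repeats=1, config=FAST)

    def test_predictions_returned(self):
        X, y = blobs(20, {-1: [0, 0], 1: [6, 6]})
        res, preds = repeated_kfold_cv(X, y, k=5, repeats=2, config=FAST,
                                       seed=1, return_predictions=True)
        assert preds.shape == (2, 40)
        assert np.mean(preds == y) == res.mean


class TestTop10Group:
    @staticmethod
    def _dummy(size, n, seed=0):
        rng = np.random.default_rng(seed)
        pool = list(combinations(range(16), size))[:n]
        assert len(pool) == n
        return [CVResult(fs, rng.uniform(0.4, 0.9, size=3)) for fs in pool]

    def test_large_pool_gives_10(self):
        assert len(top10_group(self._dummy(6, 8008), 16)) == 10

    def test_n16_gives_1(self):
        assert len(top10_group(self._dummy(1, 16), 16)) == 1

    def test_n120_gives_10(self):
        assert len(top10_group(self._dummy(2, 120), 16)) == 10

    def test_n35_gives_3(self):
        assert len(top10_group(self._dummy(3, 35), 16)) == 3

    def test_ordering_and_tiebreak(self):
        # 30 tied results except one clear winner: m = 3, ties break by
        # lexicographic rank
        pool = list(combinations(range(16), 2))[:30]
        results = [CVResult(fs, np.array([0.9 if i == 5 else 0.8]))
                   for i, fs in enumerate(pool)]
        top = top10_group(results, 16)
        assert [r.feature_set for r in top] == [pool[5], pool[0], pool[1]]


class _Fixed:
    def __init__(self, label):
        self.label = label

    def predict(self, X):
        return np.full(len(X), self.label)


class TestVotePredict:
    def test_identical_members(self):
        models = [_Fixed(1)] * 10
        assert vote_predict(models, np.zeros((3, 2))).tolist() == [1, 1, 1]

    def test_strict_majority(self):
        models = [_Fixed(1)] * 6 + [_Fixed(-1)] * 4
        assert vote_predict(models, np.zeros((1, 2)))[0] == 1

    def test_tie_goes_to_best_ranked_member(self):
        models = [_Fixed(1)] * 5 + [_Fixed(-1)] * 5  # best-ranked first
        assert vote_predict(models, np.zeros((1, 2)))[0] == 1
        models = [_Fixed(-1)] * 5 + [_Fixed(1)] * 5
        assert vote_predict(models, np.zeros((1, 2)))[0] == -1

    def test_empty_ensemble(self):
        with pytest.raises(ValueError):
            vote_predict([], np.zeros((1, 2)))


@pytest.fixture(scope="module")
def tiny_result():
    X, y = blobs(12, {-1: [0, 0, 0], 1: [4, 4, 0]}, n_features=5, seed=2)
    return wrapper_search(X, y, config=FAST, seed=1, repeats=2, k=4)


class TestWrapperSearch:
    def test_subset_counts_per_size(self, tiny_result):
        for size, results in tiny_result.results.items():
            assert len(results) == comb(5, size)
        total = sum(len(r) for r in tiny_result.results.values())
        assert total == 2**5 - 1

    def test_ordering_invariants(self, tiny_result):
        for size in tiny_result.results:
            worst = tiny_result.worst(size).mean
            best = tiny_result.best(size).mean
            assert worst <= tiny_result.median_score(size) <= best
            assert tiny_result.top10_mean(size) <= best

    def test_determinism(self):
        X, y = blobs(10, {-1: [0, 0], 1: [3, 3]}, spread=1.0, seed=4)
        a = wrapper_search(X, y, sizes=[1, 2], config=FAST, seed=7, repeats=2, k=5)
        b = wrapper_search(X, y, sizes=[1, 2], config=FAST, seed=7, repeats=2, k=5)
        assert a.to_dict() == b.to_dict()

    def test_json_roundtrip(self, tiny_result):
        d = json.loads(json.dumps(tiny_result.to_dict()))
        back = WrapperResult.from_dict(d)
        assert back.to_dict() == tiny_result.to_dict()
        assert back.best(2).feature_set == tiny_result.best(2).feature_set

    def test_planted_informative_features_dominate_top10(self):
        # 3 informative + 3 noise features; top10 of size 3 prefers the triple
        rng = np.random.default_rng(6)
        n = 60
        y = np.repeat([-1, 1], n // 2)
        X = rng.standard_normal((n, 10))  # C(10, 3) = 120 subsets -> m = 10
        X[:, :3] += y[:, None] * 1.5
        wr = wrapper_search(X, y, sizes=[3], config=FAST, seed=2, repeats=2, k=5)
        counts = np.zeros(10)
        for res in wr.top10(3):
            for f in res.feature_set:
                counts[f] += 1
        assert min(counts[:3]) > max(counts[3:])


class TestTwoFoldLoo:
    def test_separable_all_correct(self):
        # every single feature separates all three classes, so each selected
        # subset is itself perfect
        X, y = blobs(10, {-1: [0, 0, 0], 0: [6, 6, 6], 1: [12, 12, 12]}, seed=8)
        res = two_fold_loo(X, y, config=FAST, sizes=[1, 2], m=3)
        assert res["vote_accuracy"] == 1.0
        assert np.all(res["consistency"] == 1.0)

    def test_determinism(self):
        X, y = blobs(6, {-1: [0, 0], 1: [3, 3]}, spread=1.2, seed=3)
        a = two_fold_loo(X, y, config=FAST, sizes=[1], m=2)
        b = two_fold_loo(X, y, config=FAST, sizes=[1], m=2)
        assert np.array_equal(a["vote_predictions"], b["vote_predictions"])
        assert np.array_equal(a["consistency"], b["consistency"])

    def test_held_out_never_in_training(self):
        X, y = blobs(6, {-1: [0, 0], 1: [4, 4]}, seed=5)
        res = two_fold_loo(X, y, config=FAST, sizes=[1], m=1)
        n = len(y)
        for i, checksum in enumerate(res["train_checksums"]):
            expected = hashlib.sha256(
                np.array([j for j in range(n) if j != i]).tobytes()
            ).hexdigest()
            assert checksum == expected

    def test_per_size_mode(self):
        X, y = blobs(8, {-1: [0, 0], 1: [4, 4]}, seed=5)
        res = two_fold_loo(X, y, config=FAST, sizes=[1, 2], m=10, mode="per_size")
        assert res["vote_accuracy"] == 1.0

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            two_fold_loo(np.zeros((2, 3)), np.array([1, -1]))


class TestCrossDataset:
    def test_test_equals_train_separable(self):
        X, y = blobs(12, {-1: [0, 0, 0], 1: [5, 5, 0]}, seed=6)
        wr = wrapper_search(X, y, sizes=[1, 2], config=FAST, seed=0, repeats=2, k=4)
        table = cross_dataset_eval(X, y, X, y, wr, config=FAST)
        assert np.allclose(table["best_across"], 1.0)
        assert np.allclose(table["top10_voting"], 1.0)

    def test_iid_generalisation(self):
        X1, y1 = blobs(25, {-1: [0, 0], 1: [3, 3]}, spread=1.0, seed=11)
        X2, y2 = blobs(25, {-1: [0, 0], 1: [3, 3]}, spread=1.0, seed=12)
        wr = wrapper_search(X1, y1, sizes=[1, 2], config=FAST, seed=0,
                            repeats=2, k=5)
        table = cross_dataset_eval(X1, y1, X2, y2, wr, config=FAST)
        for size in table.index:
            assert abs(table.loc[size, "best_across"]
                       - table.loc[size, "best_within"]) <= 0.10

    def test_permuted_test_labels_near_chance(self):
        X1, y1 = blobs(25, {-1: [0, 0], 1: [4, 4]}, seed=13)
        X2, y2 = blobs(25, {-1: [0, 0], 1: [4, 4]}, seed=14)
        rng = np.random.default_rng(15)
        y2 = y2[rng.permutation(len(y2))]
        wr = wrapper_search(X1, y1, sizes=[2], config=FAST, seed=0, repeats=2, k=5)
        table = cross_dataset_eval(X1, y1, X2, y2, wr, config=FAST)
        assert abs(table.loc[2, "best_across"] - 0.5) <= 0.15

    def test_schema_mismatch_errors(self):
        X, y = blobs(10, {-1: [0, 0], 1: [4, 4]})
        wr = wrapper_search(X, y, sizes=[1], config=FAST, seed=0, repeats=1, k=5)
        with pytest.raises(ValueError, match="schema"):
            cross_dataset_eval(X, y, X[:, :1], y, wr, config=FAST)


class TestMergeAndCorrelation:
    def test_merge_rule(self):
        assert merge_classes(np.array([-1, 0, 1])).tolist() == [-1, -1, 1]

    def test_all_good_unchanged(self):
        assert merge_classes(np.ones(4)).tolist() == [1, 1, 1, 1]

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.sampled_from([-1, 0, 1]),
                              st.sampled_from([-1, 0, 1])),
                    min_size=1, max_size=20))
    def test_merged_accuracy_never_lower(self, pairs):
        y = np.array([p[0] for p in pairs])
        pred = np.array([p[1] for p in pairs])
        acc3 = np.mean(pred == y)
        acc2 = np.mean(merge_classes(pred) == merge_classes(y))
        assert acc2 >= acc3

    def test_identical_vectors(self):
        assert prediction_correlation([1, 0, -1], [1, 0, -1]) == pytest.approx(1.0)

    def test_exact_negation(self):
        assert prediction_correlation([-1, 0, 1, -1], [1, 0, -1, 1]) == pytest.approx(-1.0)

    def test_hand_built_oracle(self):
        a = np.array([-1.0, 0, 1, 1, -1, 0])
        b = np.array([0.0, 0, 1, -1, -1, 1])
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        oracle = cov / (a.std() * b.std())
        assert prediction_correlation(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_nan(self):
        assert np.isnan(prediction_correlation([1, 1, 1], [1, 0, -1]))


def test_loo_cv_deterministic_and_exhaustive():
    X, y = blobs(6, {-1: [0, 0], 1: [5, 5]}, seed=2)
    a = loo_cv(X, y, config=FAST)
    b = loo_cv(X, y, config=FAST)
    assert a.mean == b.mean == 1.0
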