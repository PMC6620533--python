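import numpy as np
import pytest

from neurofuse.local_classification import (
    evaluate_local_grid,
    knn_local_classifier,
    local_probability_matrices,
    rank_features,
)


def _brute_force_knn(train, labels, query, k):
    """Independent exhaustive-sort oracle for scalar KNN probability."""
    order = sorted(range(len(train)), key=lambda s: (abs(train[s] - query), s))
    return sum(labels[s] for s in order[:k]) / k


class TestScalarKNN:
    def test_single_neighbour(self):
        prob = knn_local_classifier([0.0, 10.0], ["ASD", "TD"], 0.1, k=1)
        assert prob == 1.0

    def test_counting_at_k7(self):
        train = np.arange(10.0)
        labels = ["ASD"] * 4 + ["TD"] * 6
        # query at 3.0: neighbours 3,2,4,1,5,0,6 -> ASD members {3,2,1,0} = 4 of 7
        prob = knn_local_classifier(train, labels, 3.0, k=7)
        assert prob == pytest.approx(4 / 7)

    def test_k_larger_than_train_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            knn_local_classifier([1.0, 2.0], ["ASD", "TD"], 1.5, k=3)

    def test_matches_brute_force_oracle(self, rng):
        train = rng.normal(size=50)
        y = rng.integers(0, 2, 50)
        for q in rng.normal(size=20):
            expected = _brute_force_knn(train, y, q, 7)
            assert knn_local_classifier(train, y, q, k=7) == pytest.approx(
                expected, abs=1e-12
            )

    def test_probabilities_are_multiples_of_one_over_k(self, rng):
        train = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        for k in (1, 3, 7):
            for q in rng.normal(size=10):
                p = knn_local_classifier(train, y, q, k=k)
                assert (p * k) == pytest.approx(round(p * k))


class TestLocalGrid:
    def test_perfectly_separating_feature(self):
        y = np.repeat([1, 0], 20)
        x = np.where(y == 1, 10.0, -10.0) + np.random.default_rng(0).normal(
            scale=0.1, size=40
        )
        res = evaluate_local_grid(x[:, None], y, seed=0)
        assert res.accuracy[0] == 1.0

    def test_noise_feature_near_chance(self):
        rng = np.random.default_rng(1)
        y = np.repeat([1, 0], 100)
        x = rng.normal(size=(200, 30))
        res = evaluate_local_grid(x, y, seed=1)
        assert np.all(res.accuracy >= 0.3) and np.all(res.accuracy <= 0.7)
        assert 0.35 <= res.accuracy.mean() <= 0.65

    def test_duplicate_columns_get_identical_results(self, rng):
        y = np.repeat([1, 0], 15)
        col = rng.normal(size=30)
        x = np.column_stack([col, rng.normal(size=30), col])
        res = evaluate_local_grid(x, y, seed=3)
        assert res.accuracy[0] == res.accuracy[2]
        np.testing.assert_array_equal(res.probability[:, 0], res.probability[:, 2])

    def test_out_of_fold_matches_scalar_oracle(self, rng):
        """Grid probabilities equal per-fold brute-force scalar KNN."""
        from sklearn.model_selection import StratifiedKFold

        y = np.repeat([1, 0], 20)
        x = rng.normal(size=(40, 5))
        res = evaluate_local_grid(x, y, n_folds=4, k=7, seed=9)
        skf = StratifiedKFold(n_splits=4, shuffle=True, random_state=9)
        for tr, te in skf.split(x, y):
            for f in range(5):
                for s in te:
                    expected = _brute_force_knn(x[tr, f], y[tr], x[s, f], 7)
                    assert res.probability[s, f] == pytest.approx(expected, abs=1e-12)

    def test_grid_probabilities_multiples_of_one_over_k(self, rng):
        y = np.repeat([1, 0], 20)
        x = rng.normal(size=(40, 12))
        res = evaluate_local_grid(x, y, k=7, seed=2)
        np.testing.assert_allclose(
            res.probability * 7, np.rint(res.probability * 7), atol=1e-9
        )

    def test_positive_affine_rescaling_leaves_results_unchanged(self, rng):
        # absolute distances scale uniformly under x -> a·x + b (a > 0),
        # so every neighbour set — hence every probability — is preserved
        y = np.repeat([1, 0], 25)
        x = rng.normal(size=(50, 20))
        res0 = evaluate_local_grid(x, y, seed=4)
        res1 = evaluate_local_grid(x * 3.0 + 5.0, y, seed=4)
        np.testing.assert_array_equal(res0.accuracy, res1.accuracy)
        np.testing.assert_array_equal(res0.probability, res1.probability)

    def test_label_permutation_concentrates_at_majority_rate(self):
        rng = np.random.default_rng(11)
        y = np.concatenate([np.ones(60, int), np.zeros(140, int)])
        accs = []
        for rep in range(5):
            x = rng.normal(size=(200, 50))
            yp = rng.permutation(y)
            res = evaluate_local_grid(x, yp, seed=rep)
            accs.append(res.accuracy.mean())
        # majority class rate = 0.70
        assert abs(np.mean(accs) - 0.70) < 0.08

    def test_resubstitution_mode_runs(self, rng):
        y = np.repeat([1, 0], 10)
        x = rng.normal(size=(20, 4))
        res = evaluate_local_grid(x, y, seed=0, resubstitution=True)
        assert res.probability.shape == (20, 4)


class TestRanking:
    def test_tie_breaking_by_index(self):
        from neurofuse.local_classification import LocalGridResult

        acc = np.full(2278, 0.5)
        acc[[0, 5]] = 0.9  # features (1,2) and (1,7)
        acc[100] = 0.7
        res = LocalGridResult(
            accuracy=acc, probability=np.zeros((4, 2278)),
            fold_assignment=np.zeros(4, int), k=7,
        )
        ranked = rank_features(res, "fMRI")
        assert list(ranked.head(2)[["i", "j"]].itertuples(index=False, name=None)) == [
            (1, 2), (1, 7),
        ]
        assert ranked.iloc[2]["accuracy"] == 0.7
        # all-tied tail is in lexicographic (i, j) order
        tail = ranked.iloc[3:10]
        assert (tail["accuracy"] == 0.5).all()
        pairs = list(tail[["i", "j"]].itertuples(index=False, name=None))
        assert pairs == sorted(pairs)

    def test_order_matches_reference_stable_sort(self, rng):
        from neurofuse.local_classification import LocalGridResult

        acc = rng.choice([0.4, 0.5, 0.6, 0.7], size=2278)
        res = LocalGridResult(
            accuracy=acc, probability=np.zeros((2, 2278)),
            fold_assignment=np.zeros(2, int), k=7,
        )
        ranked = rank_features(res, "fMRI")
        from neurofuse.ados_stats import fmri_feature_index

        idx = fmri_feature_index()
        oracle = sorted(
            range(2278), key=lambda c: (-acc[c], idx["f"][c], idx["i"][c], idx["j"][c])
        )
        assert ranked["column"].tolist() == oracle

    def test_probability_matrices_symmetric_with_nan_diagonal(self, rng):
        y = np.repeat([1, 0], 10)
        x = rng.normal(size=(20, 2278))
        res = evaluate_local_grid(x, y, seed=0)
        mats = local_probability_matrices(fmri=res)
        assert mats.P_F.shape == (20, 68, 68)
        np.testing.assert_array_equal(mats.P_F, mats.P_F.transpose(0, 2, 1))
        assert np.isnan(mats.P_F[:, np.arange(68), np.arange(68)]).all()
        assert np.isnan(np.diagonal(mats.acc_F)).all()
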