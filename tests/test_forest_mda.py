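import numpy as np
import pytest

from kmerforest.forest_mda import (
    ForestConfig,
    ForestModel,
    MdaTable,
    _rank_features,
    compute_mda,
    oob_accuracy,
    predict,
    rank_kmers,
    train_forest,
)
from kmerforest.kmer_features import KmerVocabulary

from conftest import dense_to_matrix


def separable_matrix(n=200, n_features=16, seed=0, vocab=None):
    """Feature 5 perfectly predicts the label; the rest is noise counts."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.poisson(2.0, size=(n, n_features)).astype(float)
    X[:, 5] = y * 3.0
    return dense_to_matrix(X, y, vocab or KmerVocabulary(2))


def brute_force_mda(model, X_dense, y, permutation_seed):
    """Independent reimplementation of OOB permutation importance with
    explicit loops, sharing only the per-(seed, tree, feature) RNG
    convention of the contract."""
    n_features = X_dense.shape[1]
    totals = np.zeros(n_features)
    for b, (tree, oob) in enumerate(zip(model.trees, model.oob_indices)):
        if len(oob) == 0:
            continue
        Xo = X_dense[oob].astype(np.float32)
        yo = y[oob]
        correct = sum(
            int(tree.predict(Xo[i : i + 1])[0] == yo[i]) for i in range(len(oob))
        )
        acc_base = correct / len(oob)
        for j in range(n_features):
            rng = np.random.default_rng((permutation_seed, b, j))
            perm = rng.permutation(len(oob))
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            correct_j = sum(
                int(tree.predict(Xp[i : i + 1])[0] == yo[i]) for i in range(len(oob))
            )
            totals[j] += acc_base - correct_j / len(oob)
    return totals / model.n_trees


class TestTraining:
    def test_separable_data_high_oob_accuracy(self):
        matrix = separable_matrix()
        model = train_forest(matrix, ForestConfig(n_trees=50, seed=1))
        assert oob_accuracy(model, matrix) >= 0.95

    def test_bootstrap_and_oob_partition(self):
        matrix = separable_matrix(n=60)
        model = train_forest(matrix, ForestConfig(n_trees=10, seed=2))
        for boot, oob in zip(model.bootstrap_indices, model.oob_indices):
            assert len(boot) == 60  # bootstrap multiset size = training size
            assert len(boot) > len(set(boot))  # repeats essentially certain
            union = set(boot) | set(oob)
            assert union == set(range(60))
            assert set(boot) & set(oob) == set()

    def test_deterministic_given_seed(self):
        matrix = separable_matrix()
        a = train_forest(matrix, ForestConfig(n_trees=20, seed=7))
        b = train_forest(matrix, ForestConfig(n_trees=20, seed=7))
        sa, _ = predict(a, matrix)
        sb, _ = predict(b, matrix)
        assert np.array_equal(sa, sb)
        assert all(
            np.array_equal(x, y)
            for x, y in zip(a.bootstrap_indices, b.bootstrap_indices)
        )

    def test_single_class_labels_error(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(1.0, size=(10, 16)).astype(float)
        matrix = dense_to_matrix(X, np.ones(10, dtype=int), KmerVocabulary(2))
        with pytest.raises(ValueError, match="single class"):
            train_forest(matrix, ForestConfig(n_trees=5, seed=0))

    def test_model_archive_roundtrip(self, tmp_path):
        matrix = separable_matrix(n=40)
        model = train_forest(matrix, ForestConfig(n_trees=5, seed=3))
        model.save(tmp_path / "model.joblib")
        back = ForestModel.load(tmp_path / "model.joblib")
        sa, _ = predict(model, matrix)
        sb, _ = predict(back, matrix)
        assert np.array_equal(sa, sb)


class TestOobAccuracy:
    def test_null_labels_give_chance_accuracy(self):
        accs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            X = rng.poisson(2.0, size=(200, 16)).astype(float)
            y = np.repeat([0, 1], 100)
            matrix = dense_to_matrix(X, y, KmerVocabulary(2))
            model = train_forest(matrix, ForestConfig(n_trees=30, seed=seed))
            accs.append(oob_accuracy(model, matrix))
        assert 0.4 <= np.mean(accs) <= 0.6

    def test_single_tree_oob_fraction_near_1_over_e(self):
        n = 2000
        rng = np.random.default_rng(5)
        X = rng.poisson(1.0, size=(n, 16)).astype(float)
        y = rng.integers(0, 2, n)
        matrix = dense_to_matrix(X, y, KmerVocabulary(2))
        model = train_forest(matrix, ForestConfig(n_trees=1, seed=5))
        n_oob = len(model.oob_indices[0])
        expected = n / np.e
        sd = np.sqrt(n * (1 / np.e) * (1 - 1 / np.e))
        assert abs(n_oob - expected) < 4 * sd

    def test_size_mismatch_error(self):
        matrix = separable_matrix(n=40)
        model = train_forest(matrix, ForestConfig(n_trees=5, seed=1))
        with pytest.raises(ValueError, match="shape"):
            oob_accuracy(model, separable_matrix(n=42))


class TestMda:
    def test_equals_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(11)
        X = rng.poisson(1.5, size=(18, 16)).astype(float)
        y = rng.integers(0, 2, 18)
        y[:3], y[-3:] = 0, 1  # both classes guaranteed
        X[:, 4] = y  # one informative feature
        matrix = dense_to_matrix(X, y, KmerVocabulary(2))
        model = train_forest(matrix, ForestConfig(n_trees=5, seed=13))
        table = compute_mda(model, matrix, permutation_seed=21)
        oracle = brute_force_mda(model, X, y, permutation_seed=21)
        assert np.array_equal(table.scores, oracle)

    def test_constant_feature_scores_exactly_zero(self):
        matrix = separable_matrix(n=50)
        # make feature 9 constant
        for v in matrix.vectors:
            dense = v.dense()
            dense[9] = 1.0
            idx = np.nonzero(dense)[0]
            v.indices, v.values = idx, dense[idx]
        model = train_forest(matrix, ForestConfig(n_trees=10, seed=3))
        table = compute_mda(model, matrix, permutation_seed=1)
        assert table.scores[9] == 0.0

    def test_informative_feature_ranks_first(self):
        matrix = separable_matrix(n=200)
        model = train_forest(matrix, ForestConfig(n_trees=50, seed=1))
        table = compute_mda(model, matrix, permutation_seed=2)
        assert table.ranking[0] == 5

    def test_null_labels_mda_mean_near_zero_and_no_top_feature(self):
        ranks, means = [], []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X = rng.poisson(2.0, size=(120, 16)).astype(float)
            X[:, 5] = rng.poisson(2.0, 120)  # signal destroyed
            y = np.repeat([0, 1], 60)
            matrix = dense_to_matrix(X, y, KmerVocabulary(2))
            model = train_forest(matrix, ForestConfig(n_trees=30, seed=seed))
            table = compute_mda(model, matrix, permutation_seed=seed)
            means.append(table.scores.mean())
            ranks.append(table.rank_of(5))
        assert abs(np.mean(means)) < 0.02
        assert np.median(ranks) > 1.6  # not consistently in the top decile of 16

    def test_feature_subset_and_out_of_range(self):
        matrix = separable_matrix(n=60)
        model = train_forest(matrix, ForestConfig(n_trees=5, seed=4))
        table = compute_mda(model, matrix, features=[5], permutation_seed=9)
        assert (table.scores[np.arange(16) != 5] == 0).all()
        with pytest.raises(IndexError):
            compute_mda(model, matrix, features=[99], permutation_seed=9)

    def test_deterministic_and_thread_invariant(self):
        matrix = separable_matrix(n=100)
        tables = []
        for threads in (1, 3):
            model = train_forest(
                matrix, ForestConfig(n_trees=20, seed=6, n_threads=threads)
            )
            tables.append(compute_mda(model, matrix, permutation_seed=8))
        assert np.array_equal(tables[0].scores, tables[1].scores)
        assert np.array_equal(tables[0].ranking, tables[1].ranking)


class TestScalingInvariance:
    def test_monotone_feature_scaling_preserves_predictions(self):
        matrix = separable_matrix(n=120, seed=9)
        scaled = separable_matrix(n=120, seed=9)
        # power-of-two constant: exact in floating point, so thresholds
        # scale without rounding and the tree structure must be identical
        for v in scaled.vectors:
            v.values = v.values * 4.0
        config = ForestConfig(n_trees=25, seed=12)
        sa, la = predict(train_forest(matrix, config), matrix)
        sb, lb = predict(train_forest(scaled, config), scaled)
        assert np.array_equal(sa, sb)
        assert np.array_equal(la, lb)


class TestPredictAndRanking:
    def test_tie_vote_maps_to_label_zero(self):
        # two single-leaf trees with opposite constant votes
        from sklearn.tree import DecisionTreeClassifier

        X = np.array([[0.0], [1.0]], dtype=np.float32)
        t0 = DecisionTreeClassifier(max_depth=1).fit(X, [0, 0])
        t1 = DecisionTreeClassifier(max_depth=1).fit(X, [1, 1])
        model = ForestModel(
            trees=[t0, t1],
            bootstrap_indices=[np.array([0, 1])] * 2,
            oob_indices=[np.array([], dtype=int)] * 2,
            config=ForestConfig(n_trees=2, seed=0),
            n_features=1,
            n_samples=2,
        )
        score, label = predict(model, np.array([[0.5]]))
        assert score[0] == 0.5 and label[0] == 0

    def test_rank_tie_break_by_ascending_index(self):
        vocab = KmerVocabulary(2)
        scores = np.zeros(16)
        scores[0], scores[1], scores[2] = 0.3, 0.1, 0.3  # AA, AC, AG
        table = MdaTable(scores, _rank_features(scores), np.array([]))
        top = rank_kmers(table, vocab, top=3)
        assert top == [("AA", 0.3, 1), ("AG", 0.3, 2), ("AC", 0.1, 3)]

    def test_all_zero_scores_rank_lexicographically(self):
        vocab = KmerVocabulary(2)
        scores = np.zeros(16)
        table = MdaTable(scores, _rank_features(scores), np.array([]))
        assert [k for k, _, _ in rank_kmers(table, vocab, top=16)] == vocab.all_kmers()

    def test_top_bounds(self):
        vocab = KmerVocabulary(2)
        table = MdaTable(np.zeros(16), _rank_features(np.zeros(16)), np.array([]))
        with pytest.raises(ValueError):
            rank_kmers(table, vocab, top=0)
        with pytest.raises(ValueError):
            rank_kmers(table, vocab, top=17)

    def test_empty_vector_gets_valid_score(self):
        from kmerforest.kmer_features import SparseKmerVector

        matrix = separable_matrix(n=40)
        model = train_forest(matrix, ForestConfig(n_trees=5, seed=2))
        empty = SparseKmerVector(16, np.array([], dtype=int), np.array([]))
        score, label = predict(model, [empty])
        assert 0.0 <= score[0] <= 1.0 and label[0] in (0, 1)

    def test_dimension_mismatch_error(self):
        matrix = separable_matrix(n=40)
        model = train_forest(matrix, ForestConfig(n_trees=5, seed=2))
        with pytest.raises(ValueError, match="dimension"):
            predict(model, np.zeros((2, 7)))
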