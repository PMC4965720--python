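"""Metrics, the ambiguity decomposition, rank tests and experiments."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

import semforest as sf
from semforest.evaluation import _holm, _subseed, _stratified_split


def brute_force_auc(y, scores):
    """Pairwise oracle: mean over all positive-negative pairs."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAccuracy:
    def test_values(self):
        assert sf.accuracy([1, 0, 1], [1, 0, 1]) == 100.0
        assert sf.accuracy([1, 0, 1, 0], [1, 0, 0, 1]) == 50.0

    def test_permutation_invariance(self):
        y = np.array([1, 0, 1, 1, 0])
        p = np.array([1, 1, 0, 1, 0])
        perm = np.array([3, 0, 4, 1, 2])
        assert sf.accuracy(y, p) == sf.accuracy(y[perm], p[perm])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sf.accuracy([], [])


class TestAuc:
    def test_worked_example(self):
        assert sf.auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.2]) == 0.75

    def test_degenerate_scores(self):
        assert sf.auc([1, 0, 1, 0], [0.3, 0.3, 0.3, 0.3]) == 0.5
        assert sf.auc([1, 1, 0], [0.9, 0.8, 0.1]) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sf.auc([1, 1], [0.2, 0.4])

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            # quantized scores so ties actually occur
            scores = np.round(rng.random(n), 1)
            assert sf.auc(y, scores) == pytest.approx(
                brute_force_auc(y, scores), abs=1e-12
            )


class TestAmbiguityDecomposition:
    def test_symmetric_example(self):
        d = sf.ambiguity_decomposition([0.0, 2.0], 1.0)
        assert (d.E, d.A, d.D) == (0.0, 1.0, 1.0)

    def test_identical_predictions(self):
        d = sf.ambiguity_decomposition([0.7, 0.7, 0.7], 0.2)
        assert d.D == pytest.approx(0.0, abs=1e-30)
        assert d.E == pytest.approx(d.A, abs=1e-15)

    def test_identity_on_random_sets(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            preds = rng.normal(size=rng.integers(1, 12))
            target = rng.normal()
            d = sf.ambiguity_decomposition(preds, target)
            assert abs(d.E - (d.A - d.D)) < 1e-10
            assert d.D >= 0.0


class TestEvaluationReport:
    def test_diversity_identity(self):
        rep = sf.EvaluationReport(
            strategy=sf.Strategy.FDR, dataset_name="x",
            fold_accuracy=np.array([88.08]), fold_auc=np.array([0.94]),
            fold_tree_accuracy=np.array([73.22]),
        )
        assert rep.diversity == pytest.approx(0.1486, abs=1e-12)

    def test_single_tree_has_zero_diversity(self, small_dataset, small_grid):
        res = sf.fit_forest(
            small_dataset, small_grid, sf.Strategy.RDR_ALL, n_trees=1, seed=0
        )
        ens, tree, div = sf.inspect_ensemble(
            res, small_dataset.episodes, small_dataset.labels
        )
        assert ens == tree
        assert div == 0.0


class TestFriedman:
    def test_perfect_ordering_hand_value(self):
        # 4 datasets; method 0 always best, method 1 always second
        scores = np.array([[3.0, 2.0, 1.0]] * 4)
        chi2, p = sf.friedman_test(scores)
        assert chi2 == pytest.approx(8.0, abs=1e-12)
        assert 0 < p < 0.05

    def test_identical_methods(self):
        chi2, p = sf.friedman_test(np.ones((5, 3)))
        assert chi2 == 0.0
        assert p == 1.0

    def test_rank_based_monotone_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.random((8, 3))
        chi2_a, _ = sf.friedman_test(X)
        chi2_b, _ = sf.friedman_test(np.exp(5 * X))
        assert chi2_a == pytest.approx(chi2_b, abs=1e-12)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n, k = int(rng.integers(3, 12)), int(rng.integers(3, 6))
            X = rng.normal(size=(n, k))
            chi2, p = sf.friedman_test(X)
            ref_chi2, ref_p = sps.friedmanchisquare(*X.T)
            assert chi2 == pytest.approx(ref_chi2, abs=1e-8)
            assert p == pytest.approx(ref_p, abs=1e-8)


class TestPosthoc:
    def test_two_methods_adjustment_is_identity(self):
        rng = np.random.default_rng(5)
        X = rng.random((6, 2))
        mat = sf.ScoreMatrix(X, methods=["a", "b"])
        adj = sf.posthoc_pairwise(mat)
        ranks = mat.mean_ranks()
        z = (ranks[0] - ranks[1]) / np.sqrt(2 * 3 / (6 * 6))
        raw = 2 * sps.norm.sf(abs(z))
        assert adj[("a", "b")] == pytest.approx(min(1.0, raw), abs=1e-12)

    def test_identical_methods_not_rejected(self):
        adj = sf.posthoc_pairwise(np.ones((5, 3)))
        assert all(p == 1.0 for p in adj.values())

    def test_bergmann_hommel_no_less_powerful_than_holm(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            X = rng.normal(size=(int(rng.integers(3, 10)), 3))
            bh = sf.posthoc_pairwise(X, method="bergmann_hommel")
            holm = sf.posthoc_pairwise(X, method="holm")
            for pair in bh:
                assert bh[pair] <= holm[pair] + 1e-12

    def test_too_many_methods_for_bergmann_hommel(self):
        with pytest.raises(ValueError, match="holm"):
            sf.posthoc_pairwise(np.random.default_rng(0).random((4, 5)))

    def test_holm_monotone_and_capped(self):
        raw = {(0, 1): 0.04, (0, 2): 0.01, (1, 2): 0.9}
        adj = _holm(raw)
        assert adj[(0, 2)] == pytest.approx(0.03)
        assert adj[(0, 1)] == pytest.approx(0.08)
        assert adj[(1, 2)] == pytest.approx(0.9)


class TestCrossValidation:
    def test_fold_structure_and_means(self, small_dataset, small_grid):
        rep = sf.cross_validate(
            small_dataset, small_grid, sf.Strategy.RDR_ALL,
            folds=3, seed=1, n_trees=8,
        )
        assert len(rep.fold_accuracy) == 3
        assert rep.accuracy == pytest.approx(rep.fold_accuracy.mean())
        assert rep.auc == pytest.approx(rep.fold_auc.mean())
        assert rep.diversity == pytest.approx(
            rep.accuracy / 100 - rep.average_tree_accuracy / 100, abs=1e-12
        )
        assert 0 <= rep.accuracy <= 100 and 0 <= rep.auc <= 1

    def test_stratified_folds_are_balanced_partition(self, small_dataset):
        from sklearn.model_selection import StratifiedKFold
        y = small_dataset.labels
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=1)
        seen = []
        for _, te in skf.split(np.zeros(len(y)), y):
            pos = y[te].sum()
            neg = len(te) - pos
            assert abs(pos - neg) <= 1
            seen.extend(te)
        assert sorted(seen) == list(range(len(y)))

    def test_too_many_folds_rejected(self, small_dataset, small_grid):
        with pytest.raises(ValueError, match="folds"):
            sf.cross_validate(
                small_dataset, small_grid, folds=40, n_trees=2
            )


class TestPoolSizeExperiment:
    def test_combination_counts_and_size_one_mean(
        self, small_dataset, small_grid
    ):
        table = sf.pool_size_experiment(
            small_dataset, small_grid, sizes=[1, 2], seed=2, n_trees=6
        )
        P = len(small_grid.windows)
        assert table.loc[1, "n_combinations"] == P
        assert table.loc[2, "n_combinations"] == 1  # C(2, 2)
        # size-1 mean is by definition the mean over single-window runs
        singles = []
        for ci, combo in enumerate(itertools.combinations(small_grid.windows, 1)):
            sub = small_grid.restrict(combo)
            tr, te = _stratified_split(
                len(small_dataset), small_dataset.labels, 0.7,
                _subseed(2, 1, ci),
            )
            res = sf.SemanticForest(
                small_dataset.subset(tr), sub, strategy=sf.Strategy.RDR_ALL,
                n_trees=6, seed=_subseed(2, 1, ci, 1),
            ).fit()
            test = small_dataset.subset(te)
            scores = res.predict_scores(test.episodes)
            singles.append(
                sf.accuracy(test.labels, (scores > 0.5).astype(int))
            )
        assert table.loc[1, "accuracy"] == pytest.approx(np.mean(singles))

    def test_invalid_sizes_rejected(self, small_dataset, small_grid):
        with pytest.raises(ValueError):
            sf.pool_size_experiment(
                small_dataset, small_grid, sizes=[0], n_trees=2
            )


def test_score_matrix_validation():
    with pytest.raises(ValueError, match="missing"):
        sf.ScoreMatrix(np.array([[1.0, np.nan]]), methods=["a", "b"])
    m = sf.ScoreMatrix(np.array([[2.0, 1.0], [1.0, 2.0]]), methods=["a", "b"])
    np.testing.assert_allclose(m.mean_ranks(), [1.5, 1.5])
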