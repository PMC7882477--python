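
import numpy as np
import pytest
from sklearn.base import clone
from sklearn.svm import LinearSVC

from scim.classify import (CVConfig, PerformanceMap, SearchlightDecoder,
                           cv_scores, decision_scores, score_performance,
                           searchlight_map, train_linear_svm)
from scim.io import Mask, TrialSet
from scim.searchlight import SphereSpec, build_index

FAST = dict(outer_folds=4, inner_folds=3, c_grid=[0.01, 1.0, 100.0])


def sqhinge_objective(w, b, X, y, C):
    margins = 1 - y * (X @ w + b)
    return 0.5 * (w @ w + b * b) + C * np.sum(np.maximum(margins, 0) ** 2)


class TestTrainLinearSVM:
    def test_separable_1d(self):
        X = np.array([[1.0], [-1.0]])
        y = np.array([1, -1])
        m = train_linear_svm(X, y, C=1e4)
        assert m.weights[0] > 0
        assert np.all(np.sign(decision_scores(m, X)) == y)

    def test_weight_vanishes_as_c_to_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 5))
        y = np.r_[np.ones(10), -np.ones(10)]
        m = train_linear_svm(X, y, C=1e-8)
        assert np.linalg.norm(m.weights) < 1e-4

    def test_symmetric_two_point_solution(self):
        # symmetry forces the optimum onto the first coordinate
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        y = np.array([1, -1])
        m = train_linear_svm(X, y, C=10.0)
        assert m.weights[0] > 0
        assert abs(m.weights[1]) < 1e-10
        assert abs(m.bias) < 1e-9

    @pytest.mark.parametrize("C", [1e-3, 1e-1, 1.0, 1e2])
    def test_matches_liblinear_oracle(self, C):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 7))
        y = np.r_[np.ones(20), -np.ones(20)]
        rng.shuffle(y)
        X[y == 1, :2] += 0.5
        m = train_linear_svm(X, y, C)
        ref = LinearSVC(penalty="l2", loss="squared_hinge", dual=False, C=C,
                        tol=1e-12, max_iter=200_000).fit(X, y)
        np.testing.assert_allclose(m.weights, ref.coef_.ravel(), atol=2e-6)
        assert m.bias == pytest.approx(ref.intercept_[0], abs=2e-6)

    def test_local_optimality_against_random_perturbations(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(16, 3))
        y = np.r_[np.ones(8), -np.ones(8)]
        C = 2.0
        m = train_linear_svm(X, y, C)
        f0 = sqhinge_objective(m.weights, m.bias, X, y, C)
        for _ in range(1000):
            dw = rng.normal(0, 0.01, size=3)
            db = rng.normal(0, 0.01)
            assert sqhinge_objective(m.weights + dw, m.bias + db, X, y, C) \
                >= f0 - 1e-10

    def test_errors(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="both classes"):
            train_linear_svm(X, [1, 1, 1, 1], 1.0)
        with pytest.raises(ValueError, match="positive"):
            train_linear_svm(X, [1, 1, -1, -1], 0.0)
        X[0, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            train_linear_svm(X, [1, 1, -1, -1], 1.0)


def pairwise_auc_oracle(scores, labels):
    """Brute-force Mann-Whitney count over all positive-negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == -1]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestScorePerformance:
    def test_perfect_ranking(self):
        assert score_performance([0.9, 0.8, 0.2, 0.1], [1, 1, -1, -1]) == 1.0

    def test_interleaved_ranking(self):
        # pairs: .9>.8, .9>.1, .2<.8, .2>.1 -> 3/4
        assert score_performance([0.9, 0.2, 0.8, 0.1], [1, 1, -1, -1]) == 0.75

    def test_all_ties_give_half(self):
        assert score_performance([0.3] * 6, [1, 1, 1, -1, -1, -1]) == 0.5

    def test_auc_equals_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = rng.integers(4, 13)
            labels = np.r_[np.ones(n // 2, int), -np.ones(n - n // 2, int)]
            rng.shuffle(labels)
            scores = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=n)
            if len(np.unique(labels)) < 2:
                continue
            assert score_performance(scores, labels) == pytest.approx(
                pairwise_auc_oracle(scores, labels), abs=1e-12)

    @pytest.mark.parametrize("transform", [np.exp, np.cbrt,
                                           lambda s: 5 * s - 2, np.arctan])
    def test_auc_invariant_under_monotone_transform(self, transform):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=30)
        labels = np.r_[np.ones(15, int), -np.ones(15, int)]
        rng.shuffle(labels)
        assert score_performance(transform(scores), labels) == pytest.approx(
            score_performance(scores, labels), abs=1e-12)

    def test_accuracy_on_grid(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=20)
        labels = np.r_[np.ones(10, int), -np.ones(10, int)]
        acc = score_performance(scores, labels, "accuracy")
        assert acc * 20 == pytest.approx(round(acc * 20))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            score_performance([0.1, 0.2], [1, 1])


class TestCVScores:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 6))
        y = np.r_[np.ones(20, int), -np.ones(20, int)]
        rng.shuffle(y)
        cfg = CVConfig(seed=3, **FAST)
        s1, p1 = cv_scores(X, y, cfg)
        s2, p2 = cv_scores(X, y, cfg)
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_array_equal(p1, p2)

    def test_signal_gives_high_auc(self):
        rng = np.random.default_rng(7)
        y = np.r_[np.ones(40, int), -np.ones(40, int)]
        rng.shuffle(y)
        X = y[:, None] + rng.normal(0, 0.3, size=(80, 4))
        s, _ = cv_scores(X, y, CVConfig(seed=0, **FAST))
        assert score_performance(s, y) > 0.95

    def test_noise_near_chance(self):
        rng = np.random.default_rng(8)
        aucs = []
        for rep in range(8):
            y = np.r_[np.ones(40, int), -np.ones(40, int)]
            rng.shuffle(y)
            X = rng.normal(size=(80, 10))
            s, _ = cv_scores(X, y, CVConfig(seed=rep, **FAST))
            aucs.append(score_performance(s, y))
        assert abs(np.mean(aucs) - 0.5) < 0.06

    def test_every_trial_scored_once(self):
        rng = np.random.default_rng(9)
        y = np.r_[np.ones(12, int), -np.ones(12, int)]
        X = rng.normal(size=(24, 3))
        s, p = cv_scores(X, y, CVConfig(outer_folds=4, inner_folds=2,
                                        c_grid=[1.0], seed=0))
        assert s.shape == (24,) and np.all(np.isfinite(s))
        assert set(np.unique(p)) <= {-1, 1}


class TestSearchlightMap:
    def test_single_searchlight_equals_composition(self):
        rng = np.random.default_rng(10)
        members = np.zeros((3, 3, 3), bool)
        members[1, 1, 1] = True
        mask = Mask(members)
        y = np.r_[np.ones(20, int), -np.ones(20, int)]
        rng.shuffle(y)
        trials = TrialSet(rng.normal(size=(40, 1)), y)
        idx = build_index(mask, SphereSpec(1.0))
        cfg = CVConfig(seed=1, **FAST)
        pm = searchlight_map(trials, idx, cfg)
        s, _ = cv_scores(trials.activations[:, idx.neighborhoods[0]], y, cfg)
        assert pm.values[0] == pytest.approx(score_performance(s, y), abs=1e-12)

    def test_batched_map_equals_per_searchlight_loop(self):
        rng = np.random.default_rng(11)
        mask = Mask(rng.random((4, 4, 3)) > 0.3)
        y = np.r_[np.ones(15, int), -np.ones(15, int)]
        rng.shuffle(y)
        trials = TrialSet(rng.normal(size=(30, mask.n_voxels)), y)
        idx = build_index(mask, SphereSpec(1.5))
        cfg = CVConfig(outer_folds=3, inner_folds=2, c_grid=[0.1, 10.0], seed=2)
        pm = searchlight_map(trials, idx, cfg)
        for k in range(idx.k_total):
            s, _ = cv_scores(trials.activations[:, idx.neighborhoods[k]], y, cfg)
            assert pm.values[k] == pytest.approx(
                score_performance(s, y), abs=1e-10)

    def test_performance_map_validates_range(self):
        with pytest.raises(ValueError):
            PerformanceMap(values=np.array([0.5, 1.2]), measure="auc")


class TestSearchlightDecoder:
    def test_sklearn_protocol(self):
        rng = np.random.default_rng(12)
        members = np.ones((3, 3, 1), bool)
        mask = Mask(members)
        idx = build_index(mask, SphereSpec(1.0))
        est = SearchlightDecoder(index=idx, outer_folds=3, inner_folds=2,
                                 c_grid=[1.0], seed=0)
        cloned = clone(est)  # get_params/set_params round trip
        y = np.r_[np.ones(10, int), -np.ones(10, int)]
        X = rng.normal(size=(20, mask.n_voxels))
        cloned.fit(X, y)
        assert cloned.values_.shape == (idx.k_total,)
        assert cloned.performance_map_.measure == "auc"
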