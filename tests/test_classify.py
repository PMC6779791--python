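"""Linear-SVM classification: margin oracles, CV schemes, permutation test."""

import numpy as np
import pytest
from scipy.optimize import minimize

from dynalff import (extract_cluster_feature, train_linear_classifier,
                     loocv_classify, kfold_classify, roc_auc,
                     label_permutation_test)
from dynalff.classify import _svm1d, _fit_fold


def primal_oracle(x, y, C=1.0):
    """Brute-force primal minimizer of 0.5 w^2 + C sum hinge for 1-D data."""
    s = np.where(y == 1, 1.0, -1.0)

    def f(p):
        w, b = p
        return 0.5 * w * w + C * np.maximum(0, 1 - s * (w * x + b)).sum()

    best = None
    for w0 in (-5.0, -1.0, 0.5, 1.0, 5.0):
        for b0 in (-2.0, 0.0, 2.0):
            r = minimize(f, [w0, b0], method="Nelder-Mead",
                         options=dict(xatol=1e-10, fatol=1e-12, maxiter=5000))
            if best is None or r.fun < best.fun:
                best = r
    return best.x, best.fun


class TestExtractClusterFeature:
    def test_single_voxel_mask(self):
        maps = np.arange(8.0).reshape(2, 2, 2, 1)
        mask = np.zeros((2, 2, 1), bool)
        mask[1, 0, 0] = True
        X = extract_cluster_feature(maps, mask)
        np.testing.assert_array_equal(X.ravel(), maps[:, 1, 0, 0])

    def test_constant_map_gives_constant(self):
        maps = np.full((3, 4, 4, 4), 2.5)
        mask = np.ones((4, 4, 4), bool)
        np.testing.assert_allclose(extract_cluster_feature(maps, mask), 2.5)

    def test_two_voxel_hand_mean(self):
        maps = np.zeros((1, 2, 1, 1))
        maps[0, :, 0, 0] = [0.1, 0.3]
        X = extract_cluster_feature(maps, np.ones((2, 1, 1), bool))
        assert X[0, 0] == pytest.approx(0.2)

    def test_voxelwise_mode(self):
        maps = np.random.default_rng(0).normal(size=(5, 3, 3, 3))
        mask = np.zeros((3, 3, 3), bool)
        mask[0] = True
        X = extract_cluster_feature(maps, mask, voxelwise=True)
        assert X.shape == (5, 9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_cluster_feature(np.ones((2, 2, 2, 2)),
                                    np.zeros((2, 2, 2), bool))


class TestTrainLinearClassifier:
    def test_separable_training_accuracy(self):
        X = np.array([0.1, 0.2, 0.3, 1.1, 1.2, 1.3])[:, None]
        y = np.array([0, 0, 0, 1, 1, 1])
        rule = train_linear_classifier(X, y)
        np.testing.assert_array_equal(rule.predict(X), y)

    def test_label_flip_negates_weights(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 1))
        y = (X.ravel() + 0.3 * rng.normal(size=20) > 0).astype(int)
        r1 = train_linear_classifier(X, y)
        r2 = train_linear_classifier(X, 1 - y)
        assert np.sign(r1.weights[0]) == -np.sign(r2.weights[0])

    def test_hard_margin_midpoint_four_points(self):
        # wide gap: hard-margin boundary lies midway between the two
        # innermost opposite-class points; verified by the brute-force oracle
        x = np.array([-3.0, -2.0, 2.0, 3.0])
        y = np.array([0, 0, 1, 1])
        rule = train_linear_classifier(x[:, None], y)
        boundary = -rule.bias / rule.weights[0]
        assert boundary == pytest.approx(0.0, abs=1e-6)
        xs = (x - x.mean()) / x.std()
        (w, b), _ = primal_oracle(xs, y)
        assert -b / w == pytest.approx(0.0, abs=1e-5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_linear_classifier(np.ones((4, 1)), np.ones(4))


class TestSvm1dSolver:
    def test_matches_svc_reference(self, rng):
        # dual route: KKT enumeration vs libsvm on overlapping random data
        from sklearn.svm import SVC
        for trial in range(50):
            n = int(rng.integers(8, 50))
            y = np.zeros(n, int)
            y[: n // 2] = 1
            x = np.where(y == 1, rng.normal(0.4, 1, n), rng.normal(-0.4, 1, n))
            x = (x - x.mean()) / x.std()
            C = float(rng.choice([0.3, 1.0, 3.0]))
            w, b = _svm1d(x, y, C)
            clf = SVC(kernel="linear", C=C).fit(x[:, None], y)
            s = np.where(y == 1, 1.0, -1.0)

            def obj(w_, b_):
                return 0.5 * w_ * w_ + C * np.maximum(
                    0, 1 - s * (w_ * x + b_)).sum()

            assert obj(w, b) <= obj(float(clf.coef_[0, 0]),
                                    float(clf.intercept_[0])) + 1e-6
            np.testing.assert_array_equal((w * x + b > 0),
                                          clf.predict(x[:, None]) == 1)

    def test_matches_primal_oracle(self, rng):
        for trial in range(10):
            n = 12
            y = np.repeat([1, 0], 6)
            x = np.where(y == 1, rng.normal(0.5, 1, n), rng.normal(-0.5, 1, n))
            x = (x - x.mean()) / x.std()
            w, b = _svm1d(x, y, 1.0)
            (wo, bo), fo = primal_oracle(x, y)
            s = np.where(y == 1, 1.0, -1.0)
            f = 0.5 * w * w + np.maximum(0, 1 - s * (w * x + b)).sum()
            assert f == pytest.approx(fo, abs=1e-5)


LOOCV_HAND_X = np.array([0.10, 0.12, 0.15, 0.16, 0.40, 0.42])
LOOCV_HAND_Y = np.array([0, 0, 0, 1, 1, 1])
# fold-by-fold enumeration with the independent primal solver: the innermost
# patient (0.16) is pulled across the soft-margin boundary when held out
LOOCV_HAND_PRED = [0, 0, 0, 0, 1, 1]


class TestLoocv:
    def test_separable_cohort_perfect_accuracy(self, rng):
        y = np.repeat([1, 0], 28)
        X = np.where(y == 1, rng.normal(5, 0.2, 56),
                     rng.normal(-5, 0.2, 56))[:, None]
        res = loocv_classify(X, y)
        assert res.accuracy == 1.0 and res.auc == 1.0

    def test_hand_instance_matches_manual_enumeration(self):
        res = loocv_classify(LOOCV_HAND_X[:, None], LOOCV_HAND_Y)
        assert res.y_pred.tolist() == LOOCV_HAND_PRED
        assert res.accuracy == pytest.approx(5 / 6)
        # recompute each fold with the independent primal solver
        for i in range(6):
            tr = np.arange(6) != i
            xtr = LOOCV_HAND_X[tr]
            mu, sd = xtr.mean(), xtr.std()
            (w, b), _ = primal_oracle((xtr - mu) / sd, LOOCV_HAND_Y[tr])
            score = w * (LOOCV_HAND_X[i] - mu) / sd + b
            assert int(score > 0) == LOOCV_HAND_PRED[i]

    def test_prediction_invariant_to_subject_order(self, rng):
        y = np.repeat([1, 0], 8)
        X = rng.normal(size=(16, 1)) + y[:, None]
        res = loocv_classify(X, y)
        perm = rng.permutation(16)
        res_p = loocv_classify(X[perm], y[perm])
        np.testing.assert_array_equal(res.y_pred[perm], res_p.y_pred)

    def test_shuffled_labels_no_better_than_chance(self, rng):
        # null LOOCV accuracy sits at or below 0.5: removing a subject tilts
        # the balanced training set against its class, so uninformative
        # features yield the classic pessimistic LOOCV bias
        accs = []
        for _ in range(30):
            X = rng.normal(size=(30, 1))
            y = rng.permutation(np.repeat([1, 0], 15))
            accs.append(loocv_classify(X, y).accuracy)
        assert np.mean(accs) < 0.55

    def test_metric_identity(self, rng):
        y = rng.integers(0, 2, 30)
        y[:3], y[-3:] = 1, 0
        X = rng.normal(size=(30, 1))
        res = loocv_classify(X, y)
        n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
        assert res.accuracy == pytest.approx(
            (res.sensitivity * n_pos + res.specificity * n_neg) / 30)


class TestKfold:
    def test_k_equals_n_reduces_to_loocv(self, rng):
        y = np.repeat([1, 0], 6)
        X = rng.normal(size=(12, 1)) + 0.8 * y[:, None]
        a = loocv_classify(X, y)
        b = kfold_classify(X, y, k=12, seed=3)
        np.testing.assert_array_equal(a.y_pred, b.y_pred)
        np.testing.assert_allclose(a.scores, b.scores)

    def test_seeded_fold_determinism(self, rng):
        y = np.repeat([1, 0], 10)
        X = rng.normal(size=(20, 1))
        a = kfold_classify(X, y, k=5, seed=7)
        b = kfold_classify(X, y, k=5, seed=7)
        np.testing.assert_array_equal(a.y_pred, b.y_pred)
        np.testing.assert_allclose(a.scores, b.scores)

    def test_separable_data_perfect(self, rng):
        y = np.repeat([1, 0], 15)
        X = np.where(y == 1, 4.0, -4.0)[:, None] + rng.normal(0, 0.1, (30, 1))
        assert kfold_classify(X, y, k=10, seed=0).accuracy == 1.0

    def test_small_class_degrades_gracefully(self, rng, caplog):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        X = rng.normal(size=(10, 1)) + y[:, None]
        with caplog.at_level("WARNING"):
            res = kfold_classify(X, y, k=5, seed=0)
        assert "smallest class" in caplog.text
        assert res.y_pred.size == 10


class TestRocAuc:
    def test_perfect_ordering(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_half(self):
        assert roc_auc([1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1]) == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, 12)
            y[0], y[1] = 0, 1
            s = rng.normal(size=12)
            pos, neg = s[y == 1], s[y == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert roc_auc(s, y) == pytest.approx(wins / (pos.size * neg.size))

    def test_one_inversion_hand_case(self):
        # scores 0.9,0.2 for patients, 0.5,0.1 for controls: 3 of 4 pairs won,
        # one lost -> AUC 0.75
        assert roc_auc([0.9, 0.2, 0.5, 0.1], [1, 1, 0, 0]) == 0.75


class TestPermutationTest:
    def test_constant_features_give_p_one(self):
        X = np.ones((12, 1))
        y = np.repeat([1, 0], 6)
        res = label_permutation_test(X, y, n_perm=20, seed=0)
        assert res.p_value == 1.0

    def test_separable_data_minimal_p(self, rng):
        y = np.repeat([1, 0], 14)
        X = np.where(y == 1, 3.0, -3.0)[:, None] + rng.normal(0, 0.2, (28, 1))
        res = label_permutation_test(X, y, n_perm=99, seed=1)
        assert res.observed_accuracy == 1.0
        assert res.p_value == pytest.approx(1 / 100)
        assert res.null_accuracies.size == 99

    def test_p_never_zero_and_bounded(self, rng):
        X = rng.normal(size=(16, 1))
        y = np.repeat([1, 0], 8)
        res = label_permutation_test(X, y, n_perm=30, seed=5)
        assert 0 < res.p_value <= 1.0

    def test_invalid_n_perm_rejected(self):
        with pytest.raises(ValueError):
            label_permutation_test(np.ones((6, 1)), np.repeat([1, 0], 3),
                                   n_perm=0)


class TestFitFoldEquivalence:
    def test_fast_path_matches_svc_scores(self, rng):
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC
        for _ in range(20):
            y = rng.integers(0, 2, 20)
            y[0], y[1] = 0, 1
            X = rng.normal(size=(20, 1)) + 0.5 * y[:, None]
            Xte = rng.normal(size=(5, 1))
            fast = _fit_fold(X, y, Xte, 1.0)
            sc = StandardScaler().fit(X)
            ref = SVC(kernel="linear", C=1.0).fit(sc.transform(X), y)
            slow = ref.decision_function(sc.transform(Xte))
            np.testing.assert_allclose(fast, slow, atol=2e-3)
            np.testing.assert_array_equal(fast > 0, slow > 0)
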