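import numpy as np
import pytest

from nir2dcos import (PLSDAClassifier, classify, confusion_metrics,
                      fit_plsda, hca, pca, permutation_test, roc_auc,
                      select_latent_variables, validate)


def two_gaussian_classes(rng, n=30, sep=6.0, d=2):
    X = np.vstack([rng.normal(0, 1, (n, d)), rng.normal(sep, 1, (n, d))])
    y = np.array(["a"] * n + ["b"] * n)
    return X, y


class TestPCA:
    def test_rank_one_data_single_component(self, rng):
        u = rng.normal(size=5)
        X = np.outer(rng.normal(size=8), u)
        _, _, evr = pca(X, 2)
        assert evr[0] == pytest.approx(1.0, abs=1e-10)

    def test_scores_reconstruct_centered_data(self, rng):
        X = rng.normal(size=(10, 4))
        scores, loadings, _ = pca(X, 4)
        Xc = X - X.mean(axis=0)
        assert np.linalg.norm(Xc - scores @ loadings.T) <= 1e-10

    def test_explained_variance_matches_covariance_eigenvalues(self, rng):
        X = rng.normal(size=(15, 5))
        _, _, evr = pca(X, 5)
        eig = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
        np.testing.assert_allclose(evr, eig / eig.sum(), rtol=1e-10)
        assert np.all(np.diff(evr) <= 1e-12)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            pca(np.ones((1, 3)), 1)


class TestHCA:
    def test_coincident_pair_merges_first_at_zero(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        Z, classes = hca(X, ["a", "b", "c"], method="single")
        assert sorted(Z[0, :2].astype(int)) == [0, 1]
        assert Z[0, 2] == 0.0

    def test_single_linkage_merge_order_1d(self):
        X = np.array([[0.0], [1.0], [10.0]])
        Z, _ = hca(X, ["a", "b", "c"], method="single")
        assert sorted(Z[0, :2].astype(int)) == [0, 1]
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(9.0)

    def test_ward_heights_monotone(self, rng):
        X = rng.normal(size=(20, 6))
        Z, _ = hca(X, [f"c{i}" for i in range(20)], method="ward")
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_needs_two_classes(self, rng):
        with pytest.raises(ValueError):
            hca(rng.normal(size=(5, 3)), ["a"] * 5)


class TestPLSDA:
    def test_separable_classes_perfect_training_fit(self, rng):
        X, y = two_gaussian_classes(rng)
        model = fit_plsda(X, y, n_latent=1)
        pred, scores = classify(model, X)
        assert (pred == y).all()
        assert scores.shape == (60, 2)

    def test_duplicated_columns_same_predictions(self, rng):
        X, y = two_gaussian_classes(rng, d=3)
        base = fit_plsda(X, y, 2).decision_function(X)
        dup = fit_plsda(np.hstack([X, X]), y, 2).decision_function(
            np.hstack([X, X]))
        np.testing.assert_allclose(dup, base, atol=1e-8)

    def test_full_rank_pls_equals_least_squares(self, rng):
        X = rng.normal(size=(25, 4))
        y = np.array(["a", "b", "c", "d", "e"] * 5)
        model = fit_plsda(X, y, n_latent=4)
        Xc = X - X.mean(axis=0)
        Y = (y[:, None] == model.classes_[None, :]).astype(float)
        coef, *_ = np.linalg.lstsq(Xc, Y - Y.mean(axis=0), rcond=None)
        ols_pred = Y.mean(axis=0) + Xc @ coef
        np.testing.assert_allclose(model.decision_function(X), ols_pred,
                                   atol=1e-8)

    def test_scores_affine_in_X(self, rng):
        X, y = two_gaussian_classes(rng)
        model = fit_plsda(X, y, 2)
        a, b = rng.normal(size=(2, 2)), rng.normal(size=2)
        lhs = model.decision_function(a + b)
        rhs = (model.decision_function(a) + model.decision_function(b)
               - model.decision_function(np.zeros((1, 2))))
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_zero_row_predicts_y_mean_when_x_centered(self, rng):
        X, y = two_gaussian_classes(rng)
        Xc = X - X.mean(axis=0)
        model = fit_plsda(Xc, y, 2)
        np.testing.assert_allclose(model.decision_function(np.zeros((1, 2))),
                                   [[0.5, 0.5]], atol=1e-10)

    def test_invalid_component_count(self, rng):
        X, y = two_gaussian_classes(rng, n=4)
        with pytest.raises(ValueError):
            fit_plsda(X, y, 50)

    def test_orthogonal_scores(self, rng):
        X, y = two_gaussian_classes(rng, d=6)
        model = fit_plsda(X, y, 3)
        T = model.pls_.x_scores_
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.diag(G).max()


class TestConfusionMetrics:
    def test_printed_sixty_degree_outcome(self):
        # 40 members of the class, 1 misclassified; 120 others, none
        # predicted into the class -> SEN = 39/40 = 0.975
        truth = np.array(["60C"] * 40 + ["other"] * 120)
        pred = truth.copy()
        pred[0] = "other"
        m = confusion_metrics(truth, pred, "60C")
        assert m.sen == pytest.approx(0.975)
        assert m.spe == 1.0

    def test_perfect_prediction(self):
        truth = np.array(["a", "b", "a"])
        m = confusion_metrics(truth, truth, "a")
        assert (m.sen, m.spe, m.acc) == (1.0, 1.0, 1.0)

    def test_hand_worked_counts(self):
        truth = np.array(["p"] * 10 + ["n"] * 90)
        pred = np.array(["p"] * 9 + ["n"] + ["p"] * 5 + ["n"] * 85)
        m = confusion_metrics(truth, pred, "p")
        assert (m.tp, m.fn, m.fp, m.tn) == (9, 1, 5, 85)
        assert m.sen == pytest.approx(0.9)
        assert m.spe == pytest.approx(0.944444, abs=1e-6)
        assert m.acc == pytest.approx(0.94)

    def test_count_identities(self, rng):
        truth = rng.choice(["a", "b", "c"], 50)
        pred = rng.choice(["a", "b", "c"], 50)
        m = confusion_metrics(truth, pred, "a")
        assert m.sen * (m.tp + m.fn) == pytest.approx(m.tp)
        assert m.spe * (m.tn + m.fp) == pytest.approx(m.tn)
        assert m.tp + m.fp + m.tn + m.fn == 50

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [], "a")


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_constant_scores_give_half(self):
        _, auc = roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert auc == 0.5

    def test_three_of_four_concordant(self):
        _, auc = roc_auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1])
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_matches_concordant_pair_fraction(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 21))
            truth = np.zeros(n, dtype=int)
            truth[rng.choice(n, int(rng.integers(1, n)), replace=False)] = 1
            scores = np.round(rng.uniform(0, 1, n), 1)  # force some ties
            pos, neg = scores[truth == 1], scores[truth == 0]
            pairs = [(0.5 if p == q else float(p > q))
                     for p in pos for q in neg]
            _, auc = roc_auc(truth, scores)
            assert auc == pytest.approx(np.mean(pairs), abs=1e-12)


class TestValidation:
    def test_noiseless_linear_labels(self, rng):
        X, y = two_gaussian_classes(rng, sep=50.0)
        rep = validate(X, y, n_components=2, folds=5)
        assert rep.rmsee < 0.05
        assert rep.r2 > 0.99

    def test_rmsecv_at_least_rmsee(self, rng):
        wins = sum(
            (lambda r: r.rmsecv >= r.rmsee)(
                validate(*two_gaussian_classes(np.random.default_rng(s),
                                               n=15, sep=2.0, d=4),
                         n_components=2, folds=5))
            for s in range(20))
        assert wins >= 19

    def test_permuted_labels_negative_q2(self):
        neg = 0
        for s in range(20):
            r = np.random.default_rng(1000 + s)
            X = r.normal(size=(80, 8))
            y = r.permutation(np.array(["a", "b"] * 40))
            neg += validate(X, y, n_components=2, folds=5).q2 <= 0
        assert neg >= 18

    def test_singleton_class_rejected(self, rng):
        # venetian-blind folds spread every class across folds, so only a
        # single-member class can ever starve a training partition — and
        # no refolding can fix that, so it is rejected up front
        X = rng.normal(size=(6, 3))
        y = np.array(["a"] * 5 + ["b"])
        with pytest.raises(ValueError, match="'b'.*cross-validation"):
            validate(X, y, 1, folds=5)

    def test_folds_spread_classes(self):
        from nir2dcos.chemometrics import venetian_blind_folds
        y = np.array(["a"] * 6 + ["b"] * 6)
        fold_of = venetian_blind_folds(y, 3)
        for f in range(3):
            assert set(y[fold_of != f]) == {"a", "b"}

    def test_folds_lower_bound(self, rng):
        X, y = two_gaussian_classes(rng, n=5)
        with pytest.raises(ValueError):
            validate(X, y, 1, folds=1)


class TestPermutationTest:
    def test_reference_point_present(self, rng):
        X, y = two_gaussian_classes(rng, n=10, d=3)
        res = permutation_test(X, y, n_perm=20, n_components=2, folds=4,
                               seed=0)
        ref = res.table.iloc[0]
        rep = validate(X, y, 2, 4)
        assert ref["correlation"] == 1.0
        assert ref["r2"] == pytest.approx(rep.r2)
        assert ref["q2"] == pytest.approx(rep.q2)

    def test_seeded_reproducibility(self, rng):
        X, y = two_gaussian_classes(rng, n=10, d=3)
        a = permutation_test(X, y, 20, 2, 4, seed=42)
        b = permutation_test(X, y, 20, 2, 4, seed=42)
        assert a.r2_intercept == b.r2_intercept
        assert a.q2_intercept == b.q2_intercept

    def test_noise_data_q2_below_r2_intercept(self):
        r = np.random.default_rng(7)
        X = r.normal(size=(24, 10))
        y = np.array(["a", "b"] * 12)
        res = permutation_test(X, y, 25, 2, 4, seed=1)
        assert res.q2_intercept < res.r2_intercept

    def test_too_few_permutations(self, rng):
        X, y = two_gaussian_classes(rng, n=10)
        with pytest.raises(ValueError):
            permutation_test(X, y, n_perm=5)


class TestSelectLatentVariables:
    def test_one_lv_separable_data(self, rng):
        X, y = two_gaussian_classes(rng, sep=20.0, d=4)
        assert select_latent_variables(X, y, max_lv=5, folds=5) == 1

    def test_max_lv_one(self, rng):
        X, y = two_gaussian_classes(rng)
        assert select_latent_variables(X, y, max_lv=1, folds=5) == 1

    def test_recovers_true_dimension(self):
        r = np.random.default_rng(3)
        # three classes arranged so that two discriminative directions are
        # needed; remaining dims are noise
        centers = {"a": (0, 0), "b": (8, 0), "c": (0, 8)}
        X, y = [], []
        for cls, c in centers.items():
            pts = r.normal(0, 1, (20, 6))
            pts[:, 0] += c[0]
            pts[:, 1] += c[1]
            X.append(pts)
            y += [cls] * 20
        X, y = np.vstack(X), np.array(y)
        lv = select_latent_variables(X, y, max_lv=6, folds=5)
        assert abs(lv - 2) <= 1
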