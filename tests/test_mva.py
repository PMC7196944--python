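"""PCA, PLS-DA, nested cross-validation, VIP signatures."""

import math

import numpy as np
import pytest

from plasmanmr import mva


def informative_blobs(n_per=20, p=8, sep=4.0, noise=1.0, seed=0):
    """Two classes separated along a known direction, isotropic noise."""
    rng = np.random.default_rng(seed)
    direction = np.zeros(p)
    direction[0] = 1.0
    X = rng.normal(0, noise, (2 * n_per, p))
    y = np.array(["neg"] * n_per + ["pos"] * n_per)
    X[y == "pos"] += sep * direction
    return X, y, direction


def angle_deg(a, b):
    cos = abs(float(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b)))
    return math.degrees(math.acos(min(cos, 1.0)))


class TestPCA:
    def test_collinear_data_explained_by_one_component(self):
        rng = np.random.default_rng(0)
        t = rng.normal(0, 2, 20)
        direction = np.array([1.0, -2.0, 0.5])
        X = np.outer(t, direction) + 5.0
        m = mva.PCA().fit(X)
        assert m.explained_variance_ratio_[0] == pytest.approx(1.0, abs=1e-12)

    def test_full_rank_decomposition_reconstructs_data(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (8, 5))
        m = mva.PCA().fit(X)
        recon = m.scores_ @ m.components_ + m.mean_
        np.testing.assert_allclose(recon, X, atol=1e-8)
        # loadings orthonormal
        np.testing.assert_allclose(m.components_ @ m.components_.T,
                                   np.eye(m.components_.shape[0]), atol=1e-10)

    def test_explained_variance_matches_direct_eigendecomposition(self):
        """6x5 table: eigenvalues of the covariance, computed directly."""
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (6, 5))
        Xc = X - X.mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(Xc.T @ Xc / (6 - 1)))[::-1]
        m = mva.PCA().fit(X)
        np.testing.assert_allclose(m.explained_variance_, eigvals[:5], atol=1e-8)

    def test_agrees_with_sklearn(self):
        from sklearn.decomposition import PCA as SkPCA

        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (12, 6))
        ours = mva.PCA(n_components=3).fit(X)
        theirs = SkPCA(n_components=3).fit(X)
        np.testing.assert_allclose(ours.explained_variance_,
                                   theirs.explained_variance_, atol=1e-10)

    def test_excessive_components_rejected(self):
        X = np.random.default_rng(0).normal(0, 1, (4, 6))
        with pytest.raises(ValueError):
            mva.PCA(n_components=5).fit(X)


class TestPLSDA:
    def test_first_weight_tracks_class_difference_direction(self):
        # strong, well-sampled separation so the geometry dominates noise
        X, y, direction = informative_blobs(n_per=50, sep=8.0, noise=0.5)
        m = mva.PLSDA(n_components=1).fit(X, y)
        assert angle_deg(m.x_weights_[:, 0], direction) < 5.0

    def test_duplicated_features_get_equal_weights(self):
        X, y, _ = informative_blobs(p=4)
        X2 = np.column_stack([X, X[:, 0]])
        m = mva.PLSDA(n_components=2).fit(X2, y)
        np.testing.assert_allclose(m.x_weights_[0], m.x_weights_[-1], atol=1e-10)

    def test_full_rank_fit_exhausts_x(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (10, 4))
        y = np.array(["a"] * 5 + ["b"] * 5)
        m = mva.PLSDA(n_components=4).fit(X, y)
        assert np.max(np.abs(m.x_residual_)) < 1e-8 or m.n_components_ < 4

    def test_scores_mutually_orthogonal(self):
        X, y, _ = informative_blobs()
        m = mva.PLSDA(n_components=3).fit(X, y)
        G = m.x_scores_.T @ m.x_scores_
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8

    def test_perfectly_separated_training_data_classified_cleanly(self):
        X, y, _ = informative_blobs(sep=8.0, noise=0.5)
        m = mva.PLSDA(n_components=1).fit(X, y)
        assert np.all(m.predict(X) == y)

    def test_centroid_prediction_falls_to_tie_class(self):
        X, y, _ = informative_blobs()
        m = mva.PLSDA(n_components=1).fit(X, y)
        centroid = X.mean(axis=0, keepdims=True)
        score = m.decision_function(centroid)
        # balanced classes -> exact 0 -> the class coded -1 (first sorted)
        assert score[0] == pytest.approx(0.0, abs=1e-10)
        assert m.predict(centroid)[0] == m.classes_[0]

    def test_held_out_sample_at_4_sigma_classified_correctly(self):
        X, y, direction = informative_blobs(sep=4.0, noise=1.0, seed=5)
        m = mva.PLSDA(n_components=1).fit(X, y)
        new = (4.0 * direction + np.zeros_like(direction))[None, :]
        assert m.predict(new)[0] == "pos"

    def test_agrees_with_sklearn_pls_regression(self):
        from sklearn.cross_decomposition import PLSRegression

        X, y, _ = informative_blobs(seed=6)
        ycode = np.where(y == "pos", 1.0, -1.0)
        ours = mva.PLSDA(n_components=2).fit(X, y)
        theirs = PLSRegression(n_components=2, scale=False).fit(X, ycode)
        ours_pred = ours.decision_function(X)
        theirs_pred = theirs.predict(X).ravel()
        np.testing.assert_allclose(ours_pred, theirs_pred, atol=1e-8)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(0, 1, (6, 3))
        with pytest.raises(ValueError):
            mva.PLSDA().fit(X, np.array(["a"] * 6))

    def test_feature_mismatch_rejected(self):
        X, y, _ = informative_blobs(p=5)
        m = mva.PLSDA(n_components=1).fit(X, y)
        with pytest.raises(ValueError, match="features"):
            m.predict(X[:, :3])

    def test_pca_and_pls_agree_when_y_follows_first_component(self):
        """Limit equivalence: y proportional to the dominant score."""
        rng = np.random.default_rng(7)
        t = rng.normal(0, 10, 40)  # dominant direction, huge variance
        direction = np.array([3.0, 1.0, 0.0, -1.0]) / np.linalg.norm([3, 1, 0, -1])
        X = np.outer(t, direction) + rng.normal(0, 0.05, (40, 4))
        y = np.where(t > 0, "hi", "lo")
        pls = mva.PLSDA(n_components=1).fit(X, y)
        pca = mva.PCA(n_components=1).fit(X)
        assert angle_deg(pls.x_weights_[:, 0], pca.components_[0]) < 5.0


class TestComponentSelection:
    def test_one_component_data_selects_one(self):
        X, y, _ = informative_blobs(sep=6.0, noise=1.0, seed=8)
        assert mva.select_components_loocv(X, y, a_max=5) == 1

    def test_selection_within_bounds(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (12, 6))
        y = np.array(["a"] * 6 + ["b"] * 6)
        a = mva.select_components_loocv(X, y)
        assert 1 <= a <= 10

    def test_ties_resolve_to_smaller_count(self):
        X, y, _ = informative_blobs(sep=50.0, noise=0.1, seed=10)
        # every a achieves 0 errors; the smallest must be returned
        assert mva.select_components_loocv(X, y, a_max=4) == 1


class TestDoubleCV:
    def test_constant_features_classify_everything_as_tie_class(self):
        X = np.ones((18, 5))
        y = np.array(["PA"] * 9 + ["PPGL"] * 9)
        wrong, preds, _ = mva.double_cv(X, y)
        # every prediction falls to the tie class -> the other class is
        # fully misclassified
        assert wrong == 9
        assert set(preds) == {"PA"}

    def test_separable_cohort_classified_perfectly(self):
        X, y, _ = informative_blobs(n_per=9, sep=6.0, noise=1.0, seed=11)
        wrong, _, comps = mva.double_cv(X, y)
        assert wrong == 0
        assert np.all(comps >= 1)

    def test_invariant_to_sample_reordering(self):
        X, y, _ = informative_blobs(n_per=6, sep=3.0, noise=1.5, seed=12)
        wrong1, _, _ = mva.double_cv(X, y, a_max=3)
        perm = np.random.default_rng(0).permutation(len(y))
        wrong2, _, _ = mva.double_cv(X[perm], y[perm], a_max=3)
        assert wrong1 == wrong2

    def test_error_vanishes_as_effect_size_grows(self):
        errors = []
        for sep in (0.5, 2.0, 8.0):
            X, y, _ = informative_blobs(n_per=6, sep=sep, noise=1.0, seed=13)
            wrong, _, _ = mva.double_cv(X, y, a_max=3)
            errors.append(wrong)
        assert errors[0] >= errors[1] >= errors[2]
        assert errors[2] == 0

    def test_permuted_labels_classify_at_chance(self):
        """Null distribution: mean error rate >= 25% over 100 permutations."""
        X, y, _ = informative_blobs(n_per=9, sep=3.0, noise=1.0, seed=14)
        rng = np.random.default_rng(15)
        rates = []
        for _ in range(100):
            yp = rng.permutation(y)
            wrong, _, _ = mva.double_cv(X, yp, a_max=3)
            rates.append(wrong / len(y))
        assert np.mean(rates) >= 0.25


class TestVIP:
    def test_uniform_weights_give_unit_vips(self):
        """Single component with equal weights: every VIP is exactly 1."""
        rng = np.random.default_rng(16)
        t = rng.normal(0, 1, 12)
        X = np.outer(t, np.ones(4))
        y = np.where(t > 0, "a", "b")
        m = mva.PLSDA(n_components=1).fit(X, y)
        sig = mva.vip_scores(m)
        np.testing.assert_allclose(sig.scores, 1.0, atol=1e-8)

    def test_single_component_closed_form(self):
        X, y, _ = informative_blobs(seed=17)
        m = mva.PLSDA(n_components=1).fit(X, y)
        sig = mva.vip_scores(m)
        w = m.x_weights_[:, 0]
        expected = math.sqrt(len(w)) * np.abs(w) / np.linalg.norm(w)
        np.testing.assert_allclose(sig.scores, expected, atol=1e-10)

    def test_two_component_model_matches_term_by_term_oracle(self):
        """5-feature, 2-component model against a hand evaluation."""
        X, y, _ = informative_blobs(p=5, seed=18)
        m = mva.PLSDA(n_components=2).fit(X, y)
        W, T, q = m.x_weights_, m.x_scores_, m.y_loadings_
        p = 5
        ssy = [q[a] ** 2 * float(T[:, a] @ T[:, a]) for a in range(2)]
        expected = []
        for j in range(p):
            acc = 0.0
            for a in range(2):
                wnorm = math.sqrt(sum(W[k, a] ** 2 for k in range(p)))
                acc += ssy[a] * (W[j, a] / wnorm) ** 2
            expected.append(math.sqrt(p * acc / sum(ssy)))
        np.testing.assert_allclose(mva.vip_scores(m).scores, expected, atol=1e-10)

    @pytest.mark.parametrize("n_components", [1, 2, 3])
    def test_squared_vips_sum_to_feature_count(self, n_components):
        X, y, _ = informative_blobs(p=7, seed=19)
        m = mva.PLSDA(n_components=n_components).fit(X, y)
        sig = mva.vip_scores(m)
        assert float(np.sum(sig.scores**2)) == pytest.approx(7.0, abs=1e-8)


class TestSignatureOverlap:
    def sig(self, positions, scores=None):
        positions = np.asarray(positions, float)
        if scores is None:
            scores = np.full(positions.size, 2.0)
        return mva.VipSignature(scores=np.asarray(scores, float),
                                positions=positions)

    def test_identical_signatures_fully_shared(self):
        a = self.sig([1.0, 2.0, 3.0])
        out = mva.signature_overlap(a, a)
        assert out == {"shared": 3, "a_only": 0, "b_only": 0}

    def test_disjoint_positions_share_nothing(self):
        out = mva.signature_overlap(self.sig([1.0, 2.0]), self.sig([5.0, 6.0]))
        assert out["shared"] == 0

    def test_constructed_partial_overlap(self):
        """3 of 5 positions match within tolerance: 60% overlap."""
        a = self.sig([1.000, 2.000, 3.000, 4.000, 5.000])
        b = self.sig([1.003, 2.002, 2.998, 4.100, 5.100])
        out = mva.signature_overlap(a, b, match_tol=0.005)
        assert out == {"shared": 3, "a_only": 2, "b_only": 2}

    def test_unimportant_features_ignored(self):
        a = self.sig([1.0, 2.0], scores=[2.0, 0.5])  # second below threshold
        b = self.sig([1.0, 2.0])
        out = mva.signature_overlap(a, b)
        assert out == {"shared": 1, "a_only": 0, "b_only": 1}

    def test_invalid_tolerance_rejected(self):
        with pytest.raises(ValueError):
            mva.signature_overlap(self.sig([1.0]), self.sig([1.0]), match_tol=0.0)
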