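"""PCA, NIPALS PLS, OPLS-DA, VIP, Q2, permutation test and CV-ANOVA."""

import numpy as np
import pytest

import woundage as wa
from woundage.chemometrics import (
    CrossvalResult,
    cv_anova,
    one_hot,
    opls_fit,
    pca,
    permutation_test,
    pls_nipals,
    q2_crossval,
    vip,
)


def _grouped_data(seed=0, n_per=12, n_classes=3, p=15, sep=3.0, noise=1.0):
    """Gaussian classes shifted along distinct feature blocks."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, noise, (n_per * n_classes, p))
    labels = []
    for k in range(n_classes):
        X[k * n_per:(k + 1) * n_per, 3 * k:3 * k + 3] += sep
        labels += [f"g{k}"] * n_per
    return X, labels


class TestPca:
    def test_rank_one_matrix_has_unit_explained_fraction(self):
        u = np.outer(np.arange(1.0, 7.0), [1.0, 2.0, 3.0])
        _, _, explained = pca(u, 1)
        assert explained[0] == pytest.approx(1.0)

    def test_full_reconstruction_equals_centered_matrix(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (10, 4))
        scores, loadings, explained = pca(X, 4)
        np.testing.assert_allclose(scores @ loadings.T, X - X.mean(axis=0), atol=1e-8)
        assert np.all(np.diff(explained) <= 1e-12)
        assert explained.sum() <= 1.0 + 1e-12

    def test_k_beyond_rank_rejected(self):
        u = np.outer(np.arange(5.0), [1.0, 2.0])
        with pytest.raises(ValueError):
            pca(u, 2)

    def test_qc_samples_cluster_tighter_than_study_samples(self, small_study, small_config):
        table = wa.add_qc(small_study, small_config)
        scores, _, _ = pca(table.log_areas().to_numpy(), 2)
        roles = table.meta["role"].to_numpy()
        rms = lambda s: np.sqrt((s**2).sum(axis=1).mean())
        assert rms(scores[roles == "qc"]) < 0.5 * rms(scores[roles == "study"])


class TestPlsNipals:
    def test_exact_fit_when_y_is_linear_in_one_column(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (30, 1))
        y = 2.5 * X[:, :1] + 1.0
        model = pls_nipals(X, y, A=1)
        assert np.abs(y - model.predict(X)).max() < 1e-8

    def test_full_rank_pls_matches_least_squares(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (40, 6))
        y = rng.normal(0, 1, (40, 1))
        model = pls_nipals(X, y, A=6)
        Xc = np.column_stack([np.ones(len(X)), X])
        beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        yhat_ls = Xc @ beta
        np.testing.assert_allclose(model.predict(X), yhat_ls, atol=1e-6)

    def test_row_permutation_permutes_scores_identically(self):
        X, labels = _grouped_data(seed=4)
        Y, _ = one_hot(labels)
        model = pls_nipals(X, Y, A=2)
        perm = np.random.default_rng(5).permutation(len(X))
        permuted = pls_nipals(X[perm], Y[perm], A=2)
        np.testing.assert_allclose(permuted.T, model.T[perm], atol=1e-8)

    def test_zero_variance_x_rejected(self):
        X = np.ones((10, 3))
        with pytest.raises(ValueError):
            pls_nipals(X, np.arange(10.0)[:, None], A=1)

    def test_components_beyond_rank_rejected(self):
        X = np.outer(np.arange(10.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            pls_nipals(X, np.arange(10.0)[:, None], A=2)


class TestOpls:
    def test_zero_orthogonal_components_reduce_to_pls(self):
        X, labels = _grouped_data(seed=6)
        Y, _ = one_hot(labels)
        model = opls_fit(X, labels, a_pred=2, a_orth=0, scale=False)
        oracle = pls_nipals(X, Y, A=2)
        np.testing.assert_allclose(model.T, oracle.T, atol=1e-8)
        np.testing.assert_allclose(model.pls.coef, oracle.coef, atol=1e-8)

    def test_score_orthogonality_and_r2y_range(self):
        X, labels = _grouped_data(seed=7)
        model = opls_fit(X, labels, a_orth=2)
        T, To = model.T, model.T_ortho
        for i in range(T.shape[1]):
            for j in range(i + 1, T.shape[1]):
                assert abs(T[:, i] @ T[:, j]) < 1e-8
        assert np.abs(T.T @ To).max() < 1e-8
        assert 0.0 <= model.r2y <= 1.0

    def test_default_synthetic_three_phase_study_fits_well(self, default_study, scheme):
        contused = default_study.subset_labels(set(scheme.coarse))
        phases = [scheme.coarse_of(l) for l in contused.meta["label"]]
        model = opls_fit(contused.log_areas().to_numpy(), phases)
        assert model.r2y >= 0.7

    def test_labels_independent_of_x_give_low_q2(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (60, 20))
        labels = ["a", "b", "c"] * 20
        cv = q2_crossval(X, labels, seed=8)
        assert cv.q2 <= 0.1

    def test_single_sample_class_rejected(self):
        X = np.random.default_rng(9).normal(0, 1, (5, 4))
        with pytest.raises(ValueError, match="single sample"):
            opls_fit(X, ["a", "a", "a", "a", "b"])

    def test_transform_on_training_data_matches_fit_scores(self):
        X, labels = _grouped_data(seed=10)
        model = opls_fit(X, labels, a_orth=1)
        np.testing.assert_allclose(model.transform(X), model.T, atol=1e-8)


class TestVip:
    def test_identical_feature_copies_all_get_vip_one(self):
        rng = np.random.default_rng(11)
        col = rng.normal(0, 1, 24)
        X = np.tile(col[:, None], (1, 6))
        labels = ["a"] * 12 + ["b"] * 12
        model = opls_fit(X, labels, a_pred=1, a_orth=0)
        np.testing.assert_allclose(model.vip_, 1.0, atol=1e-8)

    def test_sum_of_squared_vip_equals_feature_count(self):
        for seed in (12, 13):
            X, labels = _grouped_data(seed=seed)
            model = opls_fit(X, labels, a_orth=1)
            assert np.sum(model.vip_**2) == pytest.approx(X.shape[1], abs=1e-8)

    def test_informative_feature_has_maximal_vip(self):
        rng = np.random.default_rng(14)
        X = rng.normal(0, 1, (40, 10))
        labels = ["a"] * 20 + ["b"] * 20
        X[:20, 0] += 4.0
        model = opls_fit(X, labels, a_pred=1, a_orth=1)
        assert int(np.argmax(model.vip_)) == 0


class TestQ2Crossval:
    def test_separable_classes_give_high_q2(self):
        X, labels = _grouped_data(seed=15, sep=6.0, noise=0.3)
        cv = q2_crossval(X, labels, seed=15)
        assert cv.q2 >= 0.9

    def test_shuffled_labels_give_low_q2(self):
        X, labels = _grouped_data(seed=16, sep=6.0, noise=0.3)
        shuffled = list(np.random.default_rng(17).permutation(labels))
        cv = q2_crossval(X, shuffled, seed=16)
        assert cv.q2 <= 0.1

    def test_q2_never_exceeds_r2y_on_same_data(self):
        for seed in (18, 19, 20):
            X, labels = _grouped_data(seed=seed, sep=2.0)
            model = opls_fit(X, labels, a_orth=1)
            cv = q2_crossval(X, labels, a_orth=1, seed=seed)
            assert cv.q2 <= model.r2y + 1e-10

    def test_class_absent_from_training_fold_is_an_error(self):
        X, labels = _grouped_data(seed=21, n_per=3)
        with pytest.raises(ValueError, match="fewer folds"):
            q2_crossval(X, labels, folds=4)

    def test_q2_weakly_decreases_with_label_noise(self):
        X, labels = _grouped_data(seed=22, sep=5.0, noise=0.5)
        rng = np.random.default_rng(23)
        classes = sorted(set(labels))
        q2s = []
        for flip in (0.0, 0.3, 0.6):
            noisy = list(labels)
            idx = rng.choice(len(labels), size=int(flip * len(labels)), replace=False)
            for i in idx:
                noisy[i] = classes[rng.integers(len(classes))]
            q2s.append(q2_crossval(X, noisy, seed=24).q2)
        assert q2s[0] >= q2s[1] - 0.05 >= q2s[2] - 0.10


class TestCvAnova:
    def test_separable_data_is_highly_significant(self):
        X, labels = _grouped_data(seed=25, sep=6.0, noise=0.3)
        assert cv_anova(q2_crossval(X, labels, seed=25)) < 0.001

    def test_null_labels_rarely_significant(self):
        rng = np.random.default_rng(26)
        n_sig = 0
        for k in range(50):
            X = rng.normal(0, 1, (36, 8))
            labels = list(rng.permutation(["a", "b", "c"] * 12))
            p = cv_anova(q2_crossval(X, labels, folds=4, seed=k))
            n_sig += p <= 0.05
        assert 50 - n_sig >= 40  # p > 0.05 in at least 80% of null runs

    def test_no_improvement_over_mean_gives_p_one(self):
        cv = CrossvalResult(q2=0.0, press=10.0, ss_total=10.0,
                            residuals=np.zeros((10, 2)), n_components=2, n_samples=10)
        assert cv_anova(cv) == 1.0


class TestPermutationTest:
    def test_report_structure_and_correlation_range(self):
        X, labels = _grouped_data(seed=27, n_per=8, p=8)
        report = permutation_test(X, labels, n_perm=15, seed=27, folds=4)
        assert report.n_perm == 15
        assert all(-1.0 <= corr <= 1.0 for corr, _, _ in report.permuted)

    def test_separable_data_beats_most_permutations(self):
        X, labels = _grouped_data(seed=28, sep=5.0, noise=0.5, n_per=8, p=8)
        report = permutation_test(X, labels, n_perm=40, seed=28, folds=4)
        assert report.q2_quantile() >= 0.95

    def test_zero_permutations_returns_originals_only(self):
        X, labels = _grouped_data(seed=29, n_per=8, p=8)
        report = permutation_test(X, labels, n_perm=0, seed=29, folds=4)
        assert report.permuted == []
        assert np.isfinite(report.original_r2y)


def test_opls_equals_pls_on_random_matrices_property():
    """OPLS with no orthogonal components is exactly NIPALS PLS (50 draws)."""
    rng = np.random.default_rng(30)
    for draw in range(50):
        n = int(rng.integers(12, 30))
        p = int(rng.integers(3, 10))
        X = rng.normal(0, 1, (n, p))
        labels = ["a", "b"] * (n // 2) + (["a"] if n % 2 else [])
        a_pred = 1
        model = opls_fit(X, labels, a_pred=a_pred, a_orth=0, scale=False)
        Y, _ = one_hot(labels)
        oracle = pls_nipals(X, Y, A=a_pred)
        np.testing.assert_allclose(model.T, oracle.T, atol=1e-8)
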