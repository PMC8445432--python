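import numpy as np
import pytest

from ramanlda import (
    classify,
    evaluate_samples,
    fit_lda,
    fit_pca_nipals,
    generate_dataset,
    leverage_corrected_variance,
    project,
)
from ramanlda.metrics import compute_metrics

from conftest import small_config


def svd_pca(X, k):
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :k] * S[:k]
    return scores, Vt[:k], S**2 / np.sum(S**2)


def assert_matches_svd(model, X, k, tol=1e-8):
    """Check NIPALS scores/loadings against the SVD oracle up to sign."""
    ref_scores, ref_loadings, ref_evf = svd_pca(X, k)
    for a in range(k):
        v = ref_loadings[a]
        # apply this package's sign convention to the oracle component
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
            t_ref = -ref_scores[:, a]
        else:
            t_ref = ref_scores[:, a]
        assert np.max(np.abs(model.loadings[a] - v)) < tol
        assert np.max(np.abs(model.scores[:, a] - t_ref)) < tol
        assert model.explained_variance_fraction[a] == pytest.approx(
            ref_evf[a], abs=1e-10
        )


class TestNipals:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_svd_oracle_up_to_sign(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(5, 15, size=2)
        X = rng.normal(size=(n, m))
        k = int(min(n, m)) - 1
        model = fit_pca_nipals(X, n_components=k, tol=1e-13, max_iter=50000)
        assert_matches_svd(model, X, k)

    def test_rank_one_matrix_explained_by_first_component(self):
        u = np.array([1.0, 2.0, -1.0, 0.5])
        v = np.array([0.3, -0.7, 1.1, 0.2, 0.9])
        X = np.outer(u, v)
        model = fit_pca_nipals(X, n_components=2)
        assert model.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-10)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_pca_nipals(np.full((5, 4), 3.0), n_components=2)

    def test_model_invariants_on_random_data(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 12))
        k = 12
        model = fit_pca_nipals(X, n_components=k, tol=1e-13, max_iter=50000)
        # unit loadings
        np.testing.assert_allclose(
            np.linalg.norm(model.loadings, axis=1), 1.0, atol=1e-8
        )
        # non-increasing variance fractions summing to 1 over all components
        evf = model.explained_variance_fraction
        assert np.all(np.diff(evf) <= 1e-10)
        assert np.sum(evf) == pytest.approx(1.0, abs=1e-8)
        # orthogonal score columns
        G = model.scores.T @ model.scores
        norms = np.linalg.norm(model.scores, axis=0)
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off) / np.outer(norms, norms).clip(1e-30)) < 1e-6


class TestLeverage:
    def test_rank_k_matrix_has_zero_validated_residual(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 2)) @ rng.normal(size=(2, 6))
        model = fit_pca_nipals(X, n_components=2)
        lcv = leverage_corrected_variance(model, X)
        assert lcv[-1] == pytest.approx(0.0, abs=1e-16)

    def test_leverages_within_hat_bounds(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 6))
        model = fit_pca_nipals(X, n_components=3)
        n = X.shape[0]
        for k in range(1, 4):
            T = model.scores[:, :k]
            h = 1.0 / n + np.einsum(
                "ij,jk,ik->i", T, np.linalg.pinv(T.T @ T), T
            )
            assert np.all(h >= 1.0 / n - 1e-12)
            assert np.all(h < 1.0)

    def test_approximates_leave_one_out_residual_variance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 4)) @ np.diag([3.0, 2.0, 1.0, 0.5])
        model = fit_pca_nipals(X, n_components=2)
        lcv = leverage_corrected_variance(model, X)
        for k in (1, 2):
            total = 0.0
            for i in range(X.shape[0]):
                Xt = np.delete(X, i, axis=0)
                mi = fit_pca_nipals(Xt, n_components=k)
                sc = project(mi, X[i : i + 1])
                resid = (X[i] - mi.grand_mean) - sc[:, :k] @ mi.loadings[:k]
                total += float(np.sum(resid**2))
            loo = total / X.size
            assert abs(lcv[k - 1] - loo) < 0.25 * loo


class TestProject:
    def test_training_rows_reproduce_stored_scores(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 8))
        model = fit_pca_nipals(X, n_components=4, tol=1e-13, max_iter=50000)
        np.testing.assert_allclose(project(model, X), model.scores, atol=1e-8)

    def test_grand_mean_projects_to_zero(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 5))
        model = fit_pca_nipals(X, n_components=3)
        np.testing.assert_allclose(
            project(model, model.grand_mean[None, :]), 0.0, atol=1e-10
        )

    def test_orthogonal_complement_leaves_scores_unchanged(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 6))
        model = fit_pca_nipals(X, n_components=3, tol=1e-13, max_iter=50000)
        # build a vector orthogonal to all loadings
        v = rng.normal(size=6)
        for p in model.loadings:
            v -= (v @ p) * p
        np.testing.assert_allclose(
            project(model, X + v), project(model, X), atol=1e-8
        )

    def test_dimension_mismatch_rejected(self):
        model = fit_pca_nipals(np.random.default_rng(0).normal(size=(6, 4)), 2)
        with pytest.raises(ValueError, match="variable count"):
            project(model, np.ones((2, 5)))


class TestLda:
    def test_separated_clusters_classified_perfectly(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(-10, 0.1, 20), rng.normal(10, 0.1, 20)])
        labels = ["PA"] * 20 + ["ACC"] * 20
        model = fit_lda(x[:, None], labels, k=1)
        pred, post = classify(model, x[:, None])
        assert pred == labels
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_identical_class_means_tie_goes_to_pa(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 2))
        labels = ["PA"] * 20 + ["ACC"] * 20
        Xs = np.vstack([X[:20] - X[:20].mean(0), X[20:] - X[20:].mean(0)])
        model = fit_lda(Xs, labels, k=2)
        pred, post = classify(model, model.class_means[0][None, :])
        mid = (model.class_means[0] + model.class_means[1]) / 2
        pred_mid, post_mid = classify(model, mid[None, :])
        assert post_mid[0, 0] == pytest.approx(0.5, abs=1e-12)
        assert pred_mid == ["PA"]

    def test_weight_parallel_to_fisher_direction(self):
        rng = np.random.default_rng(10)
        X = np.vstack(
            [rng.normal([0, 0], [1, 2], size=(30, 2)),
             rng.normal([3, 1], [1, 2], size=(30, 2))]
        )
        labels = ["PA"] * 30 + ["ACC"] * 30
        model = fit_lda(X, labels, k=2)
        mu_pa, mu_acc = model.class_means
        fisher = np.linalg.solve(model.pooled_covariance, mu_acc - mu_pa)
        cos = (model.weights @ fisher) / (
            np.linalg.norm(model.weights) * np.linalg.norm(fisher)
        )
        assert cos > 1 - 1e-10

    def test_classify_affine_invariance(self):
        """Accuracy is unchanged under an invertible affine transform applied
        consistently to training and test scores."""
        rng = np.random.default_rng(12)
        X = np.vstack(
            [rng.normal(0, 1, size=(25, 3)), rng.normal(1.5, 1, size=(25, 3))]
        )
        labels = ["PA"] * 25 + ["ACC"] * 25
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        b = rng.normal(size=3)
        m1 = fit_lda(X, labels, k=3)
        m2 = fit_lda(X @ A + b, labels, k=3)
        p1, _ = classify(m1, X)
        p2, _ = classify(m2, X @ A + b)
        assert p1 == p2

    def test_singular_covariance_advises_reducing_k(self):
        X = np.zeros((10, 3))
        X[:, 0] = np.arange(10)
        labels = ["PA"] * 5 + ["ACC"] * 5
        with pytest.raises(ValueError, match="reduce"):
            fit_lda(X, labels, k=3)

    def test_class_mean_classified_to_own_class(self):
        rng = np.random.default_rng(13)
        X = np.vstack(
            [rng.normal(0, 1, size=(20, 2)), rng.normal(4, 1, size=(20, 2))]
        )
        labels = ["PA"] * 20 + ["ACC"] * 20
        model = fit_lda(X, labels, k=2)
        pred, post = classify(model, model.class_means)
        assert pred == ["PA", "ACC"]
        assert post[0, 0] > 0.5 and post[1, 1] > 0.5


class TestEvaluateSamples:
    def test_noise_free_set_is_perfectly_separable(self, noise_free_set):
        sset, _ = noise_free_set
        # tiny per-sample jitter so PCA/LDA are non-degenerate
        rng = np.random.default_rng(0)
        jittered = sset.map_intensities(
            lambda s: s.intensities + rng.normal(0, 1e-3, len(s.grid))
        )
        cm, detail = evaluate_samples(jittered, validation="resubstitution")
        assert cm.fp == 0 and cm.fn == 0
        assert cm.tp == 10 and cm.tn == 10

    def test_loso_runs_one_fold_per_sample(self):
        sset, _ = generate_dataset(small_config(seed=1, n_samples_per_entity=3))
        cm, detail = evaluate_samples(
            sset, validation="leave_one_sample_out",
            n_components=4, n_predictors=3,
        )
        assert len(detail["samples"]) == 6
        assert cm.total == 6

    def test_requires_two_samples_per_entity(self):
        sset, _ = generate_dataset(small_config(seed=1, n_samples_per_entity=1))
        with pytest.raises(ValueError, match="2 samples"):
            evaluate_samples(sset)

    def test_resubstitution_is_optimistic_on_average(self):
        """Resubstitution accuracy >= leave-one-sample-out accuracy averaged
        over 10 seeds (training-set optimism)."""
        resub, loso = [], []
        for seed in range(10):
            sset, _ = generate_dataset(
                small_config(seed=seed, n_samples_per_entity=4,
                             n_spectra_per_sample=6, noise_sd=400.0,
                             baseline=None)
            )
            kw = dict(n_components=5, n_predictors=4)
            cm_r, _ = evaluate_samples(sset, validation="resubstitution", **kw)
            cm_l, _ = evaluate_samples(
                sset, validation="leave_one_sample_out", **kw
            )
            resub.append(compute_metrics(cm_r).accuracy)
            loso.append(compute_metrics(cm_l).accuracy)
        assert np.mean(resub) >= np.mean(loso)
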