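"""PCA-LDA classification against brute-force and library oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ramanmargin.bands import FeatureTable
from ramanmargin.classify import (
    compute_metrics,
    fit_lda,
    fit_pca,
    loo_cross_validate,
    predict_lda,
    project,
)
from ramanmargin.errors import InsufficientSampleError, SchemaError


def table(X, labels=None, names=None):
    X = np.asarray(X, float)
    names = names or [f"B_{i}" for i in range(X.shape[1])]
    idx = [f"s{i}" for i in range(X.shape[0])]
    labels = labels if labels is not None else ["healthy"] * X.shape[0]
    return FeatureTable(
        values=pd.DataFrame(X, columns=names, index=idx),
        labels=pd.Series(labels, index=idx, name="label"),
    )


# -- independent oracles ----------------------------------------------------

def charpoly_eigh(C):
    """Brute-force symmetric eigendecomposition: characteristic polynomial
    by Faddeev-LeVerrier, roots by np.roots, eigenvectors by SVD nullspace.
    Deliberately avoids np.linalg.eigh (the implementation's route)."""
    n = C.shape[0]
    coeffs = [1.0]
    M = np.zeros_like(C)
    for k in range(1, n + 1):
        M = C @ M + coeffs[-1] * np.eye(n)
        coeffs.append(-np.trace(C @ M) / k)
    roots = np.roots(coeffs)
    eigvals = np.sort(np.real(roots))[::-1]
    vecs = []
    for lam in eigvals:
        _, _, Vt = np.linalg.svd(C - lam * np.eye(n))
        vecs.append(Vt[-1])
    return eigvals, np.column_stack(vecs)


def bayes_posteriors(X, means, cov, priors):
    """Explicit Gaussian densities, normalized; no Cholesky tricks."""
    inv = np.linalg.inv(cov)
    det = np.linalg.det(cov)
    k = cov.shape[0]
    dens = []
    for mu, pr in zip(means, priors):
        d = X - mu
        expo = -0.5 * np.sum(d @ inv * d, axis=1)
        dens.append(pr * np.exp(expo) / np.sqrt((2 * np.pi) ** k * det))
    dens = np.column_stack(dens)
    return dens / dens.sum(axis=1, keepdims=True)


class TestPCA:
    def test_all_variance_on_one_axis_gives_pc1_100_percent(self):
        X = np.zeros((6, 3))
        X[:, 1] = np.arange(6.0)
        model = fit_pca(table(X))
        assert model.percent[0] == pytest.approx(100.0)

    def test_matches_charpoly_oracle_on_random_table(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 4))
        model = fit_pca(table(X))
        C = np.cov(X, rowvar=False)
        ev, V = charpoly_eigh(C)
        np.testing.assert_allclose(model.eigenvalues, ev, atol=1e-8)
        for j in range(4):
            v = V[:, j]
            got = model.loadings[:, j]
            assert min(np.max(np.abs(got - v)), np.max(np.abs(got + v))) < 1e-8

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        extra=st.integers(2, 8),
        p=st.integers(2, 6),
        seed=st.integers(0, 10_000),
    )
    def test_property_eigendecomposition_equals_oracle(self, extra, p, seed):
        # full-rank tables: repeated zero roots of the characteristic
        # polynomial are ill-conditioned for the oracle itself
        n = p + extra
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p)) * rng.uniform(0.5, 2.0, size=p)
        model = fit_pca(table(X))
        C = np.cov(X, rowvar=False)
        ev, _ = charpoly_eigh(C)
        np.testing.assert_allclose(model.eigenvalues, ev, atol=1e-8)
        # orthonormal loadings, total variance conserved
        G = model.loadings.T @ model.loadings
        np.testing.assert_allclose(G, np.eye(p), atol=1e-8)
        assert model.eigenvalues.sum() == pytest.approx(np.trace(C), abs=1e-8)

    def test_matches_sklearn_components(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 5))
        model = fit_pca(table(X))
        sk = sklearn.PCA(n_components=5).fit(X)
        np.testing.assert_allclose(
            model.eigenvalues, sk.explained_variance_, rtol=1e-10
        )
        for j in range(5):
            a, b = model.loadings[:, j], sk.components_[j]
            assert min(np.max(np.abs(a - b)), np.max(np.abs(a + b))) < 1e-10

    def test_published_loading_column_is_unit_norm(self):
        """The printed PC1 loadings of the 12-band microscope table have
        squared norm ~1, matching this implementation's unit-norm convention."""
        printed_pc1 = [-0.117, -0.094, 0.146, 0.246, 0.440, 0.633, 0.468,
                       -0.135, 0.168, 0.087, -0.137, 0.096]
        assert np.sum(np.square(printed_pc1)) == pytest.approx(1.0, abs=0.02)

    def test_rank_deficient_table_warns_with_trailing_zero_eigenvalues(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(4, 5))
        with pytest.warns(UserWarning, match="rank-deficient"):
            model = fit_pca(table(X))
        assert np.all(model.eigenvalues[3:] < 1e-10)

    def test_constant_column_warns(self):
        X = np.random.default_rng(0).normal(size=(8, 3))
        X[:, 2] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            fit_pca(table(X))

    def test_sign_convention_largest_entry_positive(self):
        rng = np.random.default_rng(4)
        model = fit_pca(table(rng.normal(size=(20, 4))))
        for j in range(model.n_components):
            col = model.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0


class TestProjection:
    def test_full_reconstruction_recovers_centered_table(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 4))
        ft = table(X)
        model = fit_pca(ft)
        scores = project(model, ft, k=4).to_numpy()
        recon = scores @ model.loadings.T + model.feature_means
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_k_zero_rejected(self):
        ft = table(np.random.default_rng(0).normal(size=(5, 3)))
        with pytest.raises(SchemaError):
            project(fit_pca(ft), ft, k=0)

    def test_training_scores_are_centered(self):
        rng = np.random.default_rng(6)
        ft = table(rng.normal(size=(12, 5)))
        scores = project(fit_pca(ft), ft, k=3).to_numpy()
        assert np.max(np.abs(scores.mean(axis=0))) < 1e-10

    def test_column_mismatch_rejected(self):
        rng = np.random.default_rng(7)
        ft = table(rng.normal(size=(6, 3)))
        other = table(rng.normal(size=(6, 3)), names=["X", "Y", "Z"])
        with pytest.raises(SchemaError):
            project(fit_pca(ft), other, k=2)


class TestLDA:
    def test_hand_computed_one_dimensional_fit(self):
        scores = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = ["healthy", "healthy", "tumor", "tumor"]
        model = fit_lda(scores, labels)
        np.testing.assert_allclose(model.class_means, [[0.05], [10.05]])
        assert model.pooled_cov[0, 0] == pytest.approx(0.005)
        np.testing.assert_allclose(model.priors, [0.5, 0.5])

    def test_class_means_recovered_within_sampling_error(self):
        rng = np.random.default_rng(8)
        a = rng.normal([0, 0], 1.0, size=(500, 2))
        b = rng.normal([3, 1], 1.0, size=(500, 2))
        X = np.vstack([a, b])
        labels = ["healthy"] * 500 + ["tumor"] * 500
        model = fit_lda(X, labels)
        se = 1.0 / np.sqrt(500)
        assert np.all(np.abs(model.class_means[0] - [0, 0]) < 3 * se)
        assert np.all(np.abs(model.class_means[1] - [3, 1]) < 3 * se)

    def test_posteriors_match_bayes_oracle(self):
        rng = np.random.default_rng(9)
        X = np.vstack([
            rng.normal([0, 0, 0], 1.0, size=(20, 3)),
            rng.normal([2, 1, -1], 1.0, size=(20, 3)),
        ])
        labels = ["healthy"] * 20 + ["tumor"] * 20
        model = fit_lda(X, labels)
        pts = rng.normal(scale=2.0, size=(50, 3))
        _, post = predict_lda(model, pts)
        oracle = bayes_posteriors(pts, model.class_means, model.pooled_cov,
                                  model.priors)
        np.testing.assert_allclose(post, oracle[:, 1], atol=1e-10)

    def test_posteriors_match_sklearn(self):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(10)
        X = np.vstack([
            rng.normal([0, 0], 1.0, size=(15, 2)),
            rng.normal([2, 2], 1.0, size=(15, 2)),
        ])
        labels = ["healthy"] * 15 + ["tumor"] * 15
        model = fit_lda(X, labels)
        pts = rng.normal(size=(20, 2))
        _, post = predict_lda(model, pts)
        # sklearn pools with 1/(n - n_classes) too (empirical covariance of
        # the pooled centered data); solver 'lsqr' exposes the same model
        sk = sklearn.LinearDiscriminantAnalysis(store_covariance=True).fit(
            X, labels
        )
        sk_cov_scaled = sk.covariance_ * (len(labels) / (len(labels) - 2))
        np.testing.assert_allclose(model.pooled_cov, sk_cov_scaled, rtol=1e-8)
        oracle = bayes_posteriors(pts, model.class_means, model.pooled_cov,
                                  model.priors)
        np.testing.assert_allclose(post, oracle[:, 1], atol=1e-10)

    def test_point_at_class_mean_classified_to_it(self):
        model = fit_lda(
            np.array([[0.0, 0], [0.2, 0], [5, 5], [5.2, 5]]),
            ["healthy", "healthy", "tumor", "tumor"],
        )
        labels, post = predict_lda(model, model.class_means)
        assert labels == ["healthy", "tumor"]
        assert post[0] < 0.5 < post[1]

    def test_midpoint_posterior_is_half_and_tie_breaks_healthy(self):
        model = fit_lda(
            np.array([[-1.0], [-1.2], [1.0], [1.2]]),
            ["healthy", "healthy", "tumor", "tumor"],
        )
        mid = np.array([[-0.0]]) + (model.class_means[0] + model.class_means[1]) / 2
        labels, post = predict_lda(model, mid)
        assert abs(post[0] - 0.5) < 1e-12
        assert labels == ["healthy"]

    def test_tiny_class_rejected(self):
        with pytest.raises(InsufficientSampleError):
            fit_lda(np.array([[0.0], [1.0], [2.0]]),
                    ["healthy", "tumor", "tumor"])


class TestMetrics:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((27, 1, 4, 25), (86, 96, 91)),   # 1064 nm microscope
            ((10, 0, 2, 38), (95, 100, 96)),  # 785 nm microscope
            ((24, 4, 3, 26), (90, 86, 88)),   # 785 nm handheld probe
        ],
    )
    def test_published_confusion_counts_reproduce_percentages(self, counts, expected):
        assert compute_metrics(*counts) == expected

    def test_rounding_half_away_from_zero(self):
        # 50.0% of 2 -> 50; 25/29 = 86.2 -> 86; 26/29 = 89.66 -> 90
        assert compute_metrics(1, 1, 1, 1) == (50, 50, 50)

    def test_empty_class_denominator_flagged(self):
        with pytest.raises(InsufficientSampleError):
            compute_metrics(5, 0, 0, 0)


class TestLOOCrossValidation:
    def separated_table(self, n=10, gap=50.0, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([
            rng.normal(0.0, 1.0, size=(n, 4)),
            rng.normal(gap, 1.0, size=(n, 4)),
        ])
        labels = ["healthy"] * n + ["tumor"] * n
        return table(X, labels)

    def test_widely_separated_classes_score_100(self):
        rep = loo_cross_validate(self.separated_table())
        assert (rep.sensitivity, rep.specificity, rep.accuracy) == (100, 100, 100)

    @pytest.mark.parametrize("refit", [True, False])
    def test_matches_literal_refit_oracle(self, refit):
        """Every fold independently refit from scratch by a plain loop."""
        rng = np.random.default_rng(11)
        X = np.vstack([
            rng.normal(0, 1.0, size=(12, 5)),
            rng.normal(0.9, 1.0, size=(14, 5)),
        ])
        labels = np.array(["healthy"] * 12 + ["tumor"] * 14)
        ft = table(X, list(labels))
        rep = loo_cross_validate(ft, k=3, refit_pca_per_fold=refit)

        preds, posts = [], []
        full_pca = fit_pca(ft)
        for i in range(len(labels)):
            mask = np.ones(len(labels), bool)
            mask[i] = False
            sub = table(X[mask], list(labels[mask]))
            pca = fit_pca(sub) if refit else full_pca
            lda = fit_lda(project(pca, sub, k=3), list(labels[mask]))
            one = table(X[i : i + 1], [labels[i]])
            lab, post = predict_lda(lda, project(pca, one, k=3))
            preds.append(lab[0])
            posts.append(post[0])
        assert list(rep.per_sample["predicted"]) == preds
        np.testing.assert_allclose(rep.per_sample["posterior_tumor"], posts,
                                   atol=1e-12)

    def test_mixed_rows_excluded_from_metrics(self):
        ft = self.separated_table(n=6)
        X = np.vstack([ft.values.to_numpy(), [[25.0] * 4]])
        labels = list(ft.labels) + ["mixed"]
        rep = loo_cross_validate(table(X, labels))
        assert rep.n == 12  # the mixed row does not enter the confusion counts

    def test_deterministic(self):
        ft = self.separated_table(seed=13, gap=1.0)
        a = loo_cross_validate(ft)
        b = loo_cross_validate(ft)
        assert a.to_dict() == b.to_dict()

    def test_too_small_input_rejected(self):
        with pytest.raises(InsufficientSampleError):
            loo_cross_validate(table(np.ones((3, 2)),
                                     ["healthy", "tumor", "tumor"]))
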