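"""Gaussian mixture: density oracles, EM recovery, structure/BIC selection."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from replicall.gmm import (ALL_STRUCTURES, CovShape, CovTying, GMMParams,
                           all_covariate_subsets, fit_gmm, gmm_density,
                           select_gmm)
from conftest import make_site_table


def _params_1d(p, means, variances):
    K = len(p)
    return GMMParams(p=np.asarray(p, float),
                     means=np.asarray(means, float).reshape(K, 1),
                     covariances=np.asarray(variances, float).reshape(K, 1, 1),
                     structure=(CovShape.FULL, CovTying.PER_CLASS))


class TestDensity:
    def test_standard_normal_at_zero(self):
        params = _params_1d([1, 0, 0], [0, 0, 0], [1, 1, 1])
        assert gmm_density(params, [[0.0]]) == pytest.approx(0.3989423)

    def test_identical_components_equal_single(self):
        params = _params_1d([0.5, 0.5], [2.0, 2.0], [3.0, 3.0])
        x = np.array([[1.7]])
        single = multivariate_normal.pdf(x, mean=[2.0], cov=3.0)
        assert gmm_density(params, x) == pytest.approx(float(single))

    def test_matches_bruteforce_summation_2d(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(3))
        means = rng.normal(size=(3, 2))
        covs = []
        for _ in range(3):
            A = rng.normal(size=(2, 2))
            covs.append(A @ A.T + np.eye(2))
        params = GMMParams(p=p, means=means, covariances=np.stack(covs),
                           structure=(CovShape.FULL, CovTying.PER_CLASS))
        X = rng.normal(size=(10, 2))
        expected = sum(p[r] * multivariate_normal.pdf(X, means[r], covs[r])
                       for r in range(3))
        np.testing.assert_allclose(gmm_density(params, X), expected,
                                   rtol=1e-10)

    def test_singular_covariance_names_class(self):
        params = _params_1d([0.6, 0.4], [0.0, 1.0], [1.0, 0.0])
        with pytest.raises(np.linalg.LinAlgError, match="class 1"):
            gmm_density(params, [[0.0]])

    def test_dimension_mismatch(self):
        params = _params_1d([1.0], [0.0], [1.0])
        with pytest.raises(ValueError):
            gmm_density(params, [[0.0, 1.0]])


def _blobs(n, seed, means, weights, noise_dim=0):
    rng = np.random.default_rng(seed)
    z = rng.choice(len(weights), size=n, p=weights)
    X = rng.normal(size=(n, means.shape[1])) + means[z]
    if noise_dim:
        X = np.column_stack([X, rng.normal(size=(n, noise_dim))])
    return X, z


class TestFit:
    def test_single_component_recovers_sample_moments(self):
        rng = np.random.default_rng(1)
        X = rng.normal(loc=[2.0, -1.0], scale=[1.5, 0.5], size=(2000, 2))
        fit, params = fit_gmm(X, covariate_set=("a", "b"), n_classes=1,
                              n_starts=1, seed=2, standardize=False)
        np.testing.assert_allclose(params.means[0], X.mean(axis=0),
                                   atol=1e-6)
        np.testing.assert_allclose(params.covariances[0],
                                   np.cov(X.T, bias=True), atol=1e-4)

    def test_separated_components_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        means = np.array([[0, 0], [10, 0], [0, 10]], float)
        X, z = _blobs(30_000, 3, means, [0.2, 0.5, 0.3])
        fit, params = fit_gmm(X, covariate_set=("a", "b"), n_starts=3, seed=4)
        assert adjusted_rand_score(z, fit.assignment) > 0.99
        assert np.all(np.diff(fit.trace) >= -1e-6)
        np.testing.assert_allclose(fit.posteriors.sum(axis=1), 1.0,
                                   atol=1e-9)
        assert params.p.sum() == pytest.approx(1.0)

    def test_agrees_with_reference_em_implementation(self):
        # independent oracle: sklearn's GaussianMixture on easy data
        from sklearn.mixture import GaussianMixture
        means = np.array([[0.0], [8.0]])
        X, _ = _blobs(5000, 5, means, [0.4, 0.6])
        fit, _ = fit_gmm(X, covariate_set=("a",), n_classes=2, n_starts=3,
                         seed=6, standardize=False)
        ref = GaussianMixture(2, covariance_type="full", n_init=3,
                              random_state=0, tol=1e-8).fit(X)
        assert fit.loglik / len(X) == pytest.approx(
            ref.score(X), abs=1e-3)

    def test_structure_search_prefers_shared_when_true(self):
        # equal spherical covariances: the BIC-best structure is not FULL
        means = np.array([[0, 0], [6, 0], [0, 6]], float)
        X, _ = _blobs(8000, 7, means, [1 / 3, 1 / 3, 1 / 3])
        fit, params = fit_gmm(X, covariate_set=("a", "b"),
                              structure_search=True, n_starts=2, seed=8)
        assert params.structure[0] in (CovShape.SPHERICAL, CovShape.DIAGONAL)

    def test_determinism(self):
        X, _ = _blobs(2000, 9, np.array([[0.0], [5.0]]), [0.5, 0.5])
        f1, _ = fit_gmm(X, covariate_set=("a",), n_classes=2, seed=10,
                        n_starts=2)
        f2, _ = fit_gmm(X, covariate_set=("a",), n_classes=2, seed=10,
                        n_starts=2)
        assert f1.loglik == f2.loglik


class TestSelect:
    def test_single_candidate_trivially_selected(self, default_table):
        best, rows = select_gmm(default_table,
                                candidate_sets=[("ab_mean",)],
                                structure_search=False, n_starts=2, seed=11)
        assert best["covariates"] == ("ab_mean",)
        assert len(rows) == 1

    def test_noise_covariate_excluded(self):
        # two strongly informative dims + one pure-noise dim
        means = np.array([[0, 0], [10, 10], [20, 20]], float)
        X, _ = _blobs(10_000, 12, means, [0.2, 0.5, 0.3], noise_dim=1)
        table = make_site_table(
            np.ones((len(X), 3), dtype=np.int8),
            dp=X[:, 0], ab=X[:, 1], qd=X[:, 2])
        best, rows = select_gmm(table, structure_search=False, n_starts=3,
                                seed=13)
        assert "qd" not in best["covariates"]  # qd carries the noise column
        assert set(best["covariates"]) == {"dp_mean", "ab_mean"}

    def test_all_informative_covariables_jointly_selected(self):
        # every covariable separates the classes -> the full set wins BIC
        means = np.array([[0, 0, 0], [10, 10, 10], [20, 20, 20]], float)
        X, _ = _blobs(10_000, 15, means, [0.2, 0.5, 0.3])
        table = make_site_table(
            np.ones((len(X), 3), dtype=np.int8),
            dp=X[:, 0], ab=X[:, 1], qd=X[:, 2])
        best, _ = select_gmm(table, structure_search=False, n_starts=3,
                             seed=16)
        assert set(best["covariates"]) == {"dp_mean", "ab_mean", "qd"}

    def test_all_subsets_enumerated(self):
        assert len(all_covariate_subsets()) == 7


def test_all_six_structures_fit(default_table):
    sub = make_site_table(default_table.calls[:2000],
                          dp=default_table.df.dp_mean[:2000].to_numpy(),
                          ab=default_table.df.ab_mean[:2000].to_numpy(),
                          qd=default_table.df.qd[:2000].to_numpy())
    for struct in ALL_STRUCTURES:
        fit, params = fit_gmm(sub, structure=struct, n_starts=1, seed=14)
        assert np.isfinite(fit.bic)
        params.validate()
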