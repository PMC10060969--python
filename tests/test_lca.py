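"""Latent class model: likelihood oracles, EM recovery, BIC."""

import itertools

import numpy as np
import pytest

from replicall.lca import (LCAParams, align_classes, bic, fit_lca,
                           fit_lca_covariates, lca_covariate_search,
                           lca_loglik)
from conftest import make_site_table


def sample_lca(p, pi, n, seed):
    """Draw calls directly from an LCA model (class then replicate calls)."""
    rng = np.random.default_rng(seed)
    z = rng.choice(len(p), size=n, p=p)
    R = pi.shape[1]
    calls = np.empty((n, R), dtype=np.int8)
    for r in range(len(p)):
        m = z == r
        for j in range(R):
            calls[m, j] = rng.choice(3, size=m.sum(), p=pi[r, j])
    return calls, z


def brute_force_loglik(p, pi, calls):
    """Oracle: enumerate classes and multiply probabilities per site."""
    total = 0.0
    for row in calls:
        site = sum(p[r] * np.prod([pi[r, j, row[j]]
                                   for j in range(len(row))])
                   for r in range(len(p)))
        total += np.log(site)
    return total


class TestLoglik:
    def test_uniform_pmfs_closed_form(self):
        n = 40
        calls = np.random.default_rng(0).integers(0, 3, size=(n, 3))
        params = LCAParams(p=np.array([0.5, 0.3, 0.2]),
                           pi=np.full((3, 3, 3), 1 / 3))
        assert lca_loglik(params, calls) == pytest.approx(-n * 3 * np.log(3))

    def test_single_class_multinomial_mle(self):
        # with p=(1,0,0), loglik is maximized at the empirical frequencies
        calls = np.random.default_rng(1).integers(0, 3, size=(200, 3))
        freq = np.stack([np.bincount(calls[:, j], minlength=3) / 200
                         for j in range(3)])
        pi = np.stack([freq, np.full((3, 3), 1 / 3), np.full((3, 3), 1 / 3)])
        params = LCAParams(p=np.array([1.0, 0.0, 0.0]), pi=pi)
        ll_mle = lca_loglik(params, calls)
        rng = np.random.default_rng(2)
        for _ in range(20):
            other = rng.dirichlet(np.ones(3), size=3)
            params2 = LCAParams(p=np.array([1.0, 0.0, 0.0]),
                                pi=np.stack([other, pi[1], pi[2]]))
            assert lca_loglik(params2, calls) <= ll_mle + 1e-9

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(3)
        p = rng.dirichlet(np.ones(3))
        pi = rng.dirichlet(np.ones(3), size=(3, 3))
        calls = rng.integers(0, 3, size=(20, 3))
        params = LCAParams(p=p, pi=pi)
        assert lca_loglik(params, calls) == pytest.approx(
            brute_force_loglik(p, pi, calls))


class TestFit:
    def test_always_agree_data_recovers_degenerate_optimum(self):
        rng = np.random.default_rng(4)
        cats = rng.choice(3, size=3000, p=[0.05, 0.60, 0.35])
        calls = np.tile(cats[:, None], (1, 3))
        fit, params = fit_lca(calls, n_starts=20, seed=5)
        ref_p = np.array([0.05, 0.60, 0.35])
        ref_pi = np.stack([np.tile(np.eye(3)[t], (3, 1)) for t in range(3)])
        perm = align_classes(params.p, params.pi, ref_p, ref_pi)
        emp = np.bincount(cats, minlength=3) / len(cats)
        assert np.abs(params.p[perm] - emp).max() < 0.01
        assert np.abs(params.pi[perm] - ref_pi).max() < 0.02

    def test_parameter_recovery_from_known_model(self):
        p = np.array([0.10, 0.55, 0.35])
        pi = np.stack([
            np.tile([0.80, 0.15, 0.05], (3, 1)),
            np.tile([0.05, 0.90, 0.05], (3, 1)),
            np.tile([0.02, 0.08, 0.90], (3, 1)),
        ])
        calls, _ = sample_lca(p, pi, n=50_000, seed=6)
        fit, params = fit_lca(calls, n_starts=20, seed=7)
        perm = align_classes(params.p, params.pi, p, pi)
        assert np.abs(params.p[perm] - p).max() < 0.02
        assert np.abs(params.pi[perm] - pi).max() < 0.02
        # MLE dominates the generating parameters
        assert fit.loglik >= lca_loglik(LCAParams(p=p, pi=pi), calls)
        # EM monotonicity on the winning start
        assert np.all(np.diff(fit.trace) >= -1e-7)

    def test_deterministic_under_seed(self):
        calls, _ = sample_lca(np.array([0.2, 0.5, 0.3]),
                              np.random.default_rng(8).dirichlet(
                                  np.ones(3), size=(3, 3)), 500, 9)
        f1, p1 = fit_lca(calls, n_starts=5, seed=11)
        f2, p2 = fit_lca(calls, n_starts=5, seed=11)
        assert f1.loglik == f2.loglik
        np.testing.assert_array_equal(p1.p, p2.p)

    def test_posterior_rows_sum_to_one(self, default_table):
        fit, _ = fit_lca(default_table.calls, n_starts=5, seed=1)
        np.testing.assert_allclose(fit.posteriors.sum(axis=1), 1.0,
                                   atol=1e-10)
        assert fit.class_proportions.sum() == pytest.approx(1.0)


class TestBic:
    def test_arithmetic(self):
        assert bic(-1000, 10, 1000) == pytest.approx(2069.0775, abs=1e-3)
        assert bic(-500, 0, 77) == 1000.0

    def test_extra_null_parameter_raises_bic_by_log_n(self):
        ll, n = -1234.5, 500
        assert bic(ll, 6, n) - bic(ll, 5, n) == pytest.approx(np.log(n))


class TestCovariatePriors:
    def test_constant_covariate_nests_plain_lca(self):
        calls, _ = sample_lca(
            np.array([0.15, 0.55, 0.30]),
            np.stack([np.tile([0.8, 0.15, 0.05], (3, 1)),
                      np.tile([0.05, 0.9, 0.05], (3, 1)),
                      np.tile([0.05, 0.05, 0.9], (3, 1))]), 5000, 12)
        z = np.zeros((5000, 1))  # no information in the covariate
        fit_cov, _ = fit_lca_covariates(calls, z, n_starts=8, seed=13)
        fit_plain, _ = fit_lca(calls, n_starts=8, seed=13)
        assert fit_cov.loglik == pytest.approx(fit_plain.loglik, abs=0.5)

    def test_covariate_dependent_priors_win_bic(self):
        # generate with a real covariate effect on the class prior
        rng = np.random.default_rng(14)
        n = 20_000
        z = rng.normal(size=(n, 1))
        logits = np.column_stack([np.zeros(n), 1.5 * z[:, 0],
                                  -1.5 * z[:, 0]])
        pr = np.exp(logits)
        pr /= pr.sum(axis=1, keepdims=True)
        cls = np.array([rng.choice(3, p=pi) for pi in pr])
        pi = np.stack([np.tile([0.85, 0.10, 0.05], (3, 1)),
                       np.tile([0.05, 0.90, 0.05], (3, 1)),
                       np.tile([0.05, 0.10, 0.85], (3, 1))])
        calls = np.empty((n, 3), dtype=np.int8)
        for r in range(3):
            m = cls == r
            for j in range(3):
                calls[m, j] = rng.choice(3, size=m.sum(), p=pi[r, j])
        fit_cov, params = fit_lca_covariates(calls, z, n_starts=6, seed=15,
                                             max_iter=300)
        fit_plain, _ = fit_lca(calls, n_starts=10, seed=15)
        assert fit_cov.bic < fit_plain.bic
        assert np.all(np.diff(fit_cov.trace) >= -1e-6)

    def test_priors_are_proper_probabilities(self, default_table):
        fit, params = fit_lca_covariates(
            default_table.calls, default_table.covariates(("ab_mean",)),
            n_starts=2, seed=16, max_iter=150)
        pr = params.priors(default_table.covariates(("ab_mean",)))
        assert np.all(pr > 0)
        np.testing.assert_allclose(pr.sum(axis=1), 1.0, atol=1e-12)


def test_pair_with_true_effects_wins_bic_search():
    """Univariate-then-pairs protocol on priors driven by two covariables.

    With class priors genuinely depending on both AB and QD (MQ pure
    noise), the AB+QD pair attains the lowest BIC among the six candidate
    sets."""
    rng = np.random.default_rng(18)
    n = 20_000
    Z = rng.normal(size=(n, 3))  # columns play AB, QD, MQ
    logits = np.column_stack([np.zeros(n),
                              1.3 * Z[:, 0] + 1.3 * Z[:, 1],
                              -1.3 * Z[:, 0] + 1.3 * Z[:, 1]])
    pr = np.exp(logits - logits.max(axis=1, keepdims=True))
    pr /= pr.sum(axis=1, keepdims=True)
    u = rng.random(n)
    cls = (u[:, None] > pr.cumsum(axis=1)).sum(axis=1)
    pi = np.stack([np.tile([0.80, 0.15, 0.05], (3, 1)),
                   np.tile([0.05, 0.90, 0.05], (3, 1)),
                   np.tile([0.05, 0.15, 0.80], (3, 1))])
    calls = np.empty((n, 3), dtype=np.int8)
    for r in range(3):
        m = cls == r
        for j in range(3):
            calls[m, j] = rng.choice(3, size=m.sum(), p=pi[r, j])
    table = make_site_table(calls, ab=Z[:, 0], qd=Z[:, 1], mq=Z[:, 2])
    best, rows = lca_covariate_search(table, n_starts=6, seed=19,
                                      max_iter=200, short_iter=20)
    assert set(best["covariates"]) == {"ab_mean", "qd"}


def test_covariate_search_returns_all_sets(default_table):
    sub = make_site_table(default_table.calls[:3000],
                          ab=default_table.df.ab_mean[:3000].to_numpy(),
                          qd=default_table.df.qd[:3000].to_numpy(),
                          mq=default_table.df.mq[:3000].to_numpy())
    best, rows = lca_covariate_search(sub, n_starts=2, max_iter=100, seed=17)
    assert {r["covariates"] for r in rows} == {
        ("ab_mean",), ("qd",), ("mq",),
        ("ab_mean", "qd"), ("ab_mean", "mq"), ("qd", "mq")}
    assert best["bic"] == min(r["bic"] for r in rows)
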