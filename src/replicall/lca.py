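"""Latent class analysis of replicate genotype calls.

The model: each site belongs to one of ``n_classes`` latent classes with
prevalence ``p_r``; given the class, the replicate calls ``Y_1 .. Y_R`` are
independent categorical variables with class- and replicate-specific
probability mass functions ``pi[r, j, k]``.  The marginal likelihood of one
site's call pattern is therefore

    P(Y_i) = sum_r  p_r * prod_j pi[r, j, Y_ij]

The covariate extension replaces the shared prevalences with site-specific
priors through a multinomial-logit link on standardized covariables (class 0
as the reference).  Both variants are fitted by multi-start EM; model fit is
compared with BIC.  Because the no-covariate likelihood depends on the data
only through the 3^R pattern counts, its EM runs on the collapsed
contingency table and is fast at any sample size.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, softmax

from .types import ClusterFit, SiteTable

logger = logging.getLogger(__name__)

N_CATEGORIES = 3


@dataclass
class LCAParams:
    """Class prevalences and class-conditional call distributions."""

    p: np.ndarray        # (n_classes,)
    pi: np.ndarray       # (n_classes, n_replicates, N_CATEGORIES)

    def validate(self) -> None:
        if abs(self.p.sum() - 1) > 1e-9 or (self.p < 0).any():
            raise ValueError("p must be a probability vector")
        if (np.abs(self.pi.sum(axis=2) - 1) > 1e-9).any() or (self.pi < 0).any():
            raise ValueError("every pi[r, j] must be a probability vector")


@dataclass
class LCACovariateParams:
    """Call distributions plus multinomial-logit prior coefficients.

    ``beta`` has shape (n_classes - 1, d + 1): intercept plus one
    coefficient per (standardized) covariable, class 0 as reference.
    ``covariate_names``, ``center`` and ``scale`` record the standardization
    so priors can be evaluated on new data.
    """

    pi: np.ndarray
    beta: np.ndarray
    covariate_names: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray

    def priors(self, covariates: np.ndarray) -> np.ndarray:
        z = (np.asarray(covariates, dtype=float) - self.center) / self.scale
        X = np.column_stack([np.ones(len(z)), z])
        logits = np.column_stack([np.zeros(len(z)), X @ self.beta.T])
        return softmax(logits, axis=1)


def bic(loglik: float, n_params: int, n: int) -> float:
    """Bayesian information criterion, -2*loglik + k*log(n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return -2.0 * loglik + n_params * np.log(n)


# ---------------------------------------------------------------------------
# pattern utilities


def _pattern_index(calls: np.ndarray) -> np.ndarray:
    calls = np.asarray(calls, dtype=np.int64)
    R = calls.shape[1]
    return calls @ (N_CATEGORIES ** np.arange(R))


def _all_patterns(R: int) -> np.ndarray:
    # column-reversed so that _pattern_index(_all_patterns(R)) == arange(3**R)
    return np.array(list(itertools.product(range(N_CATEGORIES), repeat=R)),
                    dtype=np.int64)[:, ::-1]


def _pattern_log_prob(pi: np.ndarray, patterns: np.ndarray) -> np.ndarray:
    """(n_patterns, n_classes) log prod_j pi[r, j, pattern_j]."""
    n_classes, R, _ = pi.shape
    with np.errstate(divide="ignore"):
        logpi = np.log(pi)
    out = np.zeros((len(patterns), n_classes))
    for j in range(R):
        out += logpi[:, j, patterns[:, j]].T
    return out


def lca_loglik(params: LCAParams, calls: np.ndarray) -> float:
    """Total log-likelihood of the call patterns under the model."""
    params.validate()
    calls = np.asarray(calls)
    patterns = _all_patterns(calls.shape[1])
    with np.errstate(divide="ignore"):
        logp = np.log(params.p)
    lp = _pattern_log_prob(params.pi, patterns) + logp  # (m, r)
    site_ll = logsumexp(lp, axis=1)[_pattern_index(calls)]
    if np.isneginf(site_ll).any():
        logger.warning("pattern(s) with zero likelihood under all classes")
    return float(site_ll.sum())


# ---------------------------------------------------------------------------
# EM without covariables (runs on collapsed pattern counts)


def _em_lca(counts: np.ndarray, patterns: np.ndarray, p0: np.ndarray,
            pi0: np.ndarray, tol: float, max_iter: int):
    p, pi = p0.copy(), pi0.copy()
    n = counts.sum()
    R = patterns.shape[1]
    trace = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        lp = _pattern_log_prob(pi, patterns) + np.log(np.maximum(p, 1e-300))
        norm = logsumexp(lp, axis=1)
        ll = float(counts @ norm)
        trace.append(ll)
        resp = np.exp(lp - norm[:, None])          # (m, r)
        w = resp * counts[:, None]                  # weighted responsibilities
        class_mass = w.sum(axis=0)
        p = class_mass / n
        for j in range(R):
            for k in range(N_CATEGORIES):
                sel = patterns[:, j] == k
                pi[:, j, k] = w[sel].sum(axis=0)
        pi /= np.maximum(class_mass[:, None, None], 1e-300)
        if ll - prev < tol * max(1.0, abs(ll)) and np.isfinite(prev):
            converged = True
            break
        prev = ll
    return p, pi, np.asarray(trace), converged


def fit_lca(calls: np.ndarray, n_classes: int = 3, n_starts: int = 50,
            seed: int = 0, tol: float = 1e-8, max_iter: int = 1000
            ) -> tuple[ClusterFit, LCAParams]:
    """Multi-start EM for the no-covariate latent class model."""
    calls = np.asarray(calls)
    n, R = calls.shape
    if n < 30:
        raise ValueError("need at least 30 sites")
    patterns = _all_patterns(R)
    idx = _pattern_index(calls)
    counts_full = np.bincount(idx, minlength=len(patterns)).astype(float)
    observed = counts_full > 0  # unobserved patterns carry no likelihood
    patterns_obs = patterns[observed]
    counts = counts_full[observed]

    rng = np.random.default_rng(seed)
    results = []
    for _ in range(n_starts):
        p0 = rng.dirichlet(np.ones(n_classes))
        pi0 = rng.dirichlet(1.1 * np.ones(N_CATEGORIES),
                            size=(n_classes, R))
        results.append(_em_lca(counts, patterns_obs, p0, pi0, tol, max_iter))
    lls = np.array([r[2][-1] for r in results])
    best = int(np.argmax(lls))  # first best index under ties
    p, pi, trace, converged = results[best]
    best_frac = float(np.mean(lls >= lls[best] - 1e-4))

    params = LCAParams(p=p, pi=pi)
    lp = _pattern_log_prob(pi, patterns_obs) + np.log(np.maximum(p, 1e-300))
    norm = logsumexp(lp, axis=1)
    resp_pattern = np.exp(lp - norm[:, None])
    pattern_pos = np.cumsum(observed) - 1  # full index -> observed row
    posteriors = resp_pattern[pattern_pos[idx]]
    n_params = (n_classes - 1) + n_classes * R * (N_CATEGORIES - 1)
    ll = float(counts @ norm)
    fit = ClusterFit(model="lca", posteriors=posteriors, loglik=ll,
                     n_params=n_params, bic=bic(ll, n_params, n),
                     converged=converged, n_starts=n_starts,
                     best_start_fraction=best_frac, params=params,
                     trace=trace)
    return fit, params


# ---------------------------------------------------------------------------
# EM with covariate-dependent priors


def _lse(a: np.ndarray) -> np.ndarray:
    """Row-wise logsumexp (faster than the scipy generic for small widths)."""
    m = a.max(axis=1, keepdims=True)
    return (m + np.log(np.exp(a - m).sum(axis=1, keepdims=True)))


def _logit_newton(X: np.ndarray, resp: np.ndarray, beta: np.ndarray,
                  n_steps: int = 1, ridge: float = 1e-8) -> np.ndarray:
    """Improve the multinomial-logit Q-function with damped Newton steps.

    Soft labels are the responsibilities; step halving guarantees the
    expected complete-data log-likelihood does not decrease, and the ridge
    grows when quasi-separation makes the Hessian singular.
    """
    n, d1 = X.shape
    K = resp.shape[1]

    def q_value(b):
        logits = np.column_stack([np.zeros(n), X @ b.T])
        return float(np.sum(resp * (logits - _lse(logits))))

    for _ in range(n_steps):
        logits = np.column_stack([np.zeros(n), X @ beta.T])
        prior = softmax(logits, axis=1)
        grad = np.concatenate([X.T @ (resp[:, r] - prior[:, r])
                               for r in range(1, K)])
        H = np.zeros(((K - 1) * d1, (K - 1) * d1))
        for r in range(1, K):
            for s in range(1, K):
                wrs = prior[:, r] * ((r == s) - prior[:, s])
                H[(r - 1) * d1:r * d1, (s - 1) * d1:s * d1] = -(
                    X.T * wrs) @ X
        q0 = q_value(beta)
        lam = ridge
        for _ in range(6):
            try:
                step = np.linalg.solve(H - lam * np.eye(len(H)), -grad)
                break
            except np.linalg.LinAlgError:
                lam *= 100
                logger.info("ridge-stabilized logistic update (lambda=%g)",
                            lam)
        else:
            return beta
        step = step.reshape(K - 1, d1)
        scale = 1.0
        for _ in range(20):
            cand = beta + scale * step
            if q_value(cand) >= q0 - 1e-12:
                beta = cand
                break
            scale /= 2
    return beta


def fit_lca_covariates(calls: np.ndarray, covariates: np.ndarray,
                       covariate_names: tuple[str, ...] | None = None,
                       n_classes: int = 3, n_starts: int = 100,
                       seed: int = 0, tol: float = 1e-8,
                       max_iter: int = 1000, short_iter: int | None = None
                       ) -> tuple[ClusterFit, LCACovariateParams]:
    """Multi-start EM for the latent class model with a logistic prior link.

    This likelihood is multimodal and the global optimum is reached from
    only a minority of random starts, hence the large default start count.
    With ``short_iter`` set, an emEM-style two-phase schedule is used
    instead: every start runs ``short_iter`` EM iterations and only the best
    short run is iterated to convergence — much cheaper at large n for the
    same robustness.
    """
    calls = np.asarray(calls)
    Z = np.atleast_2d(np.asarray(covariates, dtype=float))
    if Z.shape[0] != calls.shape[0]:
        Z = Z.T
    if not np.isfinite(Z).all():
        raise ValueError("covariates must be finite")
    n, R = calls.shape
    d = Z.shape[1]
    if covariate_names is None:
        covariate_names = tuple(f"z{j}" for j in range(d))

    center = Z.mean(axis=0)
    scale = Z.std(axis=0)
    scale[scale == 0] = 1.0
    X = np.column_stack([np.ones(n), (Z - center) / scale])

    patterns = _all_patterns(R)
    idx = _pattern_index(calls)
    # one-hot call indicators per replicate, for matmul-based pi updates
    onehot = [np.equal(calls[:, j][:, None],
                       np.arange(N_CATEGORIES)[None]).astype(float)
              for j in range(R)]

    def em(beta0, pi0, n_iter):
        beta, pi = beta0.copy(), pi0.copy()
        trace = []
        prev = -np.inf
        converged = False
        resp = None
        for _ in range(n_iter):
            logits = np.column_stack([np.zeros(n), X @ beta.T])
            log_prior = logits - _lse(logits)
            lp = _pattern_log_prob(pi, patterns)[idx] + log_prior
            norm = _lse(lp)
            ll = float(norm.sum())
            trace.append(ll)
            resp = np.exp(lp - norm)
            if ll - prev < tol * max(1.0, abs(ll)) and np.isfinite(prev):
                converged = True
                break
            prev = ll
            # M-step: pi closed form, beta by damped Newton on Q
            mass = resp.sum(axis=0)
            for j in range(R):
                pi[:, j, :] = resp.T @ onehot[j]
            pi /= np.maximum(mass[:, None, None], 1e-300)
            beta = _logit_newton(X, resp, beta)
        return beta, pi, np.asarray(trace), converged, resp

    rng = np.random.default_rng(seed)
    results = []
    for _ in range(n_starts):
        beta0 = rng.normal(0, 0.5, size=(n_classes - 1, d + 1))
        pi0 = rng.dirichlet(1.1 * np.ones(N_CATEGORIES), size=(n_classes, R))
        results.append(em(beta0, pi0, short_iter or max_iter))
    lls = np.array([r[2][-1] for r in results])
    best = int(np.argmax(lls))
    best_frac = float(np.mean(lls >= lls[best] - 1e-4))
    if short_iter is not None:  # converge the winning short run
        beta, pi = results[best][0], results[best][1]
        beta, pi, tail, converged, resp = em(beta, pi, max_iter)
        trace = np.concatenate([results[best][2][:-1], tail])
        lls[best] = trace[-1]
    else:
        beta, pi, trace, converged, resp = results[best]

    params = LCACovariateParams(pi=pi, beta=beta,
                                covariate_names=tuple(covariate_names),
                                center=center, scale=scale)
    n_params = (n_classes - 1) * (d + 1) + n_classes * R * (N_CATEGORIES - 1)
    ll = float(lls[best])
    fit = ClusterFit(model="lca_cov", posteriors=resp, loglik=ll,
                     n_params=n_params, bic=bic(ll, n_params, n),
                     converged=converged, n_starts=n_starts,
                     best_start_fraction=best_frac, params=params,
                     trace=trace)
    return fit, params


def lca_covariate_search(table: SiteTable,
                         candidates: tuple[str, ...] = ("ab_mean", "qd", "mq"),
                         pairs: bool = True, n_classes: int = 3,
                         n_starts: int = 100, seed: int = 0,
                         **em_kw) -> tuple[dict, list[dict]]:
    """Univariate-then-pairs covariate selection by BIC.

    Fits one model per single covariable, then one per pair, and returns the
    BIC-best entry plus the full comparison list (each entry carries the
    covariate set, fit and BIC).
    """
    calls = table.calls
    sets = [(c,) for c in candidates]
    if pairs:
        sets += list(itertools.combinations(candidates, 2))
    rows = []
    for names in sets:
        fit, params = fit_lca_covariates(
            calls, table.covariates(names), covariate_names=names,
            n_classes=n_classes, n_starts=n_starts, seed=seed, **em_kw)
        rows.append({"covariates": names, "bic": fit.bic,
                     "loglik": fit.loglik, "fit": fit, "params": params})
    best = min(rows, key=lambda r: r["bic"])
    return best, rows


def align_classes(p_est: np.ndarray, pi_est: np.ndarray, p_ref: np.ndarray,
                  pi_ref: np.ndarray) -> np.ndarray:
    """Permutation of estimated classes minimizing L1 distance to reference.

    Returns ``perm`` such that ``p_est[perm]`` matches ``p_ref`` (handles EM
    label switching in parameter-recovery comparisons).
    """
    best_perm, best_cost = None, np.inf
    for perm in itertools.permutations(range(len(p_ref))):
        perm = np.asarray(perm)
        cost = (np.abs(p_est[perm] - p_ref).sum()
                + np.abs(pi_est[perm] - pi_ref).sum())
        if cost < best_cost:
            best_cost, best_perm = cost, perm
    return best_perm
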