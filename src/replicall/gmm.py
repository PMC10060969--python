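"""Multivariate Gaussian mixture on continuous quality covariables.

Three latent classes, density  f(x) = sum_r p_r * h(x | alpha_r)  with
``h`` multivariate normal.  Replicate calls are deliberately NOT inputs:
only the continuous covariables (by default mean read depth, mean allele
balance and QD) drive the clustering.  Fitted by multi-start EM with
k-means++-seeded initialization; the covariance structure (spherical /
diagonal / full, shared or per class) and the covariate set are selected by
BIC.
"""

from __future__ import annotations

import enum
import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import multivariate_normal
from sklearn.cluster import kmeans_plusplus

from .lca import bic
from .types import ClusterFit, SiteTable

logger = logging.getLogger(__name__)


class CovShape(enum.Enum):
    SPHERICAL = "spherical"
    DIAGONAL = "diagonal"
    FULL = "full"


class CovTying(enum.Enum):
    SHARED = "shared"
    PER_CLASS = "per_class"


ALL_STRUCTURES = tuple(itertools.product(CovShape, CovTying))

DEFAULT_COVARIATES = ("dp_mean", "ab_mean", "qd")


@dataclass
class GMMParams:
    """Mixing proportions, class means and covariances.

    ``center``/``scale`` record the per-column standardization applied
    before fitting (identity when fitted on the raw scale); means and
    covariances live in the standardized space and densities are reported
    on the input scale via the change-of-variables factor.
    """

    p: np.ndarray                      # (K,)
    means: np.ndarray                  # (K, d)
    covariances: np.ndarray            # (K, d, d), duplicated when shared
    structure: tuple[CovShape, CovTying]
    covariate_names: tuple[str, ...] = ()
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def validate(self) -> None:
        if abs(self.p.sum() - 1) > 1e-9 or (self.p < 0).any():
            raise ValueError("p must be a probability vector")
        for r, S in enumerate(self.covariances):
            if np.abs(S - S.T).max() > 1e-9:
                raise ValueError(f"covariance of class {r} not symmetric")
            if np.linalg.eigvalsh(S).min() <= 0:
                raise np.linalg.LinAlgError(
                    f"covariance of class {r} is singular")


def gmm_density(params: GMMParams, x: np.ndarray) -> np.ndarray:
    """Mixture density sum_r p_r * N(x; mu_r, Sigma_r) on the input scale."""
    params.validate()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != params.means.shape[1]:
        raise ValueError("x dimension does not match params")
    jac = 1.0
    if params.center is not None:
        x = (x - params.center) / params.scale
        jac = 1.0 / np.prod(params.scale)
    dens = np.zeros(len(x))
    for pr, mu, S in zip(params.p, params.means, params.covariances):
        dens += pr * multivariate_normal.pdf(x, mean=mu, cov=S)
    dens *= jac
    return dens if dens.size > 1 else float(dens[0])


def _n_cov_params(d: int, K: int, structure) -> int:
    shape, tying = structure
    per = {CovShape.SPHERICAL: 1, CovShape.DIAGONAL: d,
           CovShape.FULL: d * (d + 1) // 2}[shape]
    return per if tying is CovTying.SHARED else K * per


def _log_gauss(X: np.ndarray, mu: np.ndarray, S: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular
    d = X.shape[1]
    L = np.linalg.cholesky(S)
    diff = solve_triangular(L, (X - mu).T, lower=True)
    logdet = 2 * np.log(np.diag(L)).sum()
    return -0.5 * (d * np.log(2 * np.pi) + logdet + (diff ** 2).sum(axis=0))


def _regularize(S: np.ndarray, floor: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh(S)
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def _mstep_cov(X, resp, means, structure, floor):
    K = resp.shape[1]
    n, d = X.shape
    mass = resp.sum(axis=0)
    shape, tying = structure
    covs = np.empty((K, d, d))
    for r in range(K):
        diff = X - means[r]
        S = (resp[:, r][:, None] * diff).T @ diff / mass[r]
        covs[r] = S
    if tying is CovTying.SHARED:
        pooled = np.einsum("r,rij->ij", mass / n, covs)
        covs = np.repeat(pooled[None], K, axis=0)
    if shape is CovShape.DIAGONAL:
        covs = np.stack([np.diag(np.diag(S)) for S in covs])
    elif shape is CovShape.SPHERICAL:
        covs = np.stack([np.eye(d) * np.diag(S).mean() for S in covs])
    return np.stack([_regularize(S, floor) for S in covs])


class ComponentCollapse(RuntimeError):
    pass


def _em_gmm(X, K, structure, rng, tol, max_iter, floor):
    n, d = X.shape
    means, _ = kmeans_plusplus(X, n_clusters=K,
                               random_state=int(rng.integers(2 ** 31)))
    # initial responsibilities from nearest seed
    dist = ((X[:, None, :] - means[None]) ** 2).sum(axis=2)
    assign = dist.argmin(axis=1)
    resp = np.zeros((n, K))
    resp[np.arange(n), assign] = 1.0
    resp = np.clip(resp, 1e-3, None)
    resp /= resp.sum(axis=1, keepdims=True)

    p = resp.mean(axis=0)
    means = (resp.T @ X) / resp.sum(axis=0)[:, None]
    covs = _mstep_cov(X, resp, means, structure, floor)
    trace = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        log_r = np.stack([np.log(max(p[r], 1e-300))
                          + _log_gauss(X, means[r], covs[r])
                          for r in range(K)], axis=1)
        norm = logsumexp(log_r, axis=1)
        ll = float(norm.sum())
        trace.append(ll)
        resp = np.exp(log_r - norm[:, None])
        mass = resp.sum(axis=0)
        if (mass / n < 1e-6).any():
            raise ComponentCollapse
        p = mass / n
        means = (resp.T @ X) / mass[:, None]
        covs = _mstep_cov(X, resp, means, structure, floor)
        if ll - prev < tol * max(1.0, abs(ll)) and np.isfinite(prev):
            converged = True
            break
        prev = ll
    return p, means, covs, resp, np.asarray(trace), converged


def fit_gmm(table_or_X, covariate_set: tuple[str, ...] = DEFAULT_COVARIATES,
            n_classes: int = 3,
            structure: tuple[CovShape, CovTying] = (CovShape.FULL,
                                                    CovTying.PER_CLASS),
            structure_search: bool = False, n_starts: int = 5, seed: int = 0,
            tol: float = 1e-8, max_iter: int = 500, reg_floor: float = 1e-6,
            standardize: bool = True) -> tuple[ClusterFit, GMMParams]:
    """Multi-start EM Gaussian mixture on the chosen covariables.

    With ``structure_search`` the six covariance structures are each fitted
    and compared by BIC; otherwise only ``structure`` is fitted.  Collapsed
    components (mixing weight under 1e-6) trigger a logged restart.
    Covariables are z-scored before fitting by default, which puts the
    likelihoods of different covariate sets on one comparable scale (the
    selection heuristic of :func:`select_gmm`).
    """
    if isinstance(table_or_X, SiteTable):
        X = table_or_X.covariates(covariate_set)
        names = tuple(covariate_set)
    else:
        X = np.atleast_2d(np.asarray(table_or_X, dtype=float))
        names = tuple(covariate_set) if covariate_set else ()
    n = len(X)
    if n < 50:
        raise ValueError("need at least 50 sites")
    if not np.isfinite(X).all():
        raise ValueError("covariables must be finite")
    center = scale = None
    if standardize:
        center = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        X = (X - center) / scale

    structures = ALL_STRUCTURES if structure_search else (structure,)
    best = None
    for struct in structures:
        rng = np.random.default_rng(seed)
        lls, fits = [], []
        attempts = 0
        while len(fits) < n_starts and attempts < 3 * n_starts:
            attempts += 1
            try:
                fits.append(_em_gmm(X, n_classes, struct, rng, tol,
                                    max_iter, reg_floor))
            except ComponentCollapse:
                logger.info("GMM component collapsed (%s); restarting",
                            struct)
                continue
        if not fits:
            continue
        lls = np.array([f[4][-1] for f in fits])
        b = int(np.argmax(lls))
        p, means, covs, resp, trace, converged = fits[b]
        k = (n_classes - 1) + n_classes * X.shape[1] + _n_cov_params(
            X.shape[1], n_classes, struct)
        ll = float(lls[b])
        fit = ClusterFit(
            model=f"gmm[{struct[0].value},{struct[1].value}]",
            posteriors=resp, loglik=ll, n_params=k, bic=bic(ll, k, n),
            converged=converged, n_starts=len(fits),
            best_start_fraction=float(np.mean(lls >= ll - 1e-4)),
            params=GMMParams(p=p, means=means, covariances=covs,
                             structure=struct, covariate_names=names,
                             center=center, scale=scale),
            trace=trace)
        if best is None or fit.bic < best.bic:
            best = fit
    if best is None:
        raise RuntimeError("all GMM starts collapsed")
    return best, best.params


def all_covariate_subsets(names=DEFAULT_COVARIATES):
    return [tuple(c) for k in range(1, len(names) + 1)
            for c in itertools.combinations(names, k)]


def select_gmm(table: SiteTable, candidate_sets=None, n_classes: int = 3,
               structure_search: bool = True, n_starts: int = 5,
               seed: int = 0, **em_kw) -> tuple[dict, list[dict]]:
    """BIC selection over covariate sets (and covariance structures).

    All candidate sets are fitted on the same ``n`` rows so the BICs share
    the sample-size term; comparing likelihoods across covariate sets of
    different dimension remains a heuristic (densities live in different
    spaces) and the full comparison table is returned so the ranking can be
    inspected.
    """
    if candidate_sets is None:
        candidate_sets = all_covariate_subsets()
    rows = []
    for cs in candidate_sets:
        fit, params = fit_gmm(table, covariate_set=cs, n_classes=n_classes,
                              structure_search=structure_search,
                              n_starts=n_starts, seed=seed, **em_kw)
        rows.append({"covariates": tuple(cs), "bic": fit.bic,
                     "loglik": fit.loglik, "fit": fit, "params": params})
    best = min(rows, key=lambda r: r["bic"])
    return best, rows
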