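"""Kamila-style k-means for mixed continuous/categorical site features.

Continuous covariables (mean read depth capped at ``dp_cap``, mean allele
balance, QD — z-scored after capping) contribute through a radial
kernel-density model of spherical clusters: the density of the Euclidean
distance between a point and its cluster centroid is estimated with a
Gaussian KDE and sites are assigned by maximum log-density.  Categorical
variables (the three replicate calls and the difficult-region flag)
contribute a multinomial log-likelihood.  Neither domain is weighted a
priori; the assignment score is the sum of the two log terms.

Iteration: assign -> recompute centroids, category frequencies and the KDE.
The objective (sum of per-site best scores after the assignment step) is
tracked; the iteration stops when assignments stop changing, the iteration
cap is hit, or the objective would decrease, in which case the previous
state is kept — so the recorded objective trace is non-decreasing by
construction.  The KDE refit makes this clustering, like the reference
algorithm, sensitive to extreme read-depth outliers; hence the depth cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .lca import bic
from .types import ClusterFit, SiteTable
from .vcf_io import cap_dp

logger = logging.getLogger(__name__)

DEFAULT_CONTINUOUS = ("dp_mean", "ab_mean", "qd")

_KDE_MAX_SAMPLE = 4000
_GRID_SIZE = 512
_DENSITY_FLOOR = 1e-300
_SMOOTHING = 0.5  # additive smoothing per categorical level


@dataclass
class KamilaParams:
    centroids: np.ndarray                 # (K, d_cont), z-scored space
    theta: list[np.ndarray]               # per categorical var: (K, n_levels)
    kde_grid: np.ndarray                  # radial distance support grid
    kde_density: np.ndarray               # density on the grid
    kde_bandwidth: float
    objective_trace: np.ndarray
    continuous_names: tuple[str, ...] = ()
    center: np.ndarray | None = None
    scale: np.ndarray | None = None


def _radial_log_density(distances: np.ndarray, rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray, float]:
    """Gaussian-kernel KDE of min-distances on a grid (Silverman bandwidth)."""
    sample = distances
    if len(sample) > _KDE_MAX_SAMPLE:
        sample = rng.choice(sample, _KDE_MAX_SAMPLE, replace=False)
    if np.std(sample) < 1e-12:
        sample = sample + rng.normal(0, 1e-9, size=len(sample))
    kde = gaussian_kde(sample, bw_method="silverman")
    grid = np.linspace(0.0, max(float(distances.max()) * 1.05, 1e-6),
                       _GRID_SIZE)
    dens = np.maximum(kde(grid), _DENSITY_FLOOR)
    return grid, dens, float(kde.factor * np.std(sample, ddof=1))


def _categorical_matrix(table: SiteTable) -> tuple[np.ndarray, list[int]]:
    """Stack replicate calls + difficult flag as integer level codes."""
    cols = [table.calls[:, j] for j in range(table.n_replicates)]
    cols.append(table.df["difficult"].to_numpy().astype(np.int8))
    mat = np.stack(cols, axis=1).astype(np.int64)
    n_levels = [3] * table.n_replicates + [2]
    return mat, n_levels


def fit_kamila(table: SiteTable, n_classes: int = 3, n_starts: int = 10,
               seed: int = 0, max_iter: int = 50, dp_cap: float | None = 150,
               continuous: tuple[str, ...] = DEFAULT_CONTINUOUS
               ) -> tuple[ClusterFit, KamilaParams]:
    """Fit the mixed-type clustering; best of ``n_starts`` by objective."""
    if dp_cap is not None and "dp_mean" in continuous:
        table = cap_dp(table, dp_cap)
    V = table.covariates(continuous)
    center = V.mean(axis=0)
    scale = V.std(axis=0)
    informative = scale > 1e-12
    if not informative.all():
        logger.info("kamila: dropping zero-variance continuous columns %s",
                    [c for c, ok in zip(continuous, informative) if not ok])
    V = (V[:, informative] - center[informative]) / scale[informative]
    use_continuous = V.shape[1] > 0
    cat, n_levels = _categorical_matrix(table)
    n = len(table)
    K = n_classes

    master = np.random.default_rng(seed)
    best = None
    final_objectives = []
    for start in range(n_starts):
        rng = np.random.default_rng(master.integers(2 ** 31))
        if use_continuous:
            from sklearn.cluster import kmeans_plusplus
            centroids, _ = kmeans_plusplus(
                V, n_clusters=K, random_state=int(rng.integers(2 ** 31)))
        else:
            centroids = np.zeros((K, 1))
        theta = [np.full((K, L), 1.0 / L) for L in n_levels]
        grid = dens = None
        bw = 0.0
        assign = None
        trace = []
        state = None
        for _ in range(max_iter):
            scores = np.zeros((n, K))
            if use_continuous:
                dist = np.sqrt(((V[:, None, :] - centroids[None]) ** 2)
                               .sum(axis=2))
                if grid is None:
                    grid, dens, bw = _radial_log_density(dist.min(axis=1), rng)
                # point density of a spherically symmetric cluster: the
                # distance density divided by the surface factor r^(d-1)
                logdens = np.log(np.maximum(
                    np.interp(dist, grid, dens, right=_DENSITY_FLOOR),
                    _DENSITY_FLOOR))
                if V.shape[1] > 1:
                    logdens -= (V.shape[1] - 1) * np.log(
                        np.maximum(dist, 1e-12))
                scores += logdens
            for v, th in enumerate(theta):
                scores += np.log(th[:, cat[:, v]]).T
            new_assign = scores.argmax(axis=1)
            objective = float(scores.max(axis=1).sum())
            if trace and objective < trace[-1] - 1e-9:
                break  # keep the previous (better) state
            trace.append(objective)
            state = (centroids.copy(), [t.copy() for t in theta],
                     grid, dens, bw, new_assign)
            if assign is not None and (new_assign == assign).all():
                assign = new_assign
                break
            assign = new_assign
            # update step
            for r in range(K):
                mask = assign == r
                if not mask.any():
                    far = dist.min(axis=1).argmax() if use_continuous else \
                        rng.integers(n)
                    logger.info("kamila: re-seeding empty cluster %d", r)
                    assign[far] = r
                    mask = assign == r
                if use_continuous:
                    centroids[r] = V[mask].mean(axis=0)
                for v, L in enumerate(n_levels):
                    counts = np.bincount(cat[mask, v], minlength=L) + _SMOOTHING
                    theta[v][r] = counts / counts.sum()
            if use_continuous:
                dist = np.sqrt(((V[:, None, :] - centroids[None]) ** 2)
                               .sum(axis=2))
                grid, dens, bw = _radial_log_density(dist.min(axis=1), rng)
        centroids, theta, grid, dens, bw, assign = state
        result = (trace[-1], start, centroids, theta, grid, dens, bw,
                  assign.copy(), np.asarray(trace))
        final_objectives.append(trace[-1])
        if best is None or result[0] > best[0]:
            best = result

    obj, _, centroids, theta, grid, dens, bw, assign, trace = best
    final_objectives = np.asarray(final_objectives)
    posteriors = np.zeros((n, K))
    posteriors[np.arange(n), assign] = 1.0
    n_params = (K * (V.shape[1] if use_continuous else 0)
                + K * sum(L - 1 for L in n_levels))
    params = KamilaParams(centroids=centroids, theta=theta, kde_grid=grid
                          if grid is not None else np.zeros(0),
                          kde_density=dens if dens is not None else np.zeros(0),
                          kde_bandwidth=bw, objective_trace=trace,
                          continuous_names=tuple(
                              c for c, ok in zip(continuous, informative)
                              if ok),
                          center=center, scale=scale)
    fit = ClusterFit(model="kamila", posteriors=posteriors, loglik=obj,
                     n_params=n_params, bic=bic(obj, n_params, n),
                     converged=True, n_starts=n_starts,
                     best_start_fraction=float(
                         np.mean(final_objectives >= obj - 1e-4)),
                     params=params,
                     trace=trace)
    return fit, params
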