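"""Unsupervised random-forest clustering of sites.

The classic recipe: build a synthetic contrast dataset by resampling every
feature column independently from its own marginal (same marginals, no
cross-feature dependence), train a random-forest classifier to separate
original from contrast rows, read off the proximity of two original rows as
the fraction of trees in which they share a terminal node, and cut an
average-linkage dendrogram of sqrt(1 - proximity) at three clusters.

Because the proximity matrix is dense (n x n), the input is uniformly
subsampled (the study used 10,000 sites and 1,000 trees); downstream recall
evaluation scales the variant denominator by the sampling fraction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.ensemble import RandomForestClassifier

from .types import ClusterFit, SiteTable

logger = logging.getLogger(__name__)

# A float32 n x n proximity matrix above this size does not fit comfortably
# in a few GiB of memory.
MAX_PROXIMITY_N = 30_000

FEATURES_CONTINUOUS = ("dp_mean", "ab_mean", "qd")


def make_contrast_data(features: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Resample each column independently from its own marginal.

    Marginal distributions are preserved; all cross-column dependence is
    destroyed — the "no correlation between covariables" synthetic contrast.
    """
    if len(features) < 2:
        raise ValueError("need at least 2 rows")
    rng = np.random.default_rng(seed)
    out = {}
    for col in features.columns:
        vals = features[col].to_numpy()
        out[col] = vals[rng.integers(0, len(vals), size=len(vals))]
    return pd.DataFrame(out, index=features.index)


def _feature_frame(table: SiteTable) -> pd.DataFrame:
    """Model features: one indicator per replicate call level + flag + covariables."""
    cols = {}
    for j, c in enumerate(table.call_columns):
        calls = table.df[c].to_numpy()
        for k, name in enumerate(("homref", "het", "homalt")):
            cols[f"rep{j + 1}_{name}"] = (calls == k).astype(np.int8)
    cols["difficult"] = table.df["difficult"].to_numpy().astype(np.int8)
    for c in FEATURES_CONTINUOUS:
        cols[c] = table.df[c].to_numpy(dtype=float)
    return pd.DataFrame(cols)


def proximity_matrix(leaves: np.ndarray) -> np.ndarray:
    """Co-terminal-node frequency among rows from per-tree leaf indices.

    ``leaves`` is (n, n_trees).  Symmetric, unit diagonal, entries in [0, 1].
    """
    n, n_trees = leaves.shape
    prox = np.zeros((n, n), dtype=np.float32)
    for t in range(n_trees):
        order = np.argsort(leaves[:, t], kind="stable")
        sorted_leaves = leaves[order, t]
        boundaries = np.flatnonzero(np.diff(sorted_leaves)) + 1
        for grp in np.split(order, boundaries):
            if len(grp) > 1:
                prox[np.ix_(grp, grp)] += 1.0
            else:
                prox[grp[0], grp[0]] += 1.0
    prox /= n_trees
    np.fill_diagonal(prox, 1.0)
    return prox


def _cut_with_core_clusters(Z, prox: np.ndarray, n_classes: int,
                            min_core_fraction: float = 0.005) -> np.ndarray:
    """Cut the dendrogram into ``n_classes`` non-trivial clusters.

    Average-linkage trees over proximity data often leave tiny outlier
    splinters that survive to the last merges; a plain ``maxclust`` cut then
    spends clusters on a handful of isolated rows.  The cut is therefore
    deepened until ``n_classes`` clusters of at least ``min_core_fraction``
    of the rows exist; the largest such cores are kept and every remaining
    row joins the core with the highest mean proximity to it.  Falls back to
    the plain cut when no depth yields enough cores.
    """
    n = prox.shape[0]
    min_core = max(3, int(np.ceil(min_core_fraction * n)))
    for k in range(n_classes, n_classes + 13):
        labels = fcluster(Z, t=k, criterion="maxclust")
        ids, sizes = np.unique(labels, return_counts=True)
        cores = ids[sizes >= min_core]
        if len(cores) >= n_classes:
            core_ids = cores[np.argsort(-sizes[sizes >= min_core])][:n_classes]
            assign = np.full(n, -1)
            for new, cid in enumerate(core_ids):
                assign[labels == cid] = new
            stray = assign < 0
            if stray.any():
                mean_prox = np.stack(
                    [prox[:, assign == new][np.ix_(stray.nonzero()[0])]
                     .mean(axis=1) for new in range(n_classes)], axis=1)
                assign[stray] = mean_prox.argmax(axis=1)
            return assign
    return fcluster(Z, t=n_classes, criterion="maxclust") - 1


def fit_forest_clusters(table: SiteTable, sample_size: int = 10_000,
                        n_trees: int = 1000, n_classes: int = 3,
                        seed: int = 0, linkage_method: str = "average"
                        ) -> ClusterFit:
    """Subsample, contrast, forest, proximity, dendrogram cut.

    The returned fit covers only the subsampled rows; ``sample_indices``
    maps them back into the SiteTable and ``sampling_fraction`` feeds the
    adjusted recall of the evaluation step.
    """
    n_total = len(table)
    rng = np.random.default_rng(seed)
    if n_total > sample_size:
        idx = np.sort(rng.choice(n_total, sample_size, replace=False))
    else:
        idx = np.arange(n_total)
    n = len(idx)
    if n > MAX_PROXIMITY_N:
        raise MemoryError(
            f"proximity matrix for n={n} rows would need "
            f"{n * n * 4 / 1e9:.1f} GB; lower sample_size "
            f"(max {MAX_PROXIMITY_N})")

    features = _feature_frame(table).iloc[idx].reset_index(drop=True)
    contrast = make_contrast_data(features, seed=int(rng.integers(2 ** 31)))
    X = pd.concat([features, contrast], ignore_index=True).to_numpy(float)
    y = np.r_[np.ones(n, dtype=int), np.zeros(n, dtype=int)]

    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=int(rng.integers(2 ** 31)),
        n_jobs=1, min_samples_leaf=5)
    forest.fit(X, y)
    oob_like = forest.score(X, y)
    logger.info("contrast classification accuracy (in-bag): %.3f", oob_like)

    leaves = forest.apply(X[:n])  # proximity among original rows only
    prox = proximity_matrix(leaves)
    dissim = np.sqrt(np.maximum(0.0, 1.0 - prox))
    np.fill_diagonal(dissim, 0.0)
    Z = linkage(squareform(dissim, checks=False), method=linkage_method)
    assign = _cut_with_core_clusters(Z, prox, n_classes)

    found = len(np.unique(assign))
    if found < n_classes:
        logger.warning("dendrogram cut yielded %d < %d clusters", found,
                       n_classes)
    posteriors = np.zeros((n, n_classes))
    posteriors[np.arange(n), assign] = 1.0
    return ClusterFit(model="random_forest", posteriors=posteriors,
                      loglik=float("nan"), n_params=0, bic=float("nan"),
                      converged=True, n_starts=1, best_start_fraction=1.0,
                      params={"n_trees": n_trees, "linkage": linkage_method,
                              "sample_size": n, "seed": seed},
                      sample_indices=idx)
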