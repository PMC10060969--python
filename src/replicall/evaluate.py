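"""Cluster labeling, genotype-match scoring and concordance rates.

Labeling rule: with three clusters ordered by size, the largest is
interpreted as the heterozygous variants, the intermediate as the homozygous
variants and the smallest as the homozygous reference (false-positive)
class.  A model in which any cluster holds less than 0.1% of the
observations is considered unable to identify the three genotype categories
and is rejected.

Genotype-match scoring: a call counts as a true positive only when its
category equals the benchmark's; a benchmark variant called in the wrong
variant category is a false positive (not a match), a benchmark variant
called non-variant is a false negative, and a benchmark non-variant called
variant is a false positive.
"""

from __future__ import annotations

import logging
import warnings as _warnings

import numpy as np

from .types import (ClusterFit, GenotypeCategory, PerformanceReport,
                    ReconstructedCallset, SiteTable, TruthSet)

logger = logging.getLogger(__name__)

#: size-rank -> genotype category (largest first)
_SIZE_ORDER = (GenotypeCategory.HET, GenotypeCategory.HOMALT,
               GenotypeCategory.HOMREF)


class ModelRejected(RuntimeError):
    """Raised when a fit fails the minimum-cluster-proportion rule."""

    def __init__(self, proportions, min_proportion):
        self.proportions = np.asarray(proportions, dtype=float)
        self.min_proportion = min_proportion
        super().__init__(
            f"cluster proportions {np.round(self.proportions, 5).tolist()} "
            f"include one below {min_proportion:g}: model cannot identify "
            "three genotype clusters")


def label_clusters(fit: ClusterFit, min_proportion: float = 0.001) -> dict[int, GenotypeCategory]:
    """Map cluster indices to genotype categories by descending size."""
    props = np.asarray(fit.class_proportions, dtype=float)
    if props.shape != (3,):
        raise ValueError("labeling rule requires exactly 3 clusters")
    if props.min() < min_proportion:
        raise ModelRejected(props, min_proportion)
    # stable sort keeps cluster-index order on exact ties
    order = np.argsort(-props, kind="stable")
    if len(np.unique(np.round(props, 12))) < 3:
        logger.warning("exact tie in cluster proportions %s: "
                       "broken by cluster index", props)
    return {int(c): _SIZE_ORDER[rank] for rank, c in enumerate(order)}


def reconstruct(table: SiteTable, fit: ClusterFit,
                min_proportion: float = 0.001) -> ReconstructedCallset:
    """Label a fit and map per-site assignments to genotype categories."""
    labels = label_clusters(fit, min_proportion)
    lut = np.array([int(labels[c]) for c in range(fit.n_classes)],
                   dtype=np.int8)
    cats = lut[fit.assignment]
    return ReconstructedCallset.from_sites(
        table, cats, model=fit.model, params=fit.params,
        row_indices=fit.sample_indices)


def classify_site(query: int, truth: int) -> str:
    """TP/FP/FN/TN status of one (query, truth) category pair."""
    q_var = query != GenotypeCategory.HOMREF
    t_var = truth != GenotypeCategory.HOMREF
    if q_var and t_var:
        return "TP" if query == truth else "FP"
    if q_var:
        return "FP"
    return "FN" if t_var else "TN"


def _count(query: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    q_var = query != GenotypeCategory.HOMREF
    t_var = truth != GenotypeCategory.HOMREF
    tp = int(np.sum(q_var & t_var & (query == truth)))
    fp = int(np.sum(q_var) - tp)
    fn = int(np.sum(~q_var & t_var))
    tn = int(np.sum(~q_var & ~t_var))
    return tp, fp, fn, tn


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def evaluate(callset: ReconstructedCallset, truth: TruthSet,
             sampling_fraction: float | None = None,
             total_truth_variants: int | None = None) -> PerformanceReport:
    """Score a callset against the benchmark over its confident regions.

    Sites outside the confident regions are not evaluable and excluded from
    every count.  For models fitted on a uniform subsample, pass
    ``sampling_fraction`` together with ``total_truth_variants`` (benchmark
    variants among the full set of evaluable sites): the recall denominator
    becomes ``total_truth_variants * sampling_fraction`` and the report is
    flagged as adjusted.
    """
    if len(callset) == 0:
        raise ValueError("empty callset")
    truth_cats = truth.truth_for(callset.df["chrom"].to_numpy(),
                                 callset.df["pos"].to_numpy())
    evaluable = truth_cats >= 0
    query = callset.categories[evaluable]
    t = truth_cats[evaluable]
    tp, fp, fn, tn = _count(query, t)
    n_eval = int(evaluable.sum())
    warnings: list[str] = []

    adjusted = False
    if sampling_fraction is not None:
        if total_truth_variants is None:
            raise ValueError("sampling_fraction requires total_truth_variants")
        est_variants = total_truth_variants * sampling_fraction
        fn = max(0, int(round(est_variants)) - tp)
        adjusted = True
        warnings.append(
            f"recall denominator estimated as {total_truth_variants} "
            f"benchmark variants x sampling fraction {sampling_fraction:g}")

    def ratio(num, den, name):
        if den == 0:
            warnings.append(f"{name} undefined (zero denominator)")
            return None
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    accuracy = (ratio(tp + tn, tp + fp + fn + tn, "accuracy")
                if not adjusted else ratio(tp + tn, n_eval, "accuracy"))
    f1 = (f1_score(precision, recall)
          if precision is not None and recall is not None else None)

    counts = np.bincount(query, minlength=3)
    props = counts / counts.sum() if counts.sum() else None
    if props is not None:
        n_het, n_hom = counts[1], counts[2]
        if n_hom > 0 and not 1.0 <= n_het / n_hom <= 4.0:
            warnings.append(
                f"het/hom ratio {n_het / n_hom:.2f} outside the ~2 expected "
                "for WGS callsets")
        if not 0.001 <= props[0] <= 0.10:
            warnings.append(
                f"reference-class share {props[0]:.4f} outside the usual "
                "0.1%-10% range")
    for w in warnings:
        logger.info("evaluate[%s]: %s", callset.provenance, w)
    return PerformanceReport(tp=tp, fp=fp, fn=fn, tn=tn, n_evaluable=n_eval,
                             precision=precision, recall=recall,
                             accuracy=accuracy, f1=f1,
                             class_proportions=props, adjusted=adjusted,
                             warnings=warnings)


def concordance_rate(calls: np.ndarray, scope: tuple[int, ...] | str = "all") -> float:
    """Share of variant-containing sites on which the scoped replicates agree.

    ``scope`` is "all" or a tuple of replicate column indices (e.g. ``(0, 1)``
    for the pairwise rate).  The denominator is the number of sites called
    variant by at least one scoped replicate; the numerator counts the sites
    where all scoped replicates give the same category.
    """
    calls = np.asarray(calls)
    if scope != "all":
        calls = calls[:, list(scope)]
    if calls.shape[1] < 2:
        raise ValueError("concordance needs >=2 replicates in scope")
    in_view = (calls >= GenotypeCategory.HET).any(axis=1)
    if not in_view.any():
        _warnings.warn("concordance undefined: no variant-called sites")
        return float("nan")
    agree = (calls == calls[:, [0]]).all(axis=1)
    return float(np.sum(agree & in_view) / np.sum(in_view))
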