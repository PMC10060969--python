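"""Core data containers shared by all clustering models.

Genotype categories, the per-site table of replicate calls and quality
covariables (``SiteTable``), the benchmark truth set, fitted-model results
(``ClusterFit``), reconstructed callsets and performance reports.

Coordinate conventions: VCF positions are 1-based; BED intervals are 0-based
half-open.  A 1-based position ``p`` lies inside ``[start, end)`` iff
``start < p <= end``.
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class GenotypeCategory(enum.IntEnum):
    """The three genotype categories of a diploid biallelic site."""

    HOMREF = 0
    HET = 1
    HOMALT = 2


#: Sentinel for a missing genotype (``./.``).  No-calls are mapped to
#: HOMREF ("called non-variant") before modelling; the sentinel only exists
#: at the I/O boundary.
NO_CALL = -1

CATEGORY_NAMES = ("HOMREF", "HET", "HOMALT")

#: Continuous covariable columns of a SiteTable.
COVARIATE_COLUMNS = ("dp_mean", "ab_mean", "gq_mean", "qd", "mq")


def _as_call_matrix(calls: np.ndarray) -> np.ndarray:
    calls = np.asarray(calls)
    if calls.ndim != 2:
        raise ValueError("calls must be a 2-D (n_sites, n_replicates) array")
    return calls.astype(np.int8, copy=False)


@dataclass
class SiteTable:
    """Per-site replicate calls plus quality covariables (the "VCF view").

    Every row corresponds to a site called variant (HET or HOMALT) by at
    least one replicate.  ``calls`` holds the genotype category per
    replicate; ``dp_mean``/``ab_mean``/``gq_mean`` are means over the
    replicates with defined values; ``qd`` and ``mq`` are site-level INFO
    covariables shared across replicates.
    """

    df: pd.DataFrame

    REQUIRED = ("chrom", "pos", "ref", "alt", "dp_mean", "ab_mean",
                "gq_mean", "qd", "mq", "difficult")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"SiteTable missing columns: {missing}")
        if not self.call_columns:
            raise ValueError("SiteTable has no call_* columns")

    @property
    def call_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("call_")]

    @property
    def n_replicates(self) -> int:
        return len(self.call_columns)

    @property
    def calls(self) -> np.ndarray:
        """(n_sites, n_replicates) int8 matrix of genotype categories."""
        return self.df[self.call_columns].to_numpy(dtype=np.int8)

    def __len__(self) -> int:
        return len(self.df)

    def site_keys(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.df[["chrom", "pos", "ref", "alt"]])

    def validate(self) -> None:
        """Assert the VCF-view invariants; raise ``ValueError`` otherwise."""
        ab = self.df["ab_mean"].to_numpy(float)
        if np.any((ab < -1e-12) | (ab > 1 + 1e-12)):
            raise ValueError("ab_mean outside [0, 1]")
        if np.any(self.df["dp_mean"].to_numpy(float) < 0):
            raise ValueError("negative dp_mean")
        if not (self.calls >= GenotypeCategory.HET).any(axis=1).all():
            raise ValueError("row without any variant call (violates VCF view)")
        if self.site_keys().duplicated().any():
            raise ValueError("duplicate site keys")

    def covariates(self, names: Sequence[str]) -> np.ndarray:
        """Column-stacked float matrix for the requested covariables."""
        return self.df[list(names)].to_numpy(dtype=float)


class IntervalSet:
    """Non-overlapping, sorted 0-based half-open intervals per chromosome."""

    def __init__(self, intervals: Mapping[str, np.ndarray]):
        # intervals: chrom -> (k, 2) array of [start, end)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, arr in intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            arr = arr[np.argsort(arr[:, 0])]
            starts, ends = _merge_intervals(arr)
            self._starts[chrom] = starts
            self._ends[chrom] = ends

    @property
    def chroms(self) -> list[str]:
        return list(self._starts)

    def n_intervals(self) -> int:
        return sum(len(s) for s in self._starts.values())

    def contains(self, chrom: str, pos_1based: np.ndarray) -> np.ndarray:
        """Vectorized membership for 1-based positions."""
        pos = np.atleast_1d(np.asarray(pos_1based, dtype=np.int64))
        if chrom not in self._starts:
            return np.zeros(pos.shape, dtype=bool)
        starts, ends = self._starts[chrom], self._ends[chrom]
        p0 = pos - 1  # 0-based coordinate of the base
        idx = np.searchsorted(starts, p0, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(pos.shape, dtype=bool)
        inside[ok] = p0[ok] < ends[idx[ok]]
        return inside

    def intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return self._starts[chrom], self._ends[chrom]


def _merge_intervals(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if len(arr) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    starts, ends = [], []
    cur_s, cur_e = arr[0]
    for s, e in arr[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            starts.append(cur_s)
            ends.append(cur_e)
            cur_s, cur_e = s, e
    starts.append(cur_s)
    ends.append(cur_e)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


@dataclass
class TruthSet:
    """Benchmark genotype categories over a confident-region interval set.

    Sites inside the confident regions but absent from the benchmark VCF are
    homozygous reference by convention; sites outside the regions are not
    evaluable and are excluded from every performance count.
    """

    categories: dict[tuple[str, int], int]
    confident_regions: IntervalSet

    def lookup(self, chrom: str, pos: int) -> int | None:
        """Truth category at a 1-based position, or ``None`` if not evaluable."""
        if not self.confident_regions.contains(chrom, np.asarray([pos]))[0]:
            return None
        return self.categories.get((chrom, pos), int(GenotypeCategory.HOMREF))

    def truth_for(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Vectorized truth categories; -1 marks not-evaluable sites."""
        chrom = np.asarray(chrom)
        pos = np.asarray(pos, dtype=np.int64)
        out = np.full(len(pos), -1, dtype=np.int8)
        for c in np.unique(chrom):
            mask = chrom == c
            inside = self.confident_regions.contains(str(c), pos[mask])
            idx = np.flatnonzero(mask)[inside]
            vals = [self.categories.get((str(c), int(p)), 0) for p in pos[idx]]
            out[idx] = np.asarray(vals, dtype=np.int8)
        return out

    def n_variants(self) -> int:
        return sum(1 for v in self.categories.values()
                   if v != GenotypeCategory.HOMREF)


@dataclass
class ClusterFit:
    """Result of fitting one clustering model.

    ``posteriors`` are per-site class responsibilities (hard one-hot for
    non-probabilistic models); ``class_proportions`` are their means (or hard
    counts); ``best_start_fraction`` is the share of random starts whose
    final log-likelihood/objective came within 1e-4 of the best.
    """

    model: str
    posteriors: np.ndarray
    loglik: float
    n_params: int
    bic: float
    converged: bool
    n_starts: int
    best_start_fraction: float
    params: object = None
    sample_indices: np.ndarray | None = None  # set by subsampling models
    trace: np.ndarray | None = None  # per-iteration loglik/objective, best start

    @property
    def assignment(self) -> np.ndarray:
        return np.argmax(self.posteriors, axis=1)

    @property
    def n_classes(self) -> int:
        return self.posteriors.shape[1]

    @property
    def class_proportions(self) -> np.ndarray:
        return self.posteriors.mean(axis=0)


@dataclass
class ReconstructedCallset:
    """Per-site genotype categories produced by one labelled model."""

    df: pd.DataFrame  # chrom, pos, ref, alt, category
    provenance: str

    def __len__(self) -> int:
        return len(self.df)

    @property
    def categories(self) -> np.ndarray:
        return self.df["category"].to_numpy(dtype=np.int8)

    @staticmethod
    def from_sites(table: SiteTable, categories: np.ndarray, model: str,
                   params: object = None,
                   row_indices: np.ndarray | None = None) -> "ReconstructedCallset":
        df = table.df[["chrom", "pos", "ref", "alt"]]
        if row_indices is not None:
            df = df.iloc[row_indices]
        df = df.copy()
        df["category"] = np.asarray(categories, dtype=np.int8)
        digest = hashlib.sha1(repr(params).encode()).hexdigest()[:12]
        return ReconstructedCallset(df.reset_index(drop=True),
                                    provenance=f"{model}:{digest}")


@dataclass
class PerformanceReport:
    """Genotype-match benchmarking counts and indicators.

    ``precision``/``recall``/``accuracy``/``f1`` are ``None`` when their
    denominator is zero (flagged in ``warnings``).  When ``adjusted`` is
    True the recall denominator is the estimated total variant count
    (benchmark variants times the sampling fraction), the convention for
    models fitted on a uniform subsample.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    n_evaluable: int
    precision: float | None
    recall: float | None
    accuracy: float | None
    f1: float | None
    class_proportions: np.ndarray | None = None
    concordance: float | None = None
    adjusted: bool = False
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "n_evaluable": self.n_evaluable,
            "precision": self.precision, "recall": self.recall,
            "accuracy": self.accuracy, "f1": self.f1,
            "adjusted": self.adjusted, "warnings": list(self.warnings),
        }
        if self.class_proportions is not None:
            d["class_proportions"] = [float(x) for x in self.class_proportions]
        if self.concordance is not None:
            d["concordance"] = self.concordance
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)
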