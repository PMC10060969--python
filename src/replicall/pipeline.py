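"""Orchestrate the full replicate-reconstruction comparison.

Simulate (or ingest) replicate callsets, fit the requested models, label the
clusters, score everything against the truth set and emit one comparison
table: per-replicate baseline rows ("none"), the consensus row, and one row
per clustering model.  Rejected models (minimum-cluster-proportion rule)
appear with their rejection reason; any other model failure is isolated so
the remaining rows are still produced.  All randomness is derived from one
seed, so a config runs to byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import simulate as sim
from .consensus import consensus_callset
from .evaluate import ModelRejected, concordance_rate, evaluate, reconstruct
from .forest import fit_forest_clusters
from .gmm import fit_gmm
from .kamila import fit_kamila
from .lca import fit_lca, fit_lca_covariates
from .types import (IntervalSet, ReconstructedCallset, SiteTable, TruthSet)
from .vcf_io import read_replicates, read_truth

logger = logging.getLogger(__name__)

ALL_MODELS = ("consensus", "lca", "lca_cov", "gmm", "kamila",
              "random_forest")


@dataclass
class RunConfig:
    """One comparison run: input source, model list, hyperparameters, seed."""

    seed: int
    mode: str = "simulate"                     # "simulate" | "vcf"
    n_sites: int = 200_000
    models: tuple[str, ...] = ALL_MODELS
    vcf_path: str | None = None
    truth_vcf: str | None = None
    confident_bed: str | None = None
    difficult_bed: str | None = None
    out_dir: str | None = None
    lca_starts: int = 50
    lca_cov_starts: int = 100
    lca_cov_covariates: tuple[str, ...] = ("ab_mean", "qd")
    lca_cov_short_iter: int | None = None  # emEM two-phase when set
    lca_max_iter: int = 1000
    gmm_starts: int = 5
    gmm_covariates: tuple[str, ...] = ("dp_mean", "ab_mean", "qd")
    kamila_starts: int = 10
    kamila_dp_cap: float = 150.0
    rf_sample_size: int = 10_000
    rf_trees: int = 1000
    min_cluster_proportion: float = 0.001

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("at least one model is required")
        unknown = set(self.models) - set(ALL_MODELS)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        if self.mode == "vcf" and not (self.vcf_path and self.truth_vcf
                                       and self.confident_bed):
            raise ValueError("vcf mode needs vcf_path, truth_vcf and "
                             "confident_bed")


def _truthset_from_dataset(ds: sim.SyntheticDataset) -> TruthSet:
    v = ds.view()
    cats = {(str(c), int(p)): int(t)
            for c, p, t in zip(v.chrom, v.pos, v.truth) if t != 0}
    regions = {}
    for c in pd.unique(v.chrom):
        m = v.chrom == c
        regions[str(c)] = np.array([[int(v.pos[m].min()) - 1,
                                     int(v.pos[m].max())]])
    return TruthSet(cats, IntervalSet(regions))


def _load_inputs(config: RunConfig) -> tuple[SiteTable, TruthSet]:
    if config.mode == "simulate":
        ds = sim.simulate(sim.SimConfig(n_sites=config.n_sites,
                                        seed=config.seed))
        return ds.to_site_table(), _truthset_from_dataset(ds)
    table = read_replicates(config.vcf_path, config.difficult_bed)
    truth = read_truth(config.truth_vcf, config.confident_bed)
    return table, truth


def _fit_one(model: str, table: SiteTable, config: RunConfig, seed: int):
    """Fit one model and return (fit, sampling_fraction or None)."""
    if model == "lca":
        fit, _ = fit_lca(table.calls, n_starts=config.lca_starts, seed=seed,
                         max_iter=config.lca_max_iter)
        return fit, None
    if model == "lca_cov":
        fit, _ = fit_lca_covariates(
            table.calls, table.covariates(config.lca_cov_covariates),
            covariate_names=config.lca_cov_covariates,
            n_starts=config.lca_cov_starts, seed=seed,
            max_iter=config.lca_max_iter,
            short_iter=config.lca_cov_short_iter)
        return fit, None
    if model == "gmm":
        fit, _ = fit_gmm(table, covariate_set=config.gmm_covariates,
                         n_starts=config.gmm_starts, seed=seed)
        return fit, None
    if model == "kamila":
        fit, _ = fit_kamila(table, n_starts=config.kamila_starts, seed=seed,
                            dp_cap=config.kamila_dp_cap)
        return fit, None
    if model == "random_forest":
        fit = fit_forest_clusters(table, sample_size=config.rf_sample_size,
                                  n_trees=config.rf_trees, seed=seed)
        frac = (len(fit.sample_indices) / len(table)
                if len(fit.sample_indices) < len(table) else None)
        return fit, frac
    raise ValueError(model)


def run(config: RunConfig) -> dict:
    """Execute the comparison; returns the report dict (also written to disk).

    The report has one entry per baseline replicate, one per requested
    model, the pairwise/three-way concordance rates and the echoed config.
    """
    table, truth = _load_inputs(config)
    seeds = np.random.SeedSequence(config.seed).spawn(len(config.models))
    model_seeds = {m: int(s.generate_state(1)[0] % (2 ** 31))
                   for m, s in zip(config.models, seeds)}
    n_truth_variants = truth.n_variants()

    report: dict = {"config": _config_dict(config), "rows": []}
    calls = table.calls
    R = table.n_replicates
    report["concordance"] = {
        "three_way": concordance_rate(calls),
        "pairwise": {f"{i + 1}v{j + 1}": concordance_rate(calls, (i, j))
                     for i in range(R) for j in range(i + 1, R)},
    }

    for j in range(R):
        cs = ReconstructedCallset.from_sites(table, calls[:, j],
                                             model=f"replicate_{j + 1}")
        rep = evaluate(cs, truth)
        report["rows"].append(_row(f"none (replicate {j + 1})", rep))

    for model in config.models:
        try:
            if model == "consensus":
                cs = consensus_callset(table)
                rep = evaluate(cs, truth)
            else:
                fit, frac = _fit_one(model, table, config,
                                     model_seeds[model])
                cs = reconstruct(table, fit,
                                 min_proportion=config.min_cluster_proportion)
                rep = evaluate(cs, truth, sampling_fraction=frac,
                               total_truth_variants=(n_truth_variants
                                                     if frac else None))
            report["rows"].append(_row(model, rep))
        except ModelRejected as exc:
            report["rows"].append({
                "model": model, "status": "rejected",
                "reason": str(exc),
                "class_proportions": [float(x) for x in exc.proportions]})
            logger.warning("%s rejected: %s", model, exc)
        except Exception as exc:
            report["rows"].append({"model": model, "status": "failed",
                                   "reason": f"{type(exc).__name__}: {exc}"})
            logger.exception("%s failed", model)

    if config.out_dir:
        _write_report(report, config.out_dir)
    return report


def _row(name: str, rep) -> dict:
    d = rep.to_dict()
    d["model"] = name
    d["status"] = "ok"
    return d


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["models"] = list(config.models)
    return d


def _write_report(report: dict, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "comparison.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    rows = []
    for r in report["rows"]:
        rows.append({
            "model": r["model"], "status": r["status"],
            **{k: (round(100 * r[k], 3) if r.get(k) is not None else "")
               for k in ("accuracy", "precision", "recall", "f1")
               if r["status"] == "ok"},
        })
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "comparison.tsv"),
                              sep="\t", index=False)


def format_report(report: dict) -> str:
    """Human-readable comparison table, one row per callset."""
    lines = [f"{'model':28s} {'status':9s} {'acc%':>7s} {'prec%':>7s} "
             f"{'rec%':>7s} {'F1%':>7s}"]
    for r in report["rows"]:
        if r["status"] != "ok":
            lines.append(f"{r['model']:28s} {r['status']:9s} "
                         f"-- {r.get('reason', '')[:60]}")
            continue
        vals = [("" if r.get(k) is None else f"{100 * r[k]:7.2f}")
                for k in ("accuracy", "precision", "recall", "f1")]
        lines.append(f"{r['model']:28s} {r['status']:9s} " + " ".join(vals))
    c = report.get("concordance")
    if c:
        lines.append(f"three-way concordance: {100 * c['three_way']:.2f}%")
    return "\n".join(lines)
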