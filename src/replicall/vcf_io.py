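"""Read replicate multi-sample VCFs, benchmark VCF/BED and region BEDs.

Builds the :class:`~replicall.types.SiteTable` / ``TruthSet`` model and
computes the per-site covariables: mean read depth (DP), mean allele balance
(AB = alt reads / all informative reads), mean genotype quality (GQ) across
replicates, and the site-level QD and MQ INFO fields.

Conventions

* ``0/0`` -> HOMREF, ``0/1``/``1/0`` -> HET, ``1/1`` -> HOMALT; phasing
  separators are ignored.  ``./.`` is a no-call and is treated as a called
  non-variant (HOMREF) for modelling.
* Only sites called variant by at least one replicate enter the SiteTable
  (the "VCF view").
* AB for a sample with zero informative reads is 0 when the call is HOMREF
  and excluded from the site mean otherwise.
* Missing QD/MQ values are imputed with the table median (count logged).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import NO_CALL, GenotypeCategory, IntervalSet, SiteTable, TruthSet

logger = logging.getLogger(__name__)


def _gt_to_category(alleles: list) -> int:
    """Map a cyvcf2 genotype (allele indices, phased flag) to a category."""
    a = [x for x in alleles[:-1] if x is not None and x >= 0]
    if len(a) < 2:
        return NO_CALL
    n_alt = sum(1 for x in a if x > 0)
    if n_alt == 0:
        return int(GenotypeCategory.HOMREF)
    if n_alt == len(a):
        return int(GenotypeCategory.HOMALT)
    return int(GenotypeCategory.HET)


def read_bed(path: str) -> IntervalSet:
    """Parse a 3+ column BED file into an interval set (0-based half-open)."""
    intervals: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            intervals.setdefault(chrom, []).append((start, end))
    return IntervalSet({c: np.asarray(v) for c, v in intervals.items()})


def read_replicates(vcf_path, difficult_bed_path: str | None = None) -> SiteTable:
    """Read one joint-genotyped multi-sample VCF into a SiteTable.

    ``vcf_path`` may also be a list of single-sample VCF paths: they are
    merged on the site key with no-call fill for sites absent from a
    replicate.
    """
    if isinstance(vcf_path, (list, tuple)):
        return _merge_single_sample(list(vcf_path), difficult_bed_path)

    vcf = VCF(str(vcf_path), gts012=False)
    n_samples = len(vcf.samples)
    if n_samples < 2:
        raise ValueError(f"{vcf_path}: need >=2 sample columns, "
                         f"found {n_samples}")

    rows = []
    n_skipped = 0
    for variant in vcf:
        try:
            row = _site_row(variant, n_samples)
        except Exception as exc:  # malformed record: warn + skip
            n_skipped += 1
            logger.warning("skipping %s:%s (%s)", variant.CHROM,
                           variant.POS, exc)
            continue
        if row is not None:
            rows.append(row)
        else:
            n_skipped += 1
    if n_skipped:
        logger.info("read_replicates: skipped %d non-view/malformed records",
                    n_skipped)
    if not rows:
        raise ValueError(f"{vcf_path}: no variant-called sites")
    df = pd.DataFrame(rows)
    df = _impute_info(df)
    df["difficult"] = _difficult_flags(df, difficult_bed_path)
    table = SiteTable(df)
    table.validate()
    return table


def _site_row(variant, n_samples: int) -> dict | None:
    if len(variant.ALT) != 1:
        # multi-allelic sites are out of scope; first alt only, flagged
        logger.warning("multi-allelic site %s:%s: using first ALT",
                       variant.CHROM, variant.POS)
    cats = np.array([_gt_to_category(g) for g in variant.genotypes],
                    dtype=np.int8)
    called = np.where(cats == NO_CALL, GenotypeCategory.HOMREF, cats)
    if not (called >= GenotypeCategory.HET).any():
        return None  # outside the VCF view

    dp = variant.format("DP")
    dp = (dp.reshape(-1).astype(float) if dp is not None
          else np.full(n_samples, np.nan))
    dp = np.where(dp < 0, np.nan, dp)

    ad = variant.format("AD")
    ab = np.full(n_samples, np.nan)
    if ad is not None:
        ad = ad.astype(float)
        ad[ad < 0] = np.nan
        total = np.nansum(ad[:, :2], axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ab = ad[:, 1] / total
        # no informative reads: AB=0 for HOMREF calls, undefined otherwise
        zero = ~(total > 0)
        ab[zero & (called == GenotypeCategory.HOMREF)] = 0.0
        ab[zero & (called != GenotypeCategory.HOMREF)] = np.nan

    gq = variant.format("GQ")
    gq = (gq.reshape(-1).astype(float) if gq is not None
          else np.full(n_samples, np.nan))
    gq = np.where(gq < 0, np.nan, gq)

    qd = _info_float(variant, "QD")
    mq = _info_float(variant, "MQ")
    return {
        "chrom": variant.CHROM, "pos": int(variant.POS),
        "ref": variant.REF, "alt": variant.ALT[0],
        **{f"call_{j + 1}": int(called[j]) for j in range(n_samples)},
        "dp_mean": _nanmean(dp), "ab_mean": _nanmean(ab),
        "gq_mean": _nanmean(gq),
        "qd": qd, "mq": mq,
    }


def _info_float(variant, key: str) -> float:
    """INFO float re-quantized to 6 significant digits.

    htslib stores INFO floats in single precision; going through %.6g
    recovers the decimal value that was actually printed in the file.
    """
    val = variant.INFO.get(key)
    if val is None:
        return np.nan
    return float(f"{float(val):.6g}")


def _nanmean(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.nanmean(x)) if np.isfinite(x).any() else np.nan


def _impute_info(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("qd", "mq", "dp_mean", "ab_mean", "gq_mean"):
        n_missing = int(df[col].isna().sum())
        if n_missing:
            med = float(df[col].median())
            if math.isnan(med):
                med = 0.0
            df[col] = df[col].fillna(med)
            logger.info("imputed %d missing %s values with median %.4g",
                        n_missing, col, med)
    return df


def _difficult_flags(df: pd.DataFrame, bed_path: str | None) -> np.ndarray:
    if bed_path is None:
        return np.zeros(len(df), dtype=bool)
    regions = read_bed(bed_path)
    flags = np.zeros(len(df), dtype=bool)
    for chrom, sub in df.groupby("chrom", sort=False):
        flags[sub.index.to_numpy()] = regions.contains(
            str(chrom), sub["pos"].to_numpy())
    return flags


def _merge_single_sample(paths: list, difficult_bed_path) -> SiteTable:
    """Outer-join per-replicate VCFs on the site key with no-call fill."""
    partials = []
    for j, p in enumerate(paths):
        vcf = VCF(str(p), gts012=False)
        recs = []
        for v in vcf:
            cat = _gt_to_category(v.genotypes[0])
            called = (GenotypeCategory.HOMREF if cat == NO_CALL else cat)
            dp = v.format("DP")
            ad = v.format("AD")
            gq = v.format("GQ")
            ab = np.nan
            if ad is not None:
                tot = float(np.nansum(ad[0, :2]))
                ab = float(ad[0, 1]) / tot if tot > 0 else (
                    0.0 if called == GenotypeCategory.HOMREF else np.nan)
            recs.append({
                "chrom": v.CHROM, "pos": int(v.POS), "ref": v.REF,
                "alt": v.ALT[0] if v.ALT else ".",
                f"call_{j + 1}": int(called),
                f"dp_{j + 1}": float(dp.reshape(-1)[0]) if dp is not None
                else np.nan,
                f"ab_{j + 1}": ab,
                f"gq_{j + 1}": float(gq.reshape(-1)[0]) if gq is not None
                else np.nan,
                "qd": _info_float(v, "QD"), "mq": _info_float(v, "MQ"),
            })
        partials.append(pd.DataFrame(recs).set_index(
            ["chrom", "pos", "ref", "alt"]))
    merged = partials[0]
    for extra in partials[1:]:
        qdmq = merged[["qd", "mq"]].combine_first(extra[["qd", "mq"]])
        merged = merged.drop(columns=["qd", "mq"]).join(
            extra.drop(columns=["qd", "mq"]), how="outer")
        merged = merged.join(qdmq, how="left")
    merged = merged.reset_index()
    R = len(paths)
    for j in range(1, R + 1):
        merged[f"call_{j}"] = merged[f"call_{j}"].fillna(
            int(GenotypeCategory.HOMREF)).astype(np.int8)
    merged["dp_mean"] = merged[[f"dp_{j}" for j in range(1, R + 1)]].mean(axis=1)
    merged["ab_mean"] = merged[[f"ab_{j}" for j in range(1, R + 1)]].mean(axis=1)
    merged["gq_mean"] = merged[[f"gq_{j}" for j in range(1, R + 1)]].mean(axis=1)
    merged = merged.drop(columns=[f"{c}_{j}" for c in ("dp", "ab", "gq")
                                  for j in range(1, R + 1)])
    view = (merged[[f"call_{j}" for j in range(1, R + 1)]].to_numpy()
            >= GenotypeCategory.HET).any(axis=1)
    merged = merged[view].reset_index(drop=True)
    merged = _impute_info(merged)
    merged["difficult"] = _difficult_flags(merged, difficult_bed_path)
    table = SiteTable(merged)
    table.validate()
    return table


def read_truth(benchmark_vcf: str, confident_bed: str) -> TruthSet:
    """Load the gold-standard callset restricted to its confident regions."""
    regions = read_bed(confident_bed)
    if regions.n_intervals() == 0:
        raise ValueError(f"{confident_bed}: empty BED")
    categories: dict[tuple[str, int], int] = {}
    vcf = VCF(str(benchmark_vcf), gts012=False)
    for v in vcf:
        if not regions.contains(v.CHROM, np.asarray([v.POS]))[0]:
            continue
        cat = _gt_to_category(v.genotypes[0]) if len(v.genotypes) else NO_CALL
        if cat in (NO_CALL, int(GenotypeCategory.HOMREF)):
            continue
        categories[(v.CHROM, int(v.POS))] = int(cat)
    return TruthSet(categories=categories, confident_regions=regions)


def cap_dp(table: SiteTable, cap: float) -> SiteTable:
    """Return a new SiteTable with ``dp_mean`` clipped from above at ``cap``."""
    if not cap > 0:
        raise ValueError("cap must be positive")
    df = table.df.copy()
    df["dp_mean"] = np.minimum(df["dp_mean"].to_numpy(float), cap)
    return SiteTable(df)


def write_callset_vcf(callset, path: str) -> None:
    """Write a reconstructed callset as a single-sample VCF."""
    from .simulate import _GT_STRINGS, _VCF_HEADER
    contigs = pd.unique(callset.df["chrom"])
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contig=str(contigs[0]),
                                    samples="RECONSTRUCTED"))
        for row in callset.df.itertuples(index=False):
            fh.write("\t".join([
                str(row.chrom), str(row.pos), ".", str(row.ref),
                str(row.alt), ".", "PASS", ".", "GT",
                _GT_STRINGS[int(row.category)]]) + "\n")
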