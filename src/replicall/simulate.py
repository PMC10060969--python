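"""Synthetic three-replicate callsets with known truth.

The generator emulates the statistical structure of joint-genotyped technical
replicates of a single human genome:

* a latent truth category per site (homozygous reference / heterozygous /
  homozygous variant) drawn from benchmark-like proportions, default
  (4.241%, 57.891%, 37.868%);
* replicate calls drawn conditionally independently given truth from a
  per-replicate confusion matrix (the conditional-independence structure the
  latent class model assumes);
* class-conditional quality covariables: heavy-tailed read depth (lognormal,
  mean about 38), allele balance near 0 / 0.5 / 1 by class (zero-inflated
  beta, binomial, one-inflated beta), class-dependent QD in [0.02, 42.9] and
  GQ in [0, 99], and site-level MQ in [20, 60];
* an optional "difficult region" flag that can scale the per-replicate error
  mass.

``calibrate_confusion`` solves for confusion matrices that reproduce a target
three-way concordance rate on the VCF view together with a target truth
composition of the discordant sites.  Only sites called variant by at least
one replicate are emitted to the VCF view, like a real multi-sample VCF.
"""

from __future__ import annotations

import functools
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .types import NO_CALL, GenotypeCategory, SiteTable

DEFAULT_TRUTH_PROPORTIONS = (0.04241, 0.57891, 0.37868)
DEFAULT_CONCORDANCE = 0.975
DEFAULT_DISCORDANT_COMPOSITION = (0.559, 0.396, 0.045)

# Fixed parameterization constants of the confusion-matrix family solved by
# calibrate_confusion (see docs/methods.md).  A site whose truth is
# homozygous reference sits in the VCF only because callers erred there, so
# its per-replicate probability of a (correct) HOMREF call is small and
# fixed; the split of its erroneous calls between HET and HOMALT is solved.
_HOMREF_CORRECT = 0.04
_HET_ERROR_SPLIT = (0.2, 0.8)    # HET errors: to HOMREF vs HOMALT
_HOMALT_ERROR_SPLIT = (0.1, 0.9)  # HOMALT errors: to HOMREF vs HET


class CalibrationError(ValueError):
    """Requested concordance/composition has no solution in the family."""


@dataclass
class CovariateParams:
    """Class-conditional covariable distribution parameters.

    Read depth is lognormal per replicate (heavy right tail); allele balance
    is derived from an integer alt-read count so AD and AB stay exactly
    consistent; QD and GQ are truncated normals by truth class; MQ is a
    scaled beta on [20, 60] that degrades in difficult regions.
    """

    # lognormal depth per truth class; artifact-prone (truth-HOMREF) sites
    # carry elevated, heavily dispersed depth, as excess-coverage artifact
    # regions do, while genuine variant sites have tight ~38x coverage
    dp_mean: tuple[float, float, float] = (100.0, 38.0, 38.0)
    dp_sdlog: tuple[float, float, float] = (1.0, 0.25, 0.25)
    # allele balance: (zero-or-one inflation weight, beta a, beta b) per class
    # point mass at exactly 0/1 plus a beta component concentrated nearby
    # (the small ref-read contamination seen at real HOMALT sites)
    ab_homref: tuple[float, float, float] = (0.40, 1.0, 20.0)
    ab_homalt: tuple[float, float, float] = (0.60, 25.0, 1.5)
    # FP-prone sites have low variant confidence per alt read (QD under ~2,
    # the classic hard-filter region); true HET/HOMALT sites sit near 16/30
    qd_loc: tuple[float, float, float] = (1.5, 16.0, 30.0)
    qd_scale: tuple[float, float, float] = (1.0, 4.5, 5.5)
    qd_range: tuple[float, float] = (0.02, 42.9)
    gq_loc: tuple[float, float, float] = (40.0, 85.0, 90.0)
    gq_scale: tuple[float, float, float] = (20.0, 12.0, 10.0)
    mq_beta: tuple[float, float] = (1.0, 10.0)
    mq_beta_difficult: tuple[float, float] = (2.0, 5.0)
    mq_range: tuple[float, float] = (20.0, 60.0)

    def dp_meanlog(self, t: int) -> float:
        return float(np.log(self.dp_mean[t]) - self.dp_sdlog[t] ** 2 / 2)


@dataclass
class SimConfig:
    """Configuration of one synthetic replicate experiment."""

    n_sites: int
    seed: int
    truth_proportions: tuple[float, float, float] = DEFAULT_TRUTH_PROPORTIONS
    confusion: list[np.ndarray] | None = None  # None -> calibrated default
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    difficult_fraction: float = 0.10
    difficult_error_multiplier: float = 1.0
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        q = np.asarray(self.truth_proportions, dtype=float)
        if abs(q.sum() - 1.0) > 1e-12 or (q < 0).any():
            raise ValueError("truth_proportions must be a probability vector")
        if self.confusion is None:
            self.confusion = [m.copy() for m in default_confusion()]
        if len(self.confusion) != self.n_replicates:
            raise ValueError("need one confusion matrix per replicate")
        for m in self.confusion:
            m = np.asarray(m, dtype=float)
            if m.shape != (3, 3) or (m < 0).any():
                raise ValueError("confusion matrices must be non-negative 3x3")
            if np.abs(m.sum(axis=1) - 1).max() > 1e-9:
                raise ValueError("confusion rows must sum to 1")
            if np.any(np.diag(m) == 0):
                raise ValueError("degenerate confusion: zero diagonal entry")
        if self.difficult_error_multiplier < 1:
            raise ValueError("difficult_error_multiplier must be >= 1")
        if not 0 <= self.difficult_fraction <= 1:
            raise ValueError("difficult_fraction must be in [0, 1]")


@dataclass
class SyntheticDataset:
    """All simulated sites (the VCF view is the subset with a variant call)."""

    truth: np.ndarray              # (n,) int8
    calls: np.ndarray              # (n, R) int8
    dp: np.ndarray                 # (n, R) int
    ad_alt: np.ndarray             # (n, R) int
    ab: np.ndarray                 # (n, R) float, == ad_alt/dp
    gq: np.ndarray                 # (n, R) int
    qd: np.ndarray                 # (n,) float
    mq: np.ndarray                 # (n,) float
    difficult: np.ndarray          # (n,) bool
    chrom: np.ndarray              # (n,) str
    pos: np.ndarray                # (n,) int64, 1-based
    config: SimConfig

    def __len__(self) -> int:
        return len(self.truth)

    @property
    def vcf_view_mask(self) -> np.ndarray:
        """Sites called HET or HOMALT by at least one replicate."""
        return (self.calls >= GenotypeCategory.HET).any(axis=1)

    def view(self) -> "SyntheticDataset":
        m = self.vcf_view_mask
        return SyntheticDataset(
            truth=self.truth[m], calls=self.calls[m], dp=self.dp[m],
            ad_alt=self.ad_alt[m], ab=self.ab[m], gq=self.gq[m],
            qd=self.qd[m], mq=self.mq[m], difficult=self.difficult[m],
            chrom=self.chrom[m], pos=self.pos[m], config=self.config)

    def to_site_table(self) -> SiteTable:
        """The VCF-view SiteTable (replicate means over covariables)."""
        v = self.view()
        data = {"chrom": v.chrom, "pos": v.pos,
                "ref": np.full(len(v.pos), "A"), "alt": np.full(len(v.pos), "G")}
        for j in range(v.calls.shape[1]):
            data[f"call_{j + 1}"] = v.calls[:, j]
        data["dp_mean"] = v.dp.mean(axis=1)
        data["ab_mean"] = v.ab.mean(axis=1)
        data["gq_mean"] = v.gq.mean(axis=1)
        data["qd"] = v.qd
        data["mq"] = v.mq
        data["difficult"] = v.difficult
        return SiteTable(pd.DataFrame(data))

    def truth_view(self) -> np.ndarray:
        return self.truth[self.vcf_view_mask]


# ---------------------------------------------------------------------------
# confusion calibration


def _rows_from_free_params(s: float, e1: float, e2: float) -> np.ndarray:
    a0 = _HOMREF_CORRECT
    row0 = np.array([a0, s * (1 - a0), (1 - s) * (1 - a0)])
    row1 = np.array([_HET_ERROR_SPLIT[0] * e1, 1 - e1, _HET_ERROR_SPLIT[1] * e1])
    row2 = np.array([_HOMALT_ERROR_SPLIT[0] * e2, _HOMALT_ERROR_SPLIT[1] * e2,
                     1 - e2])
    return np.vstack([row0, row1, row2])


def view_statistics(truth_proportions, confusions) -> dict:
    """Closed-form VCF-view statistics implied by confusion matrices.

    Assuming truth drawn i.i.d. and replicate calls conditionally independent
    given truth, returns the view mass, the three-way concordance on the view
    and the truth composition of the discordant view sites.
    """
    q = np.asarray(truth_proportions, dtype=float)
    C = [np.asarray(m, dtype=float) for m in confusions]
    all_homref = np.prod([m[:, 0] for m in C], axis=0)       # per truth class
    agree_k = np.stack([np.prod([m[:, k] for m in C], axis=0)
                        for k in range(3)], axis=1)          # (truth, call)
    in_view = 1.0 - all_homref
    agree_variant = agree_k[:, 1] + agree_k[:, 2]
    disc = in_view - agree_variant
    view_mass = float(q @ in_view)
    disc_mass = q * disc
    return {
        "view_mass": view_mass,
        "concordance": float(q @ agree_variant) / view_mass,
        "discordant_composition": disc_mass / disc_mass.sum()
        if disc_mass.sum() > 0 else np.full(3, np.nan),
        "view_truth_proportions": q * in_view / view_mass,
    }


def calibrate_confusion(target_concordance: float,
                        discordant_composition=DEFAULT_DISCORDANT_COMPOSITION,
                        truth_proportions=DEFAULT_TRUTH_PROPORTIONS,
                        n_replicates: int = 3) -> list[np.ndarray]:
    """Solve for per-replicate confusion matrices matching view summaries.

    The solution family fixes the error-direction profile (module constants)
    and solves three free error-rate parameters so that the analytic
    three-way concordance on the VCF view equals ``target_concordance``
    (within 0.002) and the truth composition of discordant sites matches
    ``discordant_composition`` (within 0.05 per component).  All replicates
    share one matrix.
    """
    if not 0 < target_concordance <= 1:
        raise ValueError("target_concordance must be in (0, 1]")
    comp = np.asarray(discordant_composition, dtype=float)
    if abs(comp.sum() - 1.0) > 1e-9:
        raise ValueError("discordant_composition must sum to 1")
    if target_concordance >= 1.0 - 1e-12:
        return [np.eye(3) for _ in range(n_replicates)]

    def residuals(x):
        C = _rows_from_free_params(*x)
        st = view_statistics(truth_proportions, [C] * n_replicates)
        d = st["discordant_composition"]
        return [st["concordance"] - target_concordance,
                d[0] - comp[0], d[1] - comp[1]]

    sol = optimize.least_squares(
        residuals, x0=np.array([0.9, 0.01, 0.005]),
        bounds=([0.5, 1e-7, 1e-7], [0.999, 0.45, 0.45]), xtol=1e-14, ftol=1e-14)
    C = _rows_from_free_params(*sol.x)
    st = view_statistics(truth_proportions, [C] * n_replicates)
    if abs(st["concordance"] - target_concordance) > 2e-3 or np.nanmax(
            np.abs(st["discordant_composition"] - comp)) > 5e-2:
        raise CalibrationError(
            f"no confusion matrices reach concordance={target_concordance} "
            f"with composition {tuple(comp)} in this family "
            f"(best: concordance={st['concordance']:.4f}, "
            f"composition={np.round(st['discordant_composition'], 3)})")
    return [C.copy() for _ in range(n_replicates)]


@functools.lru_cache(maxsize=1)
def _default_confusion_cached() -> tuple:
    mats = calibrate_confusion(DEFAULT_CONCORDANCE,
                               DEFAULT_DISCORDANT_COMPOSITION)
    return tuple(m for m in mats)


def default_confusion() -> list[np.ndarray]:
    """Confusion matrices calibrated to the study's replicate summaries."""
    return [m.copy() for m in _default_confusion_cached()]


# ---------------------------------------------------------------------------
# simulation


def _scale_errors(row: np.ndarray, t: int, m: float) -> np.ndarray:
    """Multiply a confusion row's off-diagonal mass by m and renormalize.

    ``t`` is the truth category of the row (its diagonal index).  The whole
    row is renormalized, so any multiplier is well defined; for small error
    mass the error rate scales by ~m.
    """
    out = row.copy() * m
    out[t] = row[t]
    return out / out.sum()


def _truncnorm(rng, loc, scale, lo, hi, size):
    a, b = (lo - loc) / scale, (hi - loc) / scale
    from scipy.stats import truncnorm
    return truncnorm.rvs(a, b, loc=loc, scale=scale, size=size,
                         random_state=rng)


def simulate(config: SimConfig) -> SyntheticDataset:
    """Draw a synthetic dataset; identical configs give identical output."""
    rng = np.random.default_rng(config.seed)
    n, R = config.n_sites, config.n_replicates
    q = np.asarray(config.truth_proportions, dtype=float)
    cp = config.covariate_params

    truth = rng.choice(3, size=n, p=q).astype(np.int8)
    difficult = rng.random(n) < config.difficult_fraction

    # replicate calls given truth, conditionally independent
    calls = np.empty((n, R), dtype=np.int8)
    for j in range(R):
        Cj = np.asarray(config.confusion[j], dtype=float)
        Cd = np.vstack([_scale_errors(Cj[t], t,
                                      config.difficult_error_multiplier)
                        for t in range(3)]) \
            if config.difficult_error_multiplier != 1.0 else Cj
        u = rng.random(n)
        for t in range(3):
            for mask, M in ((~difficult, Cj), (difficult, Cd)):
                sel = mask & (truth == t)
                if sel.any():
                    cum = np.cumsum(M[t])
                    calls[sel, j] = np.searchsorted(cum, u[sel], side="right")
    calls = np.clip(calls, 0, 2)

    # read depth: lognormal per replicate and truth class, heavy right tail
    dp = np.empty((n, R), dtype=np.int64)
    for t in range(3):
        m = truth == t
        k = int(m.sum())
        if k:
            draws = rng.lognormal(cp.dp_meanlog(t), cp.dp_sdlog[t],
                                  size=(k, R))
            dp[m] = np.maximum(1, np.rint(draws)).astype(np.int64)

    # alt-read counts -> allele balance, by truth class
    ad_alt = np.zeros((n, R), dtype=np.int64)
    for t, spec_ab in ((0, cp.ab_homref), (2, cp.ab_homalt)):
        m = truth == t
        k = int(m.sum())
        if k == 0:
            continue
        w, a, b = spec_ab
        frac = rng.beta(a, b, size=(k, R))
        inflate = rng.random((k, R)) < w
        frac[inflate] = 0.0 if t == 0 else 1.0
        ad_alt[m] = np.rint(frac * dp[m]).astype(np.int64)
    m = truth == 1
    if m.any():
        ad_alt[m] = rng.binomial(dp[m], 0.5)
    ab = ad_alt / dp

    # genotype quality per replicate, truncated by class
    gq = np.empty((n, R), dtype=np.int64)
    for t in range(3):
        m = truth == t
        k = int(m.sum())
        if k:
            vals = _truncnorm(rng, cp.gq_loc[t], cp.gq_scale[t], 0, 99,
                              size=(k, R))
            gq[m] = np.rint(vals).astype(np.int64)

    # site-level QD (class-dependent) and MQ (difficulty-dependent only)
    qd = np.empty(n)
    lo, hi = cp.qd_range
    for t in range(3):
        m = truth == t
        k = int(m.sum())
        if k:
            qd[m] = _truncnorm(rng, cp.qd_loc[t], cp.qd_scale[t], lo, hi, k)
    qd = np.round(qd, 2)
    qd = np.clip(qd, lo, hi)

    mq_lo, mq_hi = cp.mq_range
    span = mq_hi - mq_lo
    beta_easy = rng.beta(*cp.mq_beta, size=n)
    beta_hard = rng.beta(*cp.mq_beta_difficult, size=n)
    mq = mq_hi - span * np.where(difficult, beta_hard, beta_easy)
    mq = np.round(np.clip(mq, mq_lo, mq_hi), 2)

    pos = 1 + 3 * np.arange(n, dtype=np.int64)
    chrom = np.full(n, "1", dtype=object)
    return SyntheticDataset(truth=truth, calls=calls, dp=dp, ad_alt=ad_alt,
                            ab=ab, gq=gq, qd=qd, mq=mq, difficult=difficult,
                            chrom=chrom, pos=pos, config=config)


# ---------------------------------------------------------------------------
# writers (plain-text VCFv4.2 + BED)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID={contig}>
##INFO=<ID=QD,Number=1,Type=Float,Description="Variant Confidence/Quality by Depth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS Mapping Quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", NO_CALL: "./."}


def write_vcf(dataset: SyntheticDataset, out_dir: str) -> dict[str, str]:
    """Write the VCF view + truth VCF + confident/difficult BEDs.

    Returns the paths under keys ``replicates_vcf``, ``truth_vcf``,
    ``confident_bed`` and ``difficult_bed``.  Round-trips bit-exactly through
    :func:`replicall.vcf_io.read_replicates`.
    """
    os.makedirs(out_dir, exist_ok=True)
    v = dataset.view()
    R = v.calls.shape[1]
    samples = "\t".join(f"REP{j + 1}" for j in range(R))
    paths = {
        "replicates_vcf": os.path.join(out_dir, "replicates.vcf"),
        "truth_vcf": os.path.join(out_dir, "truth.vcf"),
        "confident_bed": os.path.join(out_dir, "confident.bed"),
        "difficult_bed": os.path.join(out_dir, "difficult.bed"),
    }
    try:
        with open(paths["replicates_vcf"], "w") as fh:
            fh.write(_VCF_HEADER.format(contig="1", samples=samples))
            for i in range(len(v.pos)):
                info = f"QD={v.qd[i]:.2f};MQ={v.mq[i]:.2f}"
                cols = [str(v.chrom[i]), str(v.pos[i]), ".", "A", "G", ".",
                        "PASS", info, "GT:DP:AD:GQ"]
                for j in range(R):
                    dp = int(v.dp[i, j])
                    alt = int(v.ad_alt[i, j])
                    cols.append(f"{_GT_STRINGS[int(v.calls[i, j])]}:{dp}:"
                                f"{dp - alt},{alt}:{int(v.gq[i, j])}")
                fh.write("\t".join(cols) + "\n")

        with open(paths["truth_vcf"], "w") as fh:
            fh.write(_VCF_HEADER.format(contig="1", samples="TRUTH"))
            for i in range(len(v.pos)):
                t = int(v.truth[i])
                if t == GenotypeCategory.HOMREF:
                    continue  # benchmark VCFs list variant sites only
                fh.write("\t".join([
                    str(v.chrom[i]), str(v.pos[i]), ".", "A", "G", ".",
                    "PASS", ".", "GT", _GT_STRINGS[t]]) + "\n")

        with open(paths["confident_bed"], "w") as fh:
            for c in pd.unique(v.chrom):
                m = v.chrom == c
                lo, hi = int(v.pos[m].min()), int(v.pos[m].max())
                fh.write(f"{c}\t{lo - 1}\t{hi}\n")

        with open(paths["difficult_bed"], "w") as fh:
            for i in np.flatnonzero(v.difficult):
                fh.write(f"{v.chrom[i]}\t{int(v.pos[i]) - 1}\t{int(v.pos[i])}\n")
    except OSError as exc:
        raise OSError(f"failed writing synthetic dataset under {out_dir}: "
                      f"{exc}") from exc
    return paths
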