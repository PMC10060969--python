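# Methods

## Problem setting

Repeated sequencing of the same DNA sample (technical replicates) yields
several genotype callsets that agree on most sites but disagree on a
non-negligible minority. `replicall` reconstructs a single, higher-precision
callset from three or more replicate callsets by clustering the per-site
evidence, then benchmarks the reconstruction against a gold-standard truth
set with genotype-match scoring.

The statistical unit is one site of the "VCF view": a position called
heterozygous (HET) or homozygous-alternate (HOMALT) by at least one
replicate. Each site carries three genotype categories per replicate
(HOMREF / HET / HOMALT; no-calls count as called HOMREF) and five quality
covariables: mean read depth DP, mean allele balance AB (alt reads over all
informative reads), mean genotype quality GQ, and the site-level QD
(variant confidence per alt read) and MQ (RMS mapping quality).

## Model families

**Majority consensus.** The category held by more than half the replicates;
with no majority the site is classified homozygous-alternate. A strict
(unanimity) variant is available.

**Latent class analysis.** Three latent classes with prevalences `p_r`;
given the class, replicate calls are independent categoricals `pi[r, j, k]`.
The marginal probability of a call pattern is
`P(Y_i) = sum_r p_r * prod_j pi[r, j, Y_ij]`. Because the likelihood depends
on the data only through the `3^R` pattern counts, EM runs on the collapsed
contingency table and is fast at any n. Unobserved patterns are excluded
from the table (they carry no likelihood and would otherwise produce
0 * log 0 artifacts in degenerate data).

**LCA with covariate-dependent priors.** The prevalences become site
prior probabilities through a multinomial logit on standardized covariables
(class 1 as reference): `p_r(z_i) = softmax(0, X_i B)`. The M-step updates
`pi` in closed form and improves the logit coefficients with one damped
Newton step per iteration (step-halving on the expected complete-data
log-likelihood, ridge added when quasi-separation makes the Hessian
singular), so the observed log-likelihood is non-decreasing (a generalized
EM). Covariate sets are compared by BIC with the study protocol: all
univariate models, then all pairs.

**Gaussian mixture.** Three multivariate normal components on continuous
covariables only (replicate calls are deliberately excluded). EM with
kmeans++-seeded initialization, eigenvalue floor 1e-6 on covariances, and a
restart on component collapse (weight < 1e-6). Six covariance structures
(spherical / diagonal / full, shared or per class) and all non-empty
covariate subsets can be searched by BIC. Covariables are z-scored before
fitting; this puts likelihoods of different covariate subsets on one common
scale, making the cross-set BIC comparison meaningful in the "same units"
sense. It remains a heuristic — densities over different numbers of
dimensions are not strictly comparable, and a dimension lowers BIC only
when its within-class standardized spread is small enough (below
(2*pi*e)^(-1/2), about 0.24) to beat its entropy cost. The full comparison
table is always returned so the ranking can be inspected.

**Kamila-style mixed clustering.** k-means-like alternation for mixed data:
continuous covariables (DP capped at 150, AB, QD; z-scored after capping)
enter through a radial kernel-density model of spherical clusters — the
point density is the Gaussian-KDE estimate of the minimum centroid
distances divided by the surface factor r^(d-1) — and categorical variables
(the three replicate calls and the difficult-region flag) through class
multinomials with add-0.5 smoothing. Assignment maximizes the summed log
terms with no pre-specified domain weighting. The KDE uses Silverman
bandwidth on a subsample of at most 4000 distances, evaluated on a 512-point
grid with linear interpolation and a 1e-300 density floor. Because the KDE
refit is not guaranteed to increase the objective, the iteration stops as
soon as an assign/update cycle would decrease it and keeps the previous
state; the recorded objective trace is therefore non-decreasing by
construction. Centroids are seeded with kmeans++ (a distance-aware seeding
is required for the algorithm's documented sensitivity to extreme-depth
outliers to be observable at all — uniform-random seeding essentially never
places a centroid in a tiny far-out group). Empty clusters are re-seeded at
the farthest point.

The depth cap matters: with the cap removed, a <0.1%-weight group of
extreme-DP sites can capture one of the three clusters, in which case the
labeling rule rejects the model; with the cap the genotype structure is
recovered. This mirrors the known failure mode of the reference algorithm
on heavy-tailed depth.

**Unsupervised random forest.** A synthetic contrast dataset is built by
resampling every feature column independently from its own marginal
(marginals preserved, cross-feature dependence destroyed); a random forest
is trained to separate original from contrast rows; the proximity of two
original rows is the fraction of trees in which they share a terminal node;
sites are clustered by average-linkage agglomeration of sqrt(1 - proximity).
Features are the one-hot-encoded replicate calls, the difficult flag and the
three continuous covariables. Because the proximity matrix is dense, the
input is uniformly subsampled (default 10,000 sites, 1,000 trees; a guard
refuses more than 30,000 rows, where the float32 matrix approaches 4 GB).
The dendrogram cut is robustified: average-linkage trees over proximity data
often keep 2-4-row outlier splinters alive until the last merges, so a
plain 3-cluster cut can waste a cluster on isolated rows. The cut is
deepened until three clusters holding at least 0.5% of rows each exist; the
largest cores are kept and stray rows join the core with the highest mean
proximity. A plain cut is the fallback.

## Labeling and evaluation

With three clusters ordered by size, the largest is interpreted as HET, the
intermediate as HOMALT and the smallest as HOMREF (the false-positive
class) — the prior structure of a WGS VCF, where het/hom ratio is around 2
and reference (FP) sites occupy roughly 0.1-10%. Any model with a cluster
under 0.1% of observations is rejected as unable to identify the three
categories. Exact ties are broken by cluster index with a warning; the
het/hom-ratio and reference-share priors are soft report warnings, not
failures.

Genotype-match scoring against the benchmark, restricted to its confident
regions (sites outside them are not evaluable): TP = same variant category;
FP = benchmark non-variant called variant, or variant called in the wrong
variant category; FN = benchmark variant called non-variant; TN = both
non-variant. Indicators: accuracy (TP+TN)/(TP+FP+FN+TN), recall TP/(TP+FN),
precision TP/(TP+FP), F1 = harmonic mean. Zero denominators yield an
undefined (null) indicator, flagged. For the subsampled random forest the
recall denominator is the benchmark variant count times the sampling
fraction. The concordance rate of a replicate set is the share of
variant-containing sites on which all scoped replicates agree.

## Synthetic replicate generator

The generator is the package's test bed: it produces data with known truth
under the exact conditional-independence structure the latent class model
assumes, with class-conditional covariable laws chosen to emulate a
joint-genotyped human WGS experiment at mean depth ~38.

* Truth categories are i.i.d. from (4.241%, 57.891%, 37.868%) — the
  benchmark composition of a real three-replicate VCF view.
* Replicate calls are conditionally independent given truth, with one
  confusion matrix per replicate (identical by default). The default matrix
  is solved by `calibrate_confusion` so that the closed-form three-way
  concordance on the VCF view is 97.5% and the truth composition of
  discordant sites is (55.9%, 39.6%, 4.5%). The solution family fixes the
  error-direction profile — truth-HOMREF sites (which sit in the VCF only
  because callers err there) are called HOMREF with probability 0.04 per
  replicate and their erroneous calls split between HET and HOMALT by a
  solved ratio; HET errors go 20%/80% to HOMREF/HOMALT; HOMALT errors
  10%/90% to HOMREF/HET — and solves three error-rate parameters by least
  squares. The mapping from the published summaries to matrices is not
  unique; this parameterization is the package's own and is validated by
  forward simulation. A difficult-region flag (10% of sites) can scale the
  error mass (off-diagonal times m, row renormalized); the default
  multiplier is 1 so the calibration holds exactly.
* Covariables, conditional on truth: DP is lognormal per replicate —
  mean 38, sigma_log 0.25 for genuine variant sites; mean 100, sigma_log 1.0
  (a heavy tail reaching thousands) for artifact-prone truth-HOMREF sites,
  mirroring excess-coverage artifact regions. AB derives from an integer
  alt-read count (so AD and AB are exactly consistent): binomial(DP, 1/2)
  for HET; zero/one-inflated betas concentrated near 0 and 1 for
  HOMREF/HOMALT. QD is truncated normal in [0.02, 42.9] at 1.5/16/30 by
  class — artifact sites sit in the classic hard-filter region. GQ is
  truncated normal in [0, 99]; MQ is a scaled beta on [20, 60] degraded in
  difficult regions and carries no class signal (so an uninformative
  covariable exists for selection protocols).

These class-conditional laws were fixed at design time so that the three
genotype categories are identifiable by every model family, as they were in
the real experiment the generator emulates; they are all exposed in
`CovariateParams`. What the generator does **not** emulate: local
dependence between replicates given truth (systematic artifacts that fool
all replicates identically beyond what conditional independence produces),
multi-allelic sites, indels, linkage between neighbouring sites, and
reference-bias structure in AB. Consequences: the latent class model is
exactly well-specified here (its real-data advantage is smaller), and
covariate-based models (GMM, covariate-LCA) achieve near-perfect precision
because the class-conditional covariate laws are cleanly separated —
passing tests demonstrate correct implementations and the qualitative
ordering of the families, not real-data effect sizes.

## Numerical choices and defaults

* EM: relative log-likelihood tolerance 1e-8, max 1000 iterations; 50
  random starts for plain LCA, 100 for covariate LCA (Dirichlet(1.1) rows
  for pi, flat Dirichlet for p, N(0, 0.5) for logit coefficients); ties
  between starts (within 1e-4) keep the first by start index. The share of
  starts reaching the best optimum is reported (`best_start_fraction`) —
  on realistic data it is often well below 1, which is why the start counts
  are large. For the covariate LCA an emEM-style two-phase schedule
  (`short_iter`) is available: every start runs a fixed number of
  iterations and only the best short run is converged — the robustness of
  many starts at a fraction of the cost, used by the desk-scale profile.
* GMM: covariance eigenvalue floor 1e-6; collapse threshold 1e-6 with
  logged restart.
* Kamila: 10 starts, 50 iterations; depth cap 150 before z-scoring.
* Forest: 10,000-site subsample, 1,000 trees, min_samples_leaf 5, average
  linkage, core fraction 0.5% for the robust cut.
* Heavy routines are exercised in tests at reduced sizes (e.g. 20k-50k
  sites, fewer starts/trees) chosen so the full suite runs on one CPU in
  well under half an hour; the five-seed full-scale comparison uses 200,000
  sites per seed.

## Known limitations

* Cross-covariate-set BIC comparison for the GMM is a documented heuristic
  (see above), not a calibrated test.
* The kamila instantiation documents its concrete choices (Gaussian kernel,
  Silverman bandwidth, grid interpolation, add-0.5 smoothing, kmeans++
  seeding, early stop on objective decrease); it does not claim
  bit-equivalence with the original reference package.
* The random-forest proximity is the standard co-terminal-node frequency
  among original rows; descriptions of this construction in the applied
  literature sometimes conflate it with contrast-classification accuracy.
* Whole-genome negative-site accounting (specificity) is out of scope: all
  counting happens on the VCF view inside the confident regions.
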