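# Methods

This note documents the statistical models implemented in `regiongwas`, the
parameters that matter, the synthetic data the tests run on, and the design
choices made where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The window screen (stage 1)

Each chromosome is tiled with sliding windows (`WindowSpec`: 100,000 bp
window, 50,000 bp step — a 50% overlap so no signal straddles a boundary
unseen; empty windows are dropped). A window of dosages G and phenotype y is
scored by a Bayesian classification tree:

* **Leaves** carry Beta(1,1)–Binomial marginals over case counts: a leaf
  with a cases and b controls contributes log B(a+1, b+1).
* **Splits** are `dosage ≤ c`, c ∈ {0, 1}, on mean-imputed dosage. The tree
  grows greedily: a split is accepted only if it raises the total log
  marginal by more than the structural prior cost, with depth ≤ 3 and ≥ 25
  samples per leaf.
* **PLO** = (log marginal of the fitted tree − log marginal of the
  intercept-only Beta-Binomial) / ln 10. Prior odds are 1, so the PLO is a
  base-10 log Bayes factor and PLO 2.0 means posterior odds of 100. With no
  accepted split the PLO is exactly 0.

**Split prior.** The per-split log-prior cost defaults to −2.5 nats
(`TreePrior.log_split_prior`; split odds ≈ 1:12). This is a calibration to
the documented interface of decision-tree genome screens: the 95th
percentile of the per-window permutation-null PLO should sit near 1.0 — well
below the PLO ≥ 2.0 selection gate — while the null distribution keeps
enough spread (point mass at zero ≈ 0.9 at 25 SNPs/window) for the
percentile gate to operate near its nominal 5% exceedance. A cost of ln 2,
ignoring the multiplicity of candidate splits, puts the null 95th percentile
at ≈ 2.5 and breaks that interface; a full Bonferroni-style cost
ln(2·m_SNPs) collapses the null onto zero and starves the percentile gate.
Both alternatives remain reachable through the config.

**Null distribution.** "Bootstrapping" is realized as phenotype-label
permutation, which preserves the case:control ratio exactly and is the
natural exchangeability null for "no SNP in the window is associated". The
per-window gate is the type-7 (linear-interpolation) 95th percentile of
1,000 permutation PLOs by default; fewer than 20 is refused.

**Concordance selection.** Step A keeps windows with PLO ≥ 2.0 in at least
2 studies of the same stratum (X-chromosome windows are excluded from
combined-sex strata, where the tree would conflate sex dosage with disease).
Step B requires PLO > the bootstrap 95th percentile in every qualifying
study. Overlapping qualifying windows merge into one candidate region;
candidates overlapping a user-supplied list of known susceptibility regions
are reported separately rather than as novel.

## The GBJ region test (stages 2–4)

**Marginal scores.** For a region's SNPs, the covariate-only logistic null
(intercept; optionally sex, standardized age, and the top PCs) is fitted by
Newton–Raphson; each SNP's score statistic is U_j = g̃_j'(y − μ̂) with g̃ the
W-weighted projection residual of the dosage on the covariates
(W = μ̂(1−μ̂)), standardized by √(g̃_j' W g̃_j). The null covariance of the
scores is G̃' W G̃, whose correlation is Σ. With an intercept-only null this
Z equals the Cochran–Armitage trend test exactly (asserted to 1e−6 in the
suite).

**LD pruning** precedes scoring: greedy windowed pruning (50-SNP windows,
5-SNP step, r² > 0.5) on raw mean-imputed dosage correlation, dropping the
lower-MAF member of each violating pair (tie: later position), pairs
processed in descending-r² order. The window parameters mirror common
workflow defaults and are configurable; on instances that fit in one window
the result equals brute-force iterative removal on the full matrix.

**Statistic.** With |z|₍₁₎ ≥ … ≥ |z|₍d₎ and p_k = 2(1 − Φ(|z|₍ₖ₎)), the
exceedance count at threshold k has null mean μ_k = d·p_k and variance
σ²_k = d p_k(1−p_k) + Σ_{i≠j}[P(|Z_i| ≥ t_k, |Z_j| ≥ t_k | Σ_ij) − p_k²].
The pairwise absolute orthant probabilities are computed from Owen's T
function. An extended beta-binomial is matched to (μ_k, σ²_k) via
ρ_k = (σ²_k/(d p_k(1−p_k)) − 1)/(d − 1), γ_k = ρ_k/(1−ρ_k) (γ clipped below
so every pmf factor stays positive), and the k-th generalized log-likelihood
ratio compares success probability k/d against p_k at that dispersion; the
binomial coefficients cancel in the ratio. GBJ is the maximum over k with
|z|₍ₖ₎ > 1 and k/d > p_k, else 0. Under Σ = I all corrections vanish and the
statistic is the classical Berk–Jones binomial log-LR (asserted to 1e−8).

**P-values** are Monte Carlo: draws from N(0, Σ) (eigenvalue-clipped at 0
for PSD repair), p = (1 + #{draws ≥ observed})/(n_mc + 1), default
n_mc = 20,000, floor 1/(n_mc+1). For batch evaluation the pairwise-orthant
sum f(t) is precomputed on a dense grid over t ∈ [1, 9] (1,601 points,
linear interpolation; exact evaluation is used for the observed statistic
and whenever Σ is diagonal). An analytic boundary-crossing p-value is *not*
implemented: the Monte Carlo route is the supported default precisely so
that correctness never rests on delicate tail numerics.

**Summary-statistics route.** z = β/SE per SNP, sign-flipped when the
summary effect allele is the reference panel's other allele; SNPs whose
allele pair cannot be reconciled are dropped and counted. Σ comes from the
(optionally pruned) reference panel's dosage correlation. No strand flipping
is attempted; strand-ambiguous (A/T, C/G) variants are flagged in the
variant report, not removed, so this known source of cross-study attenuation
stays observable.

## Meta-analysis and sex differences (stage 4)

Per-study effects are Wald estimates from the same Newton logistic fitter
(missing genotype rows dropped, not imputed; non-convergence raised as a
separation error). Studies combine by the weighted-Z model with
**effective sample size** 4/(1/N_case + 1/N_ctrl) as the weight — the
equal-information size of a balanced study. Total-N weighting is available,
but with case:control ratios varying by factor ~4 across contributing
studies the effective-N weights reproduce published meta p-values from
published per-study inputs markedly better (the package's worked examples
compute this reconstruction; the test suite asserts it within 5% on the z
scale). Sex difference: β_F − β_M, SE = √(SE_F² + SE_M²), two-sided normal
p. Printed OR (L95, U95) rows convert back via β = ln OR,
SE = (ln U95 − ln L95)/(2·1.96); two-decimal printing induces about
|Δz| ≤ 0.05 of irreducible rounding error, which is the tolerance the tests
use. Bonferroni ledgers are α/m over the regions and the SNPs carried into
this stage.

## QC and population structure

Samples first (missing phenotype/sex, call rate < 0.95), then SNPs: call
rate < 0.95, differential case/control missingness (two-sided Fisher exact,
p < 1e−5), MAF < 0.01 (strict: exactly 0.01 is retained), and exact
Hardy–Weinberg in controls — overall and within male-only and female-only
controls (p < 1e−5) as a guard against sex-specific genotyping error. The
HWE test is the exact conditional-on-allele-counts enumeration (vectorized
through log-gamma weights), chosen over the chi-square because it is
well-defined at low counts; the filter order (samples before SNPs) follows
the standard cascade. Filters are idempotent and every rule logs
removed/retained counts.

Relatedness is the method-of-moments IBD estimator from IBS counts and
allele frequencies; pairs with π̂ > 0.1875 (midpoint of second- and
third-degree expected sharing) are broken greedily — highest flagged-pair
degree first (so the shared member of a cluster goes), then lower call rate,
then lexicographically larger id — and the output is re-scanned to assert no
pair remains above threshold. PCA standardizes SNPs by √(2f(1−f)) after
mean imputation (for PCA only), with a seeded iterative SVD above 800×800
and a fixed sign convention; ancestry outliers are flagged by robust z
(median/MAD, fallback SD) > 6 on PC1/PC2 against a reference subset — a
deterministic surrogate for the usual visual reference-cluster inspection.
Cross-study duplicates are genotype-concordance > 0.95 over shared SNPs.

## Synthetic data: what it emulates, what it does not

`build_haplotype_pool` generates haplotypes by Li–Stephens-style copying:
each new haplotype copies stretches of earlier ones, switching template with
probability 0.003 between adjacent SNPs inside an LD block and 0.3 at block
boundaries (25-SNP blocks), with copying-error rate 0.005 per SNP, 10 founder
haplotypes, base frequencies uniform on [0.05, 0.5], and one SNP per 4 kb —
roughly array density. This yields adjacent-SNP r² around 0.1 decaying with
distance and near-independence across blocks; out-of-range frequencies are
regenerated along the same template chains so repair does not distort LD.
The within-block switching is required for distance-decaying LD — pure
block-copying gives distance-flat correlation. Only the second-moment
structure matters to the statistics under test, which is why a coalescent
simulator was not used.

Disease status follows logit P(case) = logit(0.1) + Σ_j ln(OR_j)·g_j, with
sex-restricted effects applied only in the permitted sex; rejection sampling
fills exact case/control quotas. Because the generating model is the
analysis model, parameter recovery is an exact oracle. Per-study
allele-frequency heterogeneity is available as a bounded Beta(2,2)
perturbation (`maf_jitter`). Ages are Gaussian by phenotype (cases 55 ± 15,
controls 56 ± 15, clipped to [18, 95]), echoing adult-glioma study tables.

Not emulated: imputation uncertainty, strand errors, genotyping batch
effects, admixture beyond what the pool provides, X-chromosome dosage, and
real LD's long-range irregularity. Passing tests therefore demonstrate the
*statistics* behave as designed under their own assumptions — calibration,
power ordering, invariances — not that real-data artifacts are handled.

## Study conditions behind the reported numbers

All stochastic studies live in `regiongwas.benchmarks`, seeded via
`SeedSequence([base_seed, tag])` so one base seed reproduces everything.

* **GBJ calibration:** 2,000 null z-vectors (d = 50, exchangeable ρ = 0.3),
  each assigned a Monte Carlo p against one shared pool of 20,000 null
  draws; type-I error at α = 0.05 should sit in ≈ [0.04, 0.06] (binomial
  noise at 2,000 replicates).
* **Screen calibration:** one null study of 500 cases / 500 controls over
  2,600 SNPs (≈ 208 windows), 500 permutations per window. Reported: the
  fraction of windows whose null 95th percentile is below PLO 2.0 (expected
  ≈ 1) and the rate at which the observed PLO exceeds its percentile
  (nominally 5%; ties at PLO 0 make it mildly conservative).
* **End-to-end recovery:** 20 replicates of three studies (2,000/2,000 each,
  5,000 SNPs, fresh pool per replicate) with one planted 100-kb region of 3
  causal SNPs at OR 1.3; stages 1–2 run with 200 bootstrap iterations, 2
  PCs, and 2,000 Monte Carlo draws — sizes chosen so a replicate completes
  in seconds while per-SNP |z| ≈ 5 keeps recovery comfortably powered.
  Non-planted windows of the same replicates measure the null single- and
  multi-study window rates and the false-candidate rate.
* **Sex-difference power:** 20 replicates, one male-only causal SNP at OR
  1.3 in a 2,000/2,000 study; the sex-difference test at the causal SNP has
  ≈ 0.75 power at α = 0.05 under these sizes.

## Numerical choices and degenerate inputs

* Logistic fits: Newton–Raphson, η clipped at ±30, convergence on relative
  log-likelihood < 1e−10; |β| > 15 (or >1e3 mid-iteration) raised as
  separation rather than returned as a finite estimate.
* GBJ internals: p_k floored at 1e−300; exceedance variance floored at
  1e−12; γ clipped so all extended-beta-binomial factors stay positive;
  statistic comparisons use a 1e−12 slack so ties count as exceedances.
* Missing dosage is a distinct symbol (−1) end to end; it is mean-imputed
  only where a contract says so (PCA, window trees, score statistics,
  pruning r²) and dropped in per-SNP logistic fits.
* Monomorphic SNPs: dropped inside PCA and marginal scores (logged), raised
  for single-SNP association.
* Windows with no SNPs are dropped; single-class phenotype vectors are
  errors for the tree marginal; n_boot < 20 and n_mc < 100 are refused.

## Known limitations

* The window tree is a surrogate for decision-tree screening in general: it
  reproduces the documented interface (base-10 PLO, permutation null with
  95th percentile ≈ 1, bootstrap gating) with fully specified internals, not
  any particular published implementation's ensemble.
* The analytic GBJ p-value route is intentionally absent; at the Monte Carlo
  floor (p = 1/(n_mc+1)) regions are reported as "< floor", which is
  sufficient for the pipeline's 0.05-level gates but not for genome-wide
  per-region p-values.
* Summary-statistics GBJ inherits any mismatch between the reference panel's
  LD and the contributing study's LD; the test suite measures (rather than
  hides) the miscalibration when the reference is deliberately wrong.
* The aggregated-data mode (`aggregate_studies` / `aggregated_region_test`,
  study indicator added to the covariates) exists for the attenuation
  diagnostic only; the pipeline never uses pooled data for discovery, since
  pooled studies differ in collection and genotyping.
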