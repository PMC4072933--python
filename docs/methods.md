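# Methods

## The model

`methfam` analyses DNA-methylation beta values measured on twin-family
cohorts: nuclear families consisting of two parents, one monozygotic (MZ) or
dizygotic (DZ) twin pair, and a variable number of further full siblings.
The scientific question is how much of the between-person variation at each
CpG probe is attributable to additive genetic effects (heritability, h²)
versus the shared environment of the nuclear family and residual noise —
and, downstream, which DNA sequence variants (mQTLs) drive the heritable
fraction.

For one probe, let `y` be the vector of normalised methylation residuals
over `n` individuals. The variance-component model is

    y ~ N(Xb, Va·A + Vf·H + Ve·I)

where

* `A` is the additive genetic relationship matrix (twice the kinship
  coefficient): 1 on the diagonal and for MZ co-twins, 0.5 for first-degree
  relatives, 0 across families. It is built from the pedigree with the
  tabular method (founders assumed unrelated and non-inbred) and MZ co-twin
  entries are then set to 1.
* `H` is a 0/1 nuclear-household indicator. By default the whole nuclear
  family (parents included) shares a household — the observed nonzero
  spouse correlation motivates including the parents — with an
  `household="offspring"` option restricting sharing to the children.
* `X` is an intercept, optionally augmented with fixed covariates such as
  estimated cell proportions.

Heritability is `h2 = Va/(Va+Vf+Ve)` and the common-environment fraction
`c2 = Vf/(Va+Vf+Ve)`. The package fits the AE model (Va, Ve), the FE model
(Vf, Ve) and the AFE model (all three), always by maximum likelihood — not
REML — with the variances constrained non-negative.

### Estimation

Fixed effects are profiled out by generalized least squares inside every
likelihood evaluation, so the optimizer works only on the variance
components. Two numerical backends are used:

* **AE with complete data** — rotate by the eigenvectors of `A` (computed
  once per screen); the covariance becomes diagonal and one likelihood
  evaluation is O(n).
* **Anything else** (AFE/FE, or per-probe missingness) — exploit the fact
  that both `A` and `H` are block-diagonal by family: blocks are grouped by
  family size and factorized with batched Cholesky decompositions.

Optimization is bound-constrained L-BFGS-B (`ftol` 1e-12, `gtol` 1e-10) from
three starting points (equal split, null-heavy, familial-heavy) plus the
nested-null solution. Seeding the full model from its null guarantees the
nesting `loglik(full) >= loglik(null)` numerically. After optimization the
closed-form/optimized null fit is compared against the full fit and adopted
whenever it is at least as good, so true boundary solutions land exactly at
`Va = 0` (or `Vf = 0`). `Ve` has a tiny positive floor (1e-10 × var(y)) so
the degenerate perfect-heritability case (noise-free MZ pairs) converges to
`h2 -> 1` rather than a singular covariance.

### Testing a component

Because the tested variance sits on the boundary of the parameter space
under its null, the likelihood-ratio statistic is referred to an equal
mixture of a point mass at zero and chi-square(1): `p = 1` when the LRT is
zero, else `0.5·P(chi2_1 > LRT)`. The same boundary argument implies that
with a true-zero component about half of all ML estimates land exactly at
zero; the observed boundary fraction `p0` therefore bounds the fraction of
probes with a genuine genetic component from below by `100 − 2·p0·100`
percent (`zero_fraction_bound`). Boundary detection uses `h2 < 1e-6` since
optimizer output at a boundary is not reliably machine-zero.

Genome-wide significance is controlled with Benjamini–Hochberg FDR
(statsmodels step-up implementation behind `bh_fdr`).

## Relative-pair correlations

`classify_pairs` enumerates all within-family pairs (MZ, DZ, sibling —
including twin-to-non-twin pairs — parent-offspring with mother/father
subclasses, and spouse pairs defined as founder couples sharing a child),
plus optionally all cross-family pairs as "unrelated". Pair similarity is the
one-way ANOVA intraclass correlation `ICC = (MS_B − MS_W)/(MS_B + MS_W)`
with pairs as groups; per-probe ICCs are averaged unweighted across probes.
Under a purely additive model the class means are h² (MZ), h²/2 (DZ,
sibling, parent-offspring) and 0 (spouse, unrelated).

Two finite-sample effects matter when interpreting the class means. First,
the ANOVA ICC has an O(1/n_pairs) downward bias, visible for classes with
tens of pairs (MZ with ~50 pairs runs ~0.005 low at h² = 0.2); tests
therefore allow 3 Monte-Carlo SE plus a 0.01 bias allowance. Second,
all-pairs enumeration reuses individuals across pairs, which biases the very
large unrelated class slightly negative (about −1/n; −0.002 at n = 614);
`disjoint_pairs` subsamples non-overlapping pairs when an unbiased check is
needed.

## Normalization and QC

Each probe is normalised across samples with a quasi-likelihood binomial GLM
(logistic link, no integer trials) on chip, chip position, sex, age, age²,
sex×age and sex×age². Response-scale residuals (observed − fitted beta) are
the default, matching correlation analyses of normalised measurements; a
`scale="link"` flag returns logit-scale residuals instead. No global or
between-probe-type normalization is applied: variance partitioning is
within-probe, so the compressed Type II dynamic range does not affect it.
If the GLM separates or fails to converge, a linear model on logit-values
clipped to [1e-6, 1−1e-6] is used with a logged warning — a pragmatic
fallback, since the correct behaviour is not externally defined. Constant
probes are returned as all-zero residuals (the intercept fits perfectly).

Outliers further than 5 interquartile ranges from the nearest quartile
(strict inequality, type-7 linear-interpolation quartiles, single
non-iterated pass) are set to missing. With zero IQR any deviation from the
quartiles exceeds the fence, so only exact ties survive.

Probe filters: sex-chromosome probes, multi-mapping probes, probes with zero
CpGs, and probes with excess missingness or detection-p failures. The
missingness/detection cutoffs are the smallest integer `k` with
`P(Binomial(n_samples, rate) > k) < alpha/n_probes`, where the rate is the
pooled mean over all probes and samples, `alpha = 0.05`, and the Bonferroni
correction runs over probes. Probes containing annotated SNPs can be
excluded with an annotation filter (`n_snp == 0`); no variant database is
queried.

Cell composition is estimated per sample by constrained least squares of
the sample's signature-probe betas against reference cell-type profiles
(monocytes, B cells, NK, CD4+ T, CD8+ T, granulocytes): non-negative
weights summing to one, solved as NNLS with a strongly weighted sum-to-one
row and exact renormalisation. Estimated proportions enter the
variance-component model as fixed covariates when adjustment is requested
(the two-stage approach: normalization first, cell adjustment at the
heritability stage).

## mQTL scan

SNP QC removes variants with MAF < 0.05, Hardy–Weinberg exact-test
p < 1e-6 (computed on founder hard genotypes only, since within-family
genotype dependence distorts HWE counts), or missingness > 10%.

Association uses a measured-genotype GLS: the AE covariance of the probe is
estimated once under the no-SNP null, then each SNP's allelic-dosage effect
and standard error come from generalized least squares with that covariance
held fixed (a score-test-style economy that makes genome-wide scans one
vectorised pass), with a Wald p-value against the standard normal. On
unrelated individuals this collapses exactly to OLS with the null ML
variance. When residuals are logit-scale, effects read as the change in
log-odds methylated per allele. `region_effects` profiles a lead SNP against
every probe within a window (default 8 Mbp full span centred on the SNP)
and flags Bonferroni-significant probes; effects are signed, so
bidirectional regional architectures are visible.

## The synthetic-data generator

The generator defines the study conditions for every test:

* **Pedigree** — 117 families by default; zygosity MZ:DZ = 67:111 (the
  cohort's twin-pair ratio) and 0–3 extra siblings with mean 1.25, giving
  an expected 614 individuals. Parent ages uniform 35–55, offspring 10–20
  (adolescent cohort); MZ pairs share sex and age, DZ pairs share age.
* **Genotypes** — gene dropping: founder alleles Bernoulli(MAF), children
  draw one allele per parent, MZ co-twins copy the realised gamete pair.
* **Methylation** — the latent trait per probe is
  `b0 + covariates + mqtl_beta·dosage + a + f + e` on the logit scale, with
  `a` produced by an exact gene-dropping recursion (founders N(0, Va),
  children get the parental midvalue plus a Mendelian deviate N(0, Va/2),
  MZ co-twins share `a`), `f` shared within the nuclear family, `e`
  independent. Beta = expit(latent); Type II probes are shrunk linearly
  toward 0.5 with default factor s = 0.2 (the assay's compressed dynamic
  range, modelled minimally). Detection p-values are U(0, 1e-4) for passing
  entries and U(1e-3, 1) for failures; missingness is Bernoulli per entry.
  A spouse-correlation knob (`spouse_var`, default 0) adds a founder-couple
  shared component; the cohort's small observed spouse correlation is left
  unmodelled by default since its mechanism is not identified.
* **Cell composition** — Dirichlet around typical blood leukocyte means;
  optionally hierarchical (family-level Dirichlet mean first), which makes
  cell-signature probes a genuine familial confounder of h².

What the generator does **not** emulate: raw two-channel intensities,
bisulfite-conversion chemistry, probe cross-hybridisation sequences, linkage
disequilibrium between SNPs (SNPs are unlinked), genuinely heritable cell
composition (only family-correlated), or beta-distributed assay noise
(noise is Gaussian on the logit scale). Passing tests therefore demonstrate
correctness of the estimators under the assumed generative model, not
robustness to every artefact of real arrays.

## Numerical and design choices

* The generative scale is logit(beta); variance components and h² are
  defined on that latent scale. Analyses of simulated data in the tests use
  logit-scale residuals so the estimand matches the generative truth
  exactly; response-scale residuals add a small local-linearity attenuation
  at extreme beta values.
* ML (not REML): with an intercept-only mean the ML bias is O(1/n) and
  invisible at n ≈ 614 in the recovery tests.
* Optimizer tolerances: see above; convergence failures are flagged per
  probe (`converged=False`), never silently dropped. Non-positive-definite
  subset covariances are treated as infeasible points during optimization
  and lead to a flagged non-converged fit if no feasible optimum is found.
* Missing individuals are handled by per-probe subsetting of `y`, `A` and
  `H`; no imputation.
* Test problem sizes (4,000 null probes for boundary/type-I calibration,
  500 + 600 probes for recovery/slope, 2,000 probes for the correlation
  table, 100 replicates for mQTL power) were chosen so Monte-Carlo error is
  comfortably inside each tolerance while a full suite run stays desk-scale.

## Known limitations

* The AFE design cannot cleanly separate common environment from vertical
  (epigenetic) transmission; with Vf > 0 the AE model absorbs family
  variance into h² (tested behaviour, not a bug). No explicit
  transmission model is fitted.
* HWE exact test requires hard genotype calls; real-valued imputed dosages
  are skipped for HWE (but fine for association).
* The association scan holds the null variance components fixed per probe
  across SNPs; for very large single-SNP effects the SE is mildly
  conservative compared with a full joint re-fit.
* Imputation, phasing and LD-aware analyses are out of scope; genotype
  input is hard or real-valued dosage.
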