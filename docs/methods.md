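# Methods

## Statistical model

The unit of inference is an unordered SNP pair. With additive dosages
g₁, g₂ ∈ [0, 2] and a covariate block C (age, sex, genotyping site and
platform, top principal components), the interaction test compares

    full:    logit P(y=1) = β₀ + β₁g₁ + β₂g₂ + β₃ g₁g₂ + γᵀC
    reduced: logit P(y=1) = β₀ + β₁g₁ + β₂g₂           + γᵀC

by a likelihood-ratio statistic 2(ℓ_full − ℓ_reduced) referred to χ² with
**1 degree of freedom**: under the additive×additive encoding exactly one
parameter (the product term) is dropped. A genotypic (non-additive) encoding
would drop more terms and need more df; that encoding is out of scope here.

A discovery interaction is *gene-based replicated* when any SNP pair spanning
the same two genes — gene body ± 10 kb, inclusive on both boundaries — is
significant in an independent cohort. Replication significance is tiered:
marginal (LRT p < 0.01), top (p < 0.001), and family-wise Bonferroni at
α / C(n_genes, 2) over unordered gene pairs (91 genes → α/4095).

## Logistic fitter

Maximum likelihood by Newton/IRLS with monotone step-halving. Convergence:
max |score| < 1e-8, or relative log-likelihood change < 1e-10 (then accepted
only if max |score| < 1e-4). Quasi-separation (any |β| > 30) and failed
Hessian solves return a *flagged* non-converged fit rather than raising, so
exhaustive scans never abort; non-converged or rank-deficient pairs are
labelled non-testable and excluded from candidate/top-model selection. A
product term numerically inside the span of the reduced design (residual
variance < 1e-10 of its norm) is non-testable, not a zero-df test.

Negative LRT statistics can arise only from optimizer noise; values in
(−1e-8, 0) are clamped to 0 silently, values below −1e-8 are clamped and
counted on the result (`clamped`), and the null-calibration tests verify such
events are absent at scan scale.

Wald p-values are used for the single-SNP GWAS stage (standard, fast); the
LRT is reserved for the interaction stage. The two agree to |Δp| < 0.01 in
the asymptotic regime, which the suite checks.

## QC and encoding conventions

- MAF is computed from dosages as min(p̄, 1−p̄), p̄ = mean(dosage)/2, on the
  samples surviving the sample-level call-rate filter, which runs **before**
  marker filters (the PLINK convention).
- Marker filters: MAF ≥ 0.05, call rate ≥ 0.99, info ≥ 0.7 when an info
  score is present (absent = genotyped, not filtered). Boundary values pass.
- Missing genotypes are mean-imputed by default, which keeps the exhaustive
  pair scan rectangular and propagates into the product term (the design
  matrix stays internally consistent); a complete-case per-test policy is
  available (`encode_additive(..., "drop-sample-per-test")`).
- VCF: DS takes precedence over GT; multi-allelic records are rejected.
- LD pruning is greedy over the candidate list sorted by ascending
  main-effect p, so the strongest signal of each LD clique survives; r² is
  the squared Pearson correlation of dosages. Pruning is genome-wide across
  the candidate set (candidates are sparse after the p < 0.01 filter).
- Candidate (p < 0.01), discovery (LRT p < 1e-05) and replication
  (0.01 / 0.001) thresholds are strict inequalities.
- A SNP annotating to several overlapping gene windows contributes to every
  implied cross-gene pair (inclusive choice; flagged in outputs via the
  annotation table).

## Diagnostics

- Genomic inflation factor λ = median(χ²₁ quantiles of observed p) / 0.45494
  (the median-based estimator).
- KS uniformity of the discovery scan: p-values above the 1e-05 threshold are
  rescaled u = (p − t)/(1 − t) and tested against Uniform(0,1) — the
  conditional-uniform reading of "everything above the threshold is noise".
  The plain (unrescaled) test is available via `conditional=False`; at
  t = 1e-05 the two are numerically indistinguishable.

## GREML variance explained

GRM: A_jk = (1/M) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2p_i(1−p_i)) with allele
frequencies from the analyzed sample; missing dosages contribute 0 after
centering. The binary phenotype is analyzed on the observed 0/1 scale with
y = Xb + g + e, Var(y) = Aσ²_g + Iσ²_e, maximized by average-information
REML with an EM-step fallback whenever the AI step fails or decreases the
restricted likelihood, components floored at 1e-8·var(y), convergence at
|Δ log-lik| < 1e-8. All updates run in the eigenbasis of A: one symmetric
eigendecomposition up front makes each likelihood/score/AI evaluation O(n).
A GRM that is numerically a multiple of the identity leaves σ²_g and σ²_e
aliased and is reported as degenerate rather than fitted. Covariate columns
aliased with earlier ones (e.g. a constant duplicating the intercept) are
dropped — fixed effects absorb them.

Observed→liability conversion: h²_liab = h²_obs · K²(1−K)² / (P(1−P)z²),
with K the population prevalence (default 0.0186), P the sample case
proportion, and z the standard normal density at Φ⁻¹(1−K). This is the
standard ascertainment-corrected transform for case-control GREML.

## Synthetic cohorts: what they emulate and what they do not

The generator exists so every pipeline stage is testable without
controlled-access genotypes. Design:

- **Genotypes**: per-SNP MAF drawn uniformly from `maf_range` (default
  0.1–0.4, the common-variant range after a 5% MAF filter). Each haplotype is
  a thresholded latent Gaussian; within an LD block of `ld_block_size`
  adjacent SNPs the latents are equicorrelated with `ld_rho`, so each SNP is
  exactly HWE marginally while adjacent-SNP r² rises with ld_rho
  (dichotomization attenuates: ld_rho = 0.95 at matched MAFs gives dosage
  r² ≈ 0.61, just above the 0.6 pruning cutoff).
- **Confounding**: `n_axes` standard-normal ancestry axes shift per-SNP
  allele frequencies through N(0, axis_maf_shift²) loadings *and* enter the
  liability, so PC adjustment in the GWAS stage is load-bearing — a test that
  omits it visibly inflates λ.
- **Phenotype**: logit P(y=1) = β₀ + Σ main β·g + Σ interaction β·g₁g₂ +
  covariates. β₀ is calibrated by bisection so the *expected* case fraction
  (mean of the conditional probabilities over the realized predictors) equals
  `target_prevalence`; the phenotype stays marginally Bernoulli at that
  prevalence rather than being quota-sampled.
- **Heterogeneity**: `cohort_specific_snps` makes a cohort pair draw distinct
  within-gene SNP ranks for the same causal gene(s) — same genes, disjoint
  causal SNPs.
- **Missingness/info**: MCAR masking; info scores are synthetic labels
  (uniform 0.2–0.7 on a chosen fraction of variants) that exist to exercise
  the threshold filters, not estimates from data.
- Covariate defaults (per-SD log-odds ~0.2–0.4, 2 ancestry axes,
  3 sites / 2 platforms) give a mildly confounded cohort; ages ~N(60, 10)
  match an adult ophthalmology study population.

Not emulated: coalescent/haplotype-panel realism, imputation uncertainty,
relatedness, sex chromosomes. Passing tests therefore demonstrate the
*statistical machinery* (calibration, power under the stated generative
model, heterogeneity handling), not performance on any real cohort.

## Problem sizes used by the validation suite

Chosen as the package's standard desk-scale conditions:

- Interaction effect sizes ln(1.5)–ln(2.5): the two-stage design's reported
  effects are p-values only, so defaults were picked once for reasonable
  power at 2000–4000 samples and not revisited.
- Heterogeneity benchmark: β₃ = ln 2.2, 4000 samples/cohort, 5-SNP causal
  genes on a 30-SNP / 6-gene panel (LD blocks aligned to genes, ld_rho 0.3),
  50 trials. Discovery = exhaustive scan, replication = all cross-gene pairs
  of the discovery top model's gene pair vs the exact discovery SNP pair,
  both at p < 0.001.
- Null calibration: 500 replicate null pairs at n = 2000 for type-I error;
  one 142-SNP cohort (C(142,2) = 10 011 pairs) for the interaction-p
  inflation factor and KS uniformity.
- GREML recovery: planted h²_obs = 0.4, n = 1000, M ≈ 500 SNPs, 50 fits.
- Golden pipeline fixture: 50 SNPs / 10 genes / 1200 samples per cohort with
  one planted cohort-specific gene-pair interaction; its stage-count sequence
  is frozen as a regression oracle.

## Known limitations

- The exhaustive scan is dense-matrix logistic regression: fine to ~5×10³
  candidate SNPs (~10⁷ pairs), not a Boolean-algebra accelerated screen.
- Single-component GREML only; no multi-component, dominance or LDSC models.
- The KS construction above the discovery threshold is one of two defensible
  readings (conditional vs plain uniform); both are exposed, conditional is
  the default.
- Whether the GWAS stage should report Wald or LRT p-values is a convention
  choice; Wald is the default and the asymptotic-agreement test bounds the
  difference in the regime where candidate selection operates.
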