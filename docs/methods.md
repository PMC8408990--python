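# Methods

## Scope and model

`xtwas` implements a multi-tissue TWAS chain: cross-tissue penalized
training of cis gene-expression prediction models, gene-level association
from GWAS summary statistics, Cauchy-combination of per-tissue P values,
Bonferroni selection with LD-extensive-region exclusion, and Bayesian
fine-mapping of regions with correlated predicted expression. All stages
operate on plain tab-delimited artifacts so any stage can be fed externally
produced inputs that match the schemas in `xtwas.formats`.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
any particular cohort.

**Genotypes.** Each gene receives an independent cis block of SNPs (default
20). Dosages are sums of two haplotypes; each haplotype thresholds a latent
AR(1) Gaussian vector (adjacent correlation `ld_rho`, default 0.7) at the
normal quantile of a MAF drawn uniformly from `maf_range` (default
0.05–0.5). This yields realistic banded LD with exactly known structure;
`copula_dosage_correlation` provides the Monte-Carlo mapping from latent to
dosage-scale correlation used in tests. A `shared_blocks` mode places two
genes on one block to create the correlated-predicted-expression setting
fine-mapping must resolve. Blocks are laid 3 Mb apart on one chromosome so
the ±1 Mb cis-window isolates each gene.

**Expression.** Per gene, `n_causal_eqtl` SNPs (default 2) receive
per-tissue effects from a multivariate normal with pairwise correlation
`cross_tissue_cor` (default 0.8, the strong sharing regime that motivates
joint training). The genetic score is rescaled to variance `h2_expr`
(default 0.2) and N(0, 1 − h2_expr) noise is added, so the heritable and
noise shares sum to one by construction. The scaling constant is computed on
the full panel rather than per-tissue donor subsets so that perfect
cross-tissue correlation yields literally identical effect vectors; realized
per-tissue heritability is therefore ≈ h2_expr rather than exact. Tissue
donor subsets are drawn without replacement and overlap, with default
fractions matching the relative sample sizes of ten brain/pituitary tissues
in an 838-donor reference panel (205/838, 147/838, …). The default GWAS size
is 455,258.

**Expression preprocessing.** `preprocess_expression` applies a rank-based
inverse normal transform (Blom offset `(r − 3/8)/(n + 1/4)`, average ranks
for ties) per gene, then residualizes on a user-supplied covariate matrix by
least squares; the pipeline passes an intercept-only matrix for simulated
data, which already lives on the residual scale. Rank-deficient covariates
are rejected with the collinear columns identified by pivoted QR.

**GWAS summary statistics.** The trait loads on each causal gene's
tissue-averaged genetic expression score. Per block, the standardized
per-SNP effects `b` induce marginal effects `γ = R b / sd(y)` and
`Z ~ MVN(√n · γ, R)` with `R` the panel dosage correlation (ridge 1e-8 for
the Cholesky factor). Simulating at summary level matches what the pipeline
consumes; `simulate_gwas_individual` draws an explicit cohort and computes
per-SNP regression Z-scores as the slow cross-check, and is what the
summary/individual equivalence test uses.

## Model training

The objective is

  Σ_t (1/(2N_t)) ‖y_t − X_t β_t‖² + λ₁ Σ_{j,t} |β_jt| + λ₂ Σ_j ‖β_j·‖₂ .

The 1/(2N_t) loss normalization equalizes tissue contributions despite
unequal sample sizes and makes the λ scales interpretable across tissues.
The solver is plain proximal gradient (ISTA) with step 1/L (L = largest
per-tissue Gram eigenvalue), using the exact sparse-group proximal map —
entrywise soft-threshold by sλ₁ then row-wise group shrinkage by sλ₂, whose
composition is the exact prox for this penalty. A fixed step and monotone
guard give a provably non-increasing objective trace; convergence is
declared at relative objective change < 1e-6 (default) or flagged (not
raised) at 5,000 iterations. Optimality can be certified independently via
`kkt_violation`, the maximum violation of the subgradient conditions.

**Hyperparameter tuning.** A geometric ladder of 10 values per penalty from
λ_max = max_{j,t} |X_tᵀy_t|/N_t down to 1e-3·λ_max, crossed into 100 pairs
(sizes configurable), is used identically in every fold of a five-fold CV.
Validation MSE is averaged over tissues within a fold, then over folds;
ties go to the larger (λ₁, λ₂) — the sparser model — and, among duplicates,
the first grid entry. Standardization statistics come from each training
fold only; validation samples are transformed with them, so no leakage.
Fold assignment is seeded per gene.

**Performance and retention.** Performance is the Pearson `r` between
pooled out-of-fold predictions and observations, with the two-sided P from
`t = r·√((n−2)/(1−r²))`; a constant prediction vector is defined to have
r = 0, p = 1, and r² is defined as 0 when r < 0. Models are retained iff
r ≥ 0.1 and P < 0.05, both boundaries as written; the per-tissue counts of
retained models and of models with r² ≥ 0.01 are reported. Final weights
are a full-data refit at the selected pair (performance still reported from
out-of-fold predictions only), mapped back to the effect-allele dosage
scale.

The point of the shared-grid / out-of-fold design is that in-sample
evaluation of a model tuned on the same data overestimates performance and
floods downstream testing with low-quality models; the suite asserts this
directly (in-sample r of a full-data refit exceeds out-of-fold r on pure
noise essentially always).

## Association

Allele harmonization matches model and GWAS variants by id, negates Z for
swapped allele frames, and drops strand-ambiguous (A/T, C/G) and unmatched
variants — ambiguous SNPs are dropped rather than frequency-resolved, which
is conservative and deterministic. The gene statistic is
`Z_g = Σ_l w_l (σ_l/σ_g) z_l` with `σ_g² = wᵀΣw` from the full reference
panel's dosage covariance; genes with σ_g² < 1e-8 are untestable and
skipped with a reason. Effects are reported per SD of predicted expression:
`se_g = 1/(σ_g√n)`, effect = `Z_g·se_g`, 95% CI = effect ± 1.96·se_g, with
odds-ratio columns as exponentials. This per-SD convention is a
deliberately chosen reporting convention, not an identity of the statistic.

## Cross-tissue combination

Per-tissue P values are mapped to standard Cauchy quantiles and averaged;
the combined P is the analytic Cauchy tail of the average. Terms use the
reciprocal form 1/tan(πp) below p = 0.25 (algebraically identical,
numerically well conditioned in the tail) and 1/(pπ) below 1e-15; the
combined tail uses arctan(1/T)/π for T > 0 and 1/(πT) beyond 1e15, floored
at 1e-300. Each gene combines however many tissues carry a retained model
(d varies by gene). Bonferroni uses m = number of genes combined, strict
`p < α/m`. Genes overlapping the configurable blacklist (default extended
MHC, chr6:25–34 Mb) are reported but removed from the significant list;
gene spans and regions are both treated as half-open intervals, so touching
at an endpoint is not an overlap.

A calibration caveat measured by the acceptance checks: with strongly
dependent per-tissue P values (cross-tissue Z correlation ≈ 0.7 in the
default null study), the Cauchy combination is exactly calibrated in the
tail but its mid-range null distribution deviates slightly (mean combined
P ≈ 0.52 rather than 0.50 at d = 4). Type-I error at α = 0.05 is correct
within Monte-Carlo error; a Kolmogorov–Smirnov test at large n can detect
the mid-range deviation. This is a property of the combination test itself
under dependence, and is why the tail — where gene discovery happens — is
the guarantee that matters.

## Fine-mapping

Genes are grouped into regions as connected components of |Ω| > 0.05 within
a chromosome, where `Ω_ij = w_iᵀΣw_j/(σ_iσ_j)` is the correlation of
predicted expression on the union SNP frame (zero-padded weights). Within a
region, `z | c ~ MVN(0, Ω' + v·Ω'_{·c}Ω'_{c·})` with `Ω' = Ω + ridge·I`
(ridge 0.1 for invertibility — documented because it perturbs Bayes
factors). Woodbury and determinant identities reduce each configuration's
log Bayes factor to |c|-dimensional forms:

  log BF(c) = (v/2)·z_cᵀ(I + vΩ'_cc)⁻¹z_c − ½·logdet(I + vΩ'_cc).

All subsets with |c| ≤ max_causal (default 3; enumeration capped at 25
genes) are enumerated, including the null set, with independent
Bernoulli(p₀) priors (p₀ = 1e-3, effect prior variance v = 40; both
configurable defaults in the range fine-mapping tools ship with). PIPs are
configuration-posterior sums; the null model participates in normalization,
so weak data leave mass on the null and every PIP below p₀. The 90%
credible set ranks genes by PIP (ties by gene id) and includes genes until
the cumulative normalized PIP reaches 0.9 (inclusive ≥, with a 1e-12
tolerance so exact-boundary sums terminate on the boundary gene).

## Numerical and interface conventions

- Coordinates are 1-based; the cis-window [TSS − 1 Mb, TES + 1 Mb] is
  closed on both ends; blacklist overlap is half-open.
- All TSVs write reals with 12 significant digits; reading back reproduces
  the tables exactly at that precision. Malformed rows are rejected with
  1-based line numbers; missing header columns are listed by name.
- Every stage is a pure function of (config, seed); manifests record
  SHA-256 checksums, and repeated runs reproduce them bit-exactly. The CLI
  accepts `--threads` for interface compatibility; results are independent
  of it.

## Problem sizes used in tests and acceptance checks

The test and acceptance workloads are sized for a laptop-class single CPU:
solver-oracle comparisons use ≤ 10 SNPs × ≤ 3 tissues (100 instances);
null calibration uses 500 genes × 4 tissues (2,000 gene-tissue pairs) at
n_ref = 600; summary/individual equivalence uses 20 genes at n_gwas = 5,000;
recovery uses 50 single-causal-eQTL genes at n_ref = 2,000, h² = 0.5 and 50
two-gene shared-block replicates with the causal gene's effect calibrated
to an expected TWAS |Z| of 3. End-to-end pipeline tests use ~10 genes, 2–3
tissues, and reduced λ ladders (3–4 values per axis).

## Known limitations

- The generator produces disjoint (or pairwise-shared) cis blocks, AR(1)
  LD, and Gaussian residual-scale expression; it does not emulate real human
  LD maps, raw counts/TPM, latent-factor structure, or cross-gene
  co-expression. Passing tests therefore demonstrate correctness of the
  statistical machinery under the assumed model, not performance on real
  cohorts.
- Fine-mapping uses the gene-level Ω formulation with exhaustive
  enumeration; there is no stochastic search for very large regions.
- The Cauchy combination's mid-range calibration under dependence is
  approximate (see above).
- Strand-ambiguous SNPs are dropped, never frequency-resolved; GWAS
  ingestion assumes pre-computed Z-scores.
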