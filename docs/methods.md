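# Methods

## Model and null distribution

For q quantitative traits and m SNPs, the observed data are the Wald
t-statistics Z_jk of SNP k's coefficient in the univariate linear
regression of trait j on SNP k plus covariates (standard GWAS practice;
per-SNP univariate models, not a joint multi-SNP fit). Under the global
null — no SNP associated with any trait — vec(Z) (column-stacked, so the
SNP index is the outer block index) is asymptotically N(0, Δθ ⊗ Δρ) with

    corr(Z_jk, Z_j'k') = ρ_jj' · θ_kk',

ρ_jj' the phenotypic correlation and θ_kk' the partial correlation of the
two SNPs' dosages given the regression covariates. The factorization is
verified empirically in the test suite: simulated covariate-adjusted Wald
statistics reproduce the product entrywise within Monte-Carlo error at
2×10⁴ replications.

## Correlation estimation

**Trait correlation Δρ.** Sample Pearson correlation of per-trait Z-score
columns over L approximately independent null SNPs. Null SNPs are selected
as those with two-sided p > .05 in every trait, then greedily LD-pruned at
r² < 0.1 against the reference panel (threshold configurable; pruning
scans candidates in input order and keeps a SNP unless it is in LD with an
already-kept one). The minimum accepted L is 50; the simulation engine
pools 20 replicates × 2000 SNPs (see the rejection-rate studies below),
matching the precision of the genome-wide supply a real scan provides.

**SNP correlation Δθ.** Three covariate regimes:

1. *Environment-only covariates* are independent of genotype, so Δθ is the
   plain Pearson correlation of panel dosages.
2. *Stratification covariates*: dosages are first projected on
   I − C(CᵀC)⁻¹Cᵀ, where C holds an intercept plus the panel's top-s
   principal coordinates; Δθ is the Pearson correlation of the residuals.
3. *Mixed*: environmental covariates can be ignored; identical to case 2.

Principal coordinates are classical multidimensional scaling of pairwise
Euclidean distances between individuals' (mean-imputed) dosage vectors,
computed exactly via the SVD of the row-centred dosage matrix. Axis signs
are fixed by making each axis's largest-magnitude SNP loading positive so
results are machine-independent. The study-level default is s = 2 axes.

Missing dosages are mean-imputed per SNP up to a 5% missingness ceiling
(configurable); beyond it the SNP is rejected.

**Regularization.** Estimated correlation matrices can be numerically
singular (duplicated or near-duplicated SNPs). Before any quadratic form,
eigenvalues are clipped from below at ε_pd = 1e-6 and the matrix rescaled
to unit diagonal; inputs already positive definite at the floor pass
through unchanged. The floor guarantees invertibility of Δρ, Δθ and every
principal submatrix of their Kronecker product without materially
perturbing well-conditioned estimates.

## Test statistics

- **T1 (per-trait)**: Z{j}ᵀ Δθ⁻¹ Z{j} ~ χ²_m for each trait row, p-values
  p_1…p_q.
- **T2 (per-SNP)**: Z[k]ᵀ Δρ⁻¹ Z[k] ~ χ²_q for each SNP column, p-values
  p_[1]…p_[m].
- **T3 (truncated)**: for each η in Ω = {0.1, …, 0.9, 1}, keep the
  s = ⌈ηM⌉ largest |vec(Z)| entries (M = qm; ties broken by ascending
  vector index, a deterministic convention) and form Z_ηᵀ Δ_η⁻¹ Z_η with
  Δ_η the matching principal submatrix of Δθ ⊗ Δρ. At η = 1 the statistic
  is the full quadratic form with an exact χ²_M p-value.

Each family is combined with the Cauchy combination transform
tan((0.5 − p)π) under uniform weights (1/q, 1/m, 1/#Ω respectively —
general non-negative weights summing to one are supported for the
combination primitive itself), and the three resulting p-values P1, P2, P3
are combined the same way with weights 1/3. Quadratic forms are evaluated
by Cholesky factor-and-solve, never explicit inversion, and agree with the
explicit-inverse computation to 1e-8 (tested).

**p-value clipping.** Before every tangent transform, p-values are clipped
to [1e-14, 1 − 1e-6]. The floor reflects the double-precision limit of the
tan/arctan round trip: probabilities below 1e-14 are not representable, so
no reported p-value is smaller. The ceiling is deliberately much looser
than the floor: a component p-value of exactly 1 (which genuinely occurs,
e.g. a row of all-zero Z-scores) would otherwise map to a tangent of order
−10¹⁴ and single-handedly veto strong evidence carried by other
components; capping at 1 − 1e-6 bounds that drag at tan ≈ −3×10⁵ while
leaving the null tail untouched (a null p-value exceeds the cap with
probability 1e-6). Empirical type-I error at the 1e-3 level is identical
under either cap.

**Degenerate dimensions.** q = 1 or m = 1 are permitted; T1/T2 collapse to
single quadratic forms, and the Cauchy combination of one p-value is the
identity.

## Calibration of the truncated statistics

For η < 1 the truncated statistic has no classical null law. It is
calibrated by parametric bootstrap: draw B vectors from N(0, Δθ ⊗ Δρ),
compute every truncated statistic, and match the first three cumulants of
each level's sample (mean K, variance L, third central moment Mu) to a
generalized chi-square surrogate a·χ²_d + b via

    a = Mu / 4L,    b = K − 2L²/Mu,    d = 8L³/Mu².

The surrogate's survival function prices observed statistics, including
tails far below 1/B. Matching requires right skew (Mu > 0), which
quadratic-form mixtures have in practice; a violation raises an error
rather than silently mis-calibrating (no silent fallback is provided — a
symmetric or left-skewed bootstrap sample indicates the surrogate family
is wrong for the input covariance).

Default B = 100 000: large enough that cumulant noise is negligible
against the ±20% relative-tail-accuracy verified in the acceptance tests,
small enough to fit in seconds. A calibration depends only on (Δθ, Δρ), so
it is computed once per covariance pair and reused across genes and across
simulation replications; tables serialize to JSON (η, a, b, d, B, seed).

**Nested evaluation.** All truncation levels of one draw are computed from
a single factorization: permuting Δ into descending-|z| order makes the
kept sets nested, the leading s×s block of the permuted Cholesky factor is
the factor of the leading s×s principal submatrix, and one triangular
solve plus a cumulative sum of squares yields every level at once. This
replaces #Ω solves per draw with one, and is what makes 10⁵-replication
studies and 10⁵-draw calibrations run in minutes on one CPU. The batched
path is tested to agree with the direct per-level submatrix solve to 1e-8.

## Synthetic data

The simulation engine emulates the study design end to end.

**Genotypes** follow a latent-Gaussian threshold model: per haplotype, a
latent vector ~ N(0, Σ_LD) is thresholded at Φ⁻¹(MAF) and the dosage is
the sum of two independent haplotypes. Defaults mirror the study
conditions: cohort size n = 2504 (the size of a standard public reference
panel), AR(1) LD, MAF drawn uniformly from [0.05, 0.5]. This reproduces
the LD *class* of real panels — smooth, distance-decaying dosage
correlation — but not their empirical block structure, allele-frequency
spectrum, or long-range LD; a real panel matrix can be substituted
directly. Note the realized dosage correlation is an attenuated transform
of the latent correlation (tetrachoric-style), which is irrelevant here
because Δθ is always estimated from the generated panel, never assumed.

**Phenotypes** follow y_ij = α_j + Σ_k g_ik β_jk + c_i γ_j + ε_ij with
per-individual error vectors ~ N(0, Δρ) and a one-dimensional covariate c
(standard normal by default; a two-cluster mean-shift mode emulates
stratification so the principal-coordinate adjustment path can be
exercised end to end). Signal allocations NONE / SINGLE / ROW / COLUMN
place the non-zero entries of the q×m coefficient matrix.

**Wald statistics** are computed for all (j, k) at once by residualizing
phenotypes and genotypes on the covariate design (Frisch–Waugh–Lovell),
which is algebraically identical to fitting each covariate-adjusted
regression separately (tested against statsmodels OLS at 1e-10).

**Rejection-rate studies** fix the panel, covariate, estimated Δθ and Δρ,
and one bootstrap calibration per scenario, then redraw phenotype noise
per replication; replications are processed in vectorized chunks with
seeds derived from the scenario seed through `numpy` SeedSequence
spawning, so runs are bitwise reproducible and trivially parallelizable.
Rejections are counted with strict inequality p < α. Trait correlation is
estimated from the Wald Z-scores of freshly generated independent null
SNPs — the same route a real analysis uses. Z-scores taken against a
single phenotype replicate converge (in the number of SNPs) to that
replicate's *realized* residual correlation, which deviates from the
generating trait correlation by O(1/√n); since the tested replications
redraw the phenotype noise, the engine pools null-SNP Z-scores over 20
independent replicates × 2000 SNPs, reproducing the precision a
genome-wide estimate has for the cohort it is applied to. The SNP
correlation entering the test is the partial correlation of panel dosages
given the actual regression design — the exact conditional covariance of
the Wald statistics for the fixed panel and covariate.

The q = 6 non-identity trait correlation used in the null-calibration
study is a fixed matrix emulating a panel of six plasma fatty-acid-like
traits (two strongly coupled pairs, moderate cross-correlations); it is
defined once in `twt.simulate.default_trait_correlation` and not tuned.

**Problem sizes.** The shipped studies use 10⁵ replications with B = 10⁵
calibration (acceptance script and heavy tests), 10⁶ draws for the
surrogate-tail accuracy check, and 2×10⁴ replications for the
product-identity and uniformity checks — sizes chosen so each check's
Monte-Carlo error is small against the tolerance it asserts.

## What passing tests do and do not show

Synthetic genotypes cannot certify behaviour on real LD blocks, real MAF
spectra, imputation dosages, or binary traits (logistic Wald statistics
are out of scope). What the simulations do establish: the Kronecker
product identity holds for covariate-adjusted statistics; the surrogate
tail is accurate to ±20% down to 10⁻³; and the combined test's type-I
error at the 10⁻³ level is within Monte-Carlo error of nominal under
realistic correlation structure.

One caveat is intrinsic to the method, not to this implementation: the
Cauchy combination is *tail*-accurate under arbitrary dependence, but its
combined p-value is mildly conservative in the bulk when the inputs are
strongly dependent (the three components share one Z matrix; at the median
the combined p-value's CDF sits ≈ 0.05 below uniform). Consequently the
final p-value fails a strict uniformity test on its whole distribution
even though its rejection rates at stringent levels — the regime gene
scans operate in — are calibrated. Component p-values from the quadratic
forms (p_j, p_[k], and the η = 1 statistic) are exactly uniform given the
true covariance.

## Summary-statistics preprocessing

Allele harmonization keeps a SNP only when its (counted, alternative)
allele pair matches the reference panel exactly (default), or additionally
accepts reversed pairs with a Z sign flip in swap mode — except
strand-ambiguous A/T and C/G variants, which are dropped in swap mode
because orientation cannot be resolved from labels alone. Harmonization
never alters |Z|.

SNPs map to genes by position: a gene's testing window is its interval
widened by a symmetric flank (default 5 kb), 1-based inclusive at both
edges; BED inputs are converted from 0-based half-open on read. A SNP in
overlapping windows joins every gene. Genes with fewer than m_min = 2 or
more than m_max = 500 SNPs are excluded (both configurable; the extremes
make quadratic forms either trivial or numerically fragile). Within a
gene, SNPs are ordered by position, and the Z-matrix column order always
matches the LD-matrix order. Multiple testing across genes uses Bonferroni
at the configured family-wise level, reported alongside raw p-values.

## Known limitations

- Wald statistics are assumed to come from per-SNP univariate linear
  models; meta-analysed or logistic summary statistics are not supported.
- The truncated statistics' surrogate is a three-moment approximation;
  extreme tail accuracy (beyond the verified 10⁻³ relative regime) relies
  on the surrogate family's adequacy, not on direct simulation.
- No liftover: summary statistics, panel and gene annotation must share a
  genome build.
- Identifying *which* trait or SNP drives a signal is limited to
  inspecting the reported component p-values.
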