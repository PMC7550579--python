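# Methods

`prstrial` implements, end to end, the statistical pipeline used to ask
whether common polygenic risk moderates the response to social skills group
training (SSGT) versus standard care in a randomized trial for autistic
children and adolescents.  Because the motivating trial's genotype and
phenotype data are private, the package ships a synthetic-data generator
that reproduces the study's design conditions, and every downstream stage
is validated against that generator's known truth.

## The outcome model

The primary outcome is the parent-rated Social Responsiveness Scale (SRS),
a 65-item instrument with total score in [0, 195] (higher = more severe),
recorded at pre-intervention, post-intervention, and 3-month follow-up.
For individual *i* at center *c* and timepoint *t*, the three-way mixed
model is

    SRS_ict = b0 + b_P PRS_i + b_T[t] + b_A arm_i + (interactions)
              + b_age age_i + b_sex sex_i + Σ_k b_k PC_ki + b_CNV cnv_i
              + u_c + v_i + e_ict,
    u_c ~ N(0, s2_center),  v_i ~ N(0, s2_individual),  e ~ N(0, s2_resid)

with treatment contrasts (pre-intervention and standard care as
references), so the three-way products `PRS x post x SSGT` and
`PRS x followup x SSGT` read directly as the SRS-point difference per PRS
standard deviation at that timepoint in SSGT relative to standard care;
positive values mean a worse (inferior) SSGT outcome.  The two-way variant
drops the arm factor and is intended for single-arm subsets.  When the
ADHD score is analyzed, ADHD comorbidity enters as an additional fixed
effect; the CNV adjustment can be the clinically-significant-carrier flag,
the large-CNV flag, or absent.

Estimation is REML through `statsmodels` MixedLM with a center random
intercept and an individual variance component nested within centers.
Inference is Wald z without a degrees-of-freedom correction — the common
default at this design size; the package does not implement Satterthwaite
or Kenward-Roger adjustments, and the type-I-error simulations below are
the empirical check that this choice is calibrated at n = 188.  Three
scores (ASD, ADHD, educational attainment) define the testing family, so
the family-wise threshold is alpha / 3 = 0.0167.

Unbalanced panels from dropout are handled by the mixed-model likelihood;
no imputation is performed.

### Variance explained

Marginal R² is var(Xb) / (var(Xb) + s2_center + s2_individual + s2_resid);
conditional R² adds the two random-intercept variances to the numerator
(the Nakagawa–Schielzeth decomposition for random-intercept Gaussian
models).  The PRS contribution is reported as a difference: the full model
minus the model with *every* PRS-containing term removed (main effect and
all interactions), both fit by REML with otherwise identical structure.
Dropping only the interactions is available behind the same machinery by
constructing the reduced design manually, but the all-terms reading is the
default because "the model without PRS" most plausibly means no PRS
anywhere.

### The zero-variance member

A mixed model whose random-effect variances are zero is ordinary least
squares.  This reduction cannot be demonstrated through an iterative REML
fit on finite data: with truly zero generating variance the REML maximum
for a variance component still lands at an interior positive value with
positive probability, leaving the GLS fixed effects ~0.2 SRS points from
OLS at n = 188.  `fit_mlm(..., varcomp_fixed={"center": 0, "individual": 0})`
therefore evaluates the GLS estimator at pinned variance components in
closed form (own linear algebra, no optimizer); the test suite compares
that path against an independent OLS implementation and they agree to
~1e-13.

## Polygenic scores

Clump-and-threshold construction:

1. **Harmonization.** Reference effect alleles are matched to the panel's
   counted alleles directly, then through strand complement; a mismatch in
   the counted/other orientation flips the dosage (2 − d).  Palindromic
   (A/T, C/G) variants are kept by default — the synthetic panel has no
   strand ambiguity — with `drop` available for real data.
2. **Clumping.** Greedy by ascending GWAS P (ties: position, then id):
   each index claims every variant on its chromosome within 500 kb
   (|Δbp| ≤ window × 1000, the PLINK `--clump-kb` reading of "within a
   window") whose genotype r² with it is ≥ 0.1.  r² is the squared Pearson
   correlation of dosages over pairwise-complete individuals.
3. **Scoring.** At each threshold Pt in {0.01, 0.05, 0.1, 0.5, 1}, the
   score is the sum of ln(OR) × oriented dosage over retained variants
   with P < Pt.  Missing dosages contribute the variant's mean oriented
   dosage (scoring-tool default); omit-and-ignore is available.
4. **Standardization.** Each column is z-scored (ddof = 1) on the analyzed
   set.

## Genotype QC

Per-individual filters first (genotype failure rate > 0.03;
heterozygosity beyond 3 cohort SDs of the cohort mean), then per-marker
filters in a fixed, logged order: combined individual missingness > 0.1,
marker missingness > 0.05, MAF < 0.05 (non-missing calls only), exact
Hardy–Weinberg P < 1e-6.  The HWE test is the conditional exact test
(enumeration over heterozygote counts with the observed parity via the
stable log-recurrence, two-sided by summing all tables no more probable
than the observed).  Filter order changes denominators, so each report
records the order applied and the first reason that removed each item.
Sex checks and relatedness pruning need raw-array/IBD inputs and are out
of scope; `apply_exclusion_list` accepts an external exclusion list.

## Gene-set association

A transparent, permutation-calibrated variant of the MAGMA-style
competitive workflow (a defined re-implementation, not a clone of MAGMA's
gene model):

- **Change scores:** endpoint SRS minus pre-intervention SRS per
  individual; individuals missing the endpoint are excluded and counted.
- **Residualization:** the change score is regressed once on age group,
  sex, intervention arm, four ancestry PCs and CNV carrier flags; gene
  statistics use the residual.
- **Gene statistic:** mean squared Pearson correlation between each mapped
  polymorphic SNP's (mean-imputed) dosage and the residual.  SNPs map to a
  gene when their position lies in [start − w, end + w] (inclusive,
  w = 0 kb by default).
- **Calibration:** n_perm permutations of the residual vector, one shared
  permutation order across all genes per replicate (preserving inter-gene
  correlation); P = (1 + #{null ≥ obs}) / (n_perm + 1), clamped to
  [1/(n_perm+1), 1 − 1/(n_perm+1)], and z = probit(1 − P).
- **Competitive test:** OLS of gene z on set membership plus n_snps,
  log n_snps, gene length and log length (MAGMA's default size
  covariates).  Positive beta = the set's genes carry more
  change-associated signal, i.e. an inferior-response signal.
- **Correction:** Bonferroni across all sets at one endpoint by default;
  Benjamini–Hochberg available.

## Bootstrap power

Cluster bootstrap: individuals are resampled with replacement (each
carrying all longitudinal records and its original center), duplicates
receive fresh ids so the individual random intercept stays well defined,
the mixed model is refit, and power is the fraction of converged refits
with the target term's P < alpha (default reps = 1000, alpha = 0.05).
Non-converged refits are excluded from the denominator and counted; a
point with > 20% failures carries a warning.

A caveat that matters for interpretation: resampling a single realized
cohort centers the bootstrap distribution on that cohort's *observed*
coefficient, not on the generating value, so "power" from a null cohort of
the same size as the target is upward-biased.  The calibration tests
therefore resample a target of 188 individuals from much larger null
source cohorts (n = 2000), which approximates fresh sampling from a null
population; with source and target the same size the procedure is a
post-hoc power estimate and inherits that bias.

## The synthetic-data generator

What it emulates, and the defaults that encode the study conditions:

- **Cohort geometry:** 188 individuals, arms (99 SSGT, 89 standard care),
  13 centers (uniform assignment), timepoints pre/post/followup with
  missing-completely-at-random dropout at rates 19/188 and 36/188
  (expected 169 and 152 observed).
- **Genotypes:** Gaussian-copula haplotypes — latent MVN with
  compound-symmetric correlation `within_block_r` (default 0.6) inside
  blocks of 8 variants, thresholded at the MAF quantile (MAF ~ U(0.05,
  0.5)); dosage = sum of two haplotypes, counting the minor allele.
  Blocks sit on one chromosome, 10 kb between variants within a block and
  2 Mb between blocks, so default clumping windows never span blocks.
- **Reference GWAS:** true log-ORs N(0, 0.1²) for a causal fifth of
  variants (0 otherwise); estimates add noise with SE = 1/sqrt(2 N p(1−p))
  at N = 50 000; P from the Wald z.
- **Outcomes:** baseline 95 SRS points; time effects −5 (post) and −6
  (follow-up); additional SSGT improvement −3 at both; variance components
  center 3, individual 15, residual 8 SRS points (SD scale); PRS effects
  all zero by default (the null); scores rounded to integers and truncated
  to [0, 195].  The motivating study does not report per-arm SRS means or
  SDs, so these magnitudes are chosen as clinically plausible for an ASD
  trial population rather than calibrated to it: baseline near the
  clinical SRS range, between-person variance dominating within-person
  noise, and a small center effect.
- **Covariates:** sex 75% male (typical of ASD trial cohorts), age group
  50/50, four standard-normal PCs, CNV carrier flags at 10%, and an ADHD
  comorbidity flag whose logit increases by `comorbidity_prs_shift`
  (default 0.5) per SD of the individual's true polygenic score.
- **Truth record:** causal variants, true log-ORs, true standardized PRS,
  generating betas and variance components — everything parameter-recovery
  tests need.

What it does **not** emulate: realistic recombination maps or LD decay,
phased haplotypes, the X chromosome, imputation uncertainty, informative
dropout, center-size imbalance, batch effects, or ancestry structure
beyond independent PC columns.  Passing calibration and recovery tests on
this generator therefore shows the estimators are correct under the
design's assumed covariance structure, not that real-data violations of
those assumptions (e.g. informative dropout or cryptic relatedness) are
handled.

## Problem sizes used by the test suite and acceptance script

Simulation-based checks run at sizes the package chooses for a
single-workstation workflow; all are ordinary parameters of the public
API, so larger runs are one argument away:

- Mixed-model type-I error: 400 null studies at n = 188 (test) / 200
  (acceptance script); the acceptance band is the 95% binomial interval
  around 0.05 at the reps actually run.
- Interaction recovery (+6.7 SRS/SD at follow-up): 50 studies at n = 1000
  with 40 centers; CI coverage is sample-size-free, so the check does not
  need the motivating cohort's scale.
- Bootstrap power null calibration: 8 source cohorts × 64 resamples
  (512 total) at target n = 188, 99% binomial band.
- Gene-set calibration: pooled KS uniformity over 6 null studies × 50
  genes at 400-500 permutations; competitive type-I over 500 random sets
  (10 independent null gene-statistic lists × 50 sets); planted-gene
  detection over 50 seeds.

## Numerical and degenerate-input choices

- HWE exact probabilities via log-gamma recurrence; ties in the two-sided
  sum tolerate 1e-12 relative rounding.
- Optimizer cascade for REML: L-BFGS, then Powell (robust at variance
  boundaries), then CG; genuine non-convergence raises with diagnostics,
  while a variance component estimated at ~0 is a warning (singular fit).
- A threshold selecting zero variants scores 0 with a warning and
  n_snps_used = 0; zero-SD score columns make standardization fail loudly.
- Monomorphic or missing-only genes are skipped and reported, never
  silently scored.
- Clumping tie-break on equal P: position, then id — full determinism.
- `inject_missingness` draws two independent entry-level masks (marker and
  individual rates) and blanks their union, so each marginal expectation
  is exact when the other rate is zero.

## Known limitations

- No external-panel LD reference: clumping r² always comes from the
  analyzed genotypes.
- No shrinkage/continuous-weight PRS methods, no threshold
  cross-validation.
- Wald-z inference only (no Satterthwaite/KR df, no likelihood-ratio
  P values); no random slopes; Gaussian outcomes only.
- The gene statistic is a deliberately transparent stand-in with the same
  competitive logic as MAGMA's workflow, not a reimplementation of
  MAGMA's multivariate gene model; absolute gene P values are not
  comparable across the two.
- Power estimates from a single cohort are post-hoc bootstrap power (see
  caveat above).
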