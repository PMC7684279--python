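# Methods

## The analysis

The pipeline estimates transethnic polygenic overlap between smoking
behaviour and schizophrenia liability with the classical p-value
thresholding (P_T) PRS design. Discovery GWAS summary statistics for
four smoking phenotypes — smoking initiation (ever/never), age at
smoking initiation (log scale, ever-smokers), smoking quantity
(cigarettes per day, ever-smokers) and smoking cessation
(current/former, ever-smokers) — supply per-variant weights: the log
odds ratio for binary traits, β for continuous ones. Target-cohort
variants pass QC and sliding-window LD pruning; each individual's score
at cutoff P_T is the raw sum of effect-allele dosage × weight over
variants with discovery p ≤ P_T, over the eight nested cutoffs
1e-4 … 1. Scores are raw sums (no division by SNP count); standardized
columns are additionally available for reporting.

Association is assessed per cutoff: linear regression with adjusted
R² = 1 − (1 − R²)(n − 1)/(n − p − 1) for continuous outcomes, logistic
regression with Nagelkerke's pseudo-R² for binary ones, Wald tests for
the score coefficient. The diagnosis analysis codes HC = 0, FR = 1,
SCZ = 2 and fits a linear trend — the equidistant ordinal coding is the
only reading under which a three-group analysis yields an adjusted R²;
a case/control logistic fit on the FR-free subset is the consistency
check. Reported scans keep the maximum variance explained across
cutoffs with deliberately uncorrected p-values; the cost of that choice
is quantified (below) rather than corrected away. Survival of the
never-smoking state is compared across groups with Kaplan–Meier curves
and the k-group log-rank test (lifelines); never-smokers are censored
at their interview age. Demographic tables are tested with Pearson χ²
(no continuity correction) and one-way ANOVA reconstructed from
(n, mean, SD) triples — between-group SS from n(mean − grand mean)²,
within-group SS from (n − 1)·SD².

## QC, harmonization and pruning choices

* QC order: duplicate ids, strand-ambiguous alleles, chromosome drop
  list (Y, MT), INFO ≥ 0.9, MAF ≥ 0.01, exact HWE p ≥ 1e-6. Each
  exclusion is logged once with the first failing rule, so stage counts
  reconcile exactly. "Low MAF" and the HWE rule are unquantified in
  the source protocol; 0.01 and 1e-6 are the field's customary values.
* The HWE test is the exact conditional test (enumeration of
  heterozygote counts given allele counts), avoiding χ² small-count
  failure; it runs only on hard genotype calls and is skipped for
  fractional dosages. The test is discrete and therefore conservative:
  across simulated founder panels its rejection rate sits at or below
  the nominal α, which the test suite asserts as a band rather than a
  point.
* Strand-ambiguous (A/T, C/G) SNPs are always dropped, never
  frequency-resolved. Harmonization tries direct and allele-flipped
  matches first and complement-strand matches only for non-ambiguous
  pairs; irreconcilable allele sets become excluded *values*, not
  exceptions. Flipping both discovery alleles and the weight sign is a
  no-op (property-tested), and matching is by variant id only.
* Pruning uses squared Pearson correlation of (mean-imputed) dosages —
  the standard statistic on imputed data, where phased haplotype r² is
  unavailable. Window 200 SNPs / r² ≤ 0.25; the step (50) is a common
  companion setting, configurable. Within a window the worst pair is
  removed first, dropping the member with the larger discovery p-value
  (ties: the later position); a final sweep guarantees the
  post-condition that no kept pair within a window exceeds the
  threshold. The panel is pruned once (using the smallest p across the
  four discovery traits as priority), not once per trait.

## The generative model

The simulator exists so that every stage — file parsing through
survival analysis — runs under a model with the structure the analysis
assumes:

* **Variants.** Biallelic SNPs with MAF ~ U(maf_range), laid out in
  fixed-size blocks (default 50) across autosomes 1–22. Within a block,
  haplotypes come from a Gaussian copula with AR(1) correlation
  `within_block_rho` (default 0.7) thresholded at each MAF; blocks are
  independent. This is the simplest structure that makes window pruning
  non-trivial; it does not attempt to match human LD maps or real
  allele-frequency spectra.
* **Effects.** An exact fraction `prop_causal` of variants is causal;
  causal pairs (β_smoking, β_liability) are bivariate normal with
  correlation `rg`, built explicitly as β₂ = rg·β₁ + √(1−rg²)·ε so the
  degenerate |rg| = 1 case is exact. Each vector is scaled so
  Σ 2p(1−p)β² equals the trait's heritability (h² = 0.5 by default);
  realized genetic values are additionally standardized against a
  reference founder draw, so the realized h² is exact even under LD.
* **Target cohort.** Liability = genetic value + N(0, 1−h²); disease
  iff liability exceeds Φ⁻¹(1 − prevalence) (prevalence 0.01 by
  default, so the threshold for prevalence 0.5 is exactly 0). Cases are
  ascertained by rejection sampling of sibling-pair families; the
  attached relative is a full sibling built from the same four parental
  haplotypes with per-LD-block Mendelian transmission (expected
  genotypic correlation ½, property-tested), with its environmental
  residual redrawn until unaffected — matching a family design that
  recruits unaffected relatives. Controls are founders screened to be
  unaffected. All four smoking phenotypes load on one latent smoking
  genetic value through logistic (ever/never, current/former),
  log-normal (initiation age) and negative-binomial (CPD) links, so a
  single `rg` governs the smoking–liability overlap. Default group
  sizes 130/56/146 and the demographic distributions mirror the
  published target cohort's margins.
* **Discovery statistics** are produced by actually regressing the
  simulated trait on every variant — closed-form OLS for continuous
  traits, vectorized Newton-scored logistic (weights are log odds
  ratios) for binary ones — so β's and p-values are internally
  consistent; statsmodels is the per-variant oracle in tests.
  Monomorphic variants get weight 0, p = 1, and a flag. A configured
  fraction of emitted records swaps the effect allele to REF (negating
  the weight) or writes both alleles on the opposite strand, so
  harmonization is exercised end to end.

Determinism: every randomness source derives from the config seed
through named SeedSequence streams; regenerating a fixture set is
byte-identical, and the pipeline writes deterministic result tables.

## Calibration studies and their design

Four simulation studies characterize the statistics (replicate sizes
chosen to finish in minutes on one CPU; the test suite runs them at the
same sizes):

* **Type-I.** 200 independent worlds with 2,000 variants, 400 discovery
  and 300 target samples, no genetic overlap. The simulated null sets
  rg = 0 *and* the target-trait heritability to zero: with rg = 0 but a
  heritable target trait, the realized correlation of two finite effect
  vectors is O(1/√n_causal) with random sign, which makes single
  replicates slightly anticonservative — a genuine property of sparse
  polygenic overlap worth knowing, not a test artifact we wished to
  measure here. The pre-fixed-cutoff rejection rate is checked against
  the binomial 95% band around 5%; the best-of-scan p-value, reported
  alongside, runs near 20% — the documented price of scanning eight
  correlated cutoffs without correction.
* **Power.** rg = 0.5, h² = 0.5, 20,000 variants, 2,000 discovery /
  1,000 target samples, 10 seeds; the score is tested against the
  *same* smoking trait in the target (the design's primary analysis).
  Because the age-at-initiation GWAS is defined on ever-smokers only,
  the calibration studies regress a latent continuous smoking trait
  measured on the full discovery cohort, keeping the nominal discovery
  n meaningful.
* **Ordering.** rg = 1, h² = 0.8, 2,000 variants, default group sizes
  and prevalence, 20 seeds; checks mean score of cases > relatives >
  controls.
* **Monotonicity.** Liability-side variance explained across discovery
  n ∈ {500, 2,000, 8,000} at rg = 0.8 (rg is free here; 0.8 separates
  the three levels beyond Monte-Carlo noise at target n = 1,000),
  5 seeds, strict monotonicity per seed.

## What passing tests do and do not show

The generator's LD is block-diagonal AR(1), its effect sizes are
Gaussian, its families are sibling pairs only, and its phenotype links
are the simplest standard choices; passing tests therefore demonstrate
correctness of the algorithms and calibration of the statistics under
this model, not robustness to real-data pathologies (population
stratification, imputation error correlated with MAF, X-chromosome
dosage, assortative mating, age-cohort smoking trends). Positional
allele matching, genotype imputation, clumping (as opposed to pruning),
shrinkage scores and Cox regression are out of scope. The published
cohort's age and education ANOVA statistics are not exactly
recoverable from their printed group summaries (the recomputed values
differ from the printed ones); the recomputed-table statistics are
therefore restricted to the smoking variables and sex/ever-never
contingency tables, which do reproduce.

## Numerical notes

* Dosage r² uses pairwise-complete observations and returns 0 for a
  zero-variance vector by convention; fewer than two complete pairs is
  an error.
* Logistic fits are statsmodels Newton ML; fits with |coef| > 10³ or
  non-finite parameters are reported as separation errors. Nagelkerke
  R² is clipped to [0, 1]; a constant lone predictor collapses to the
  null model (R² = 0) rather than erroring, while a constant predictor
  alongside covariates is a named rank-deficiency error.
* The exact HWE p-value sums probabilities of heterozygote counts no
  more probable than observed, with a 1 + 1e-12 tolerance on the
  equality comparison to absorb floating-point ties.
* Missing dosages: mean imputation per variant is the default scoring
  policy; an "omit" policy rescales each individual's score by the
  total/observed |weight| mass. The pruning matrix path mean-imputes
  before correlation.
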