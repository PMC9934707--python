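# Methods

`lifemr` implements a complete two-sample / multivariable Mendelian-randomisation
(MR) analysis separating the direct causal effects of childhood and adulthood BMI
on diabetes-related outcomes, exercised end to end on synthetic cohorts generated
under the assumed lifecourse causal diagram.  This note documents the generative
model, every estimator, the numerical choices, and what the synthetic studies do
and do not establish about real data.

## 1. Generative model (the synthetic two-sample study)

Two non-overlapping cohorts share a panel of independent biallelic variants with
effect-allele frequencies drawn uniformly from `maf_range` and dosages drawn
Binomial(2, p) under Hardy-Weinberg (no LD, no relatedness, no population
structure).  Variants are partitioned into child-specific, adult-specific and
shared sets; per-variant effects are Normal(0, `effect_sd`) in SD units per
allele, with shared variants receiving bivariate-normal child/adult effects at a
configurable correlation (default 0.5), so variants with larger adulthood than
childhood effects — and vice versa — arise naturally.

Phenotypes follow, per individual with dosage row G and hidden confounder
U ~ N(0,1):

    child   = G b_child + c U + eps
    adult   = gamma child + G b_adult + c U + eps'
    outcome = d_child child + d_adult adult + G b_pleio + c U + eps''

Residual variances are solved **analytically** from the drawn effects so every
trait has population variance exactly 1.  This makes "SD units" exact, keeps the
nominal path coefficients as the estimands (childhood total effect =
`d_child + gamma * d_adult`), and turns an over-specified configuration
(structural variance >= 1) into an immediate configuration error rather than a
silent rescaling.  Small sex/age/centre nuisance effects (< 1% of variance) are
added and removed again by GWAS residualisation.  A binary outcome replaces the
third equation with a Bernoulli draw through a logistic link on the same linear
predictor; the intercept is solved by root-finding (Brent, tolerance 1e-10) so
the population prevalence matches `binary_prevalence`.  Because the link is
logistic, marginal per-allele log-ORs are non-collapsible: GWAS log-ORs (and
hence MR estimates on that scale) are attenuated relative to the conditional
coefficients — visible as MVMR ORs of ~1.6-1.7 when exp(0.6) ~ 1.82 would be the
conditional value.  This mirrors what case-control GWAS measure.

The recall variable discretises true childhood BMI at the empirical quantiles of
the configured category proportions (default 0.32/0.51/0.17 — a configuration
parameter, not a claimed reproduction of any cohort's actual proportions), with
ties going to the lower category.  The hidden confounder is never written to
analysis-facing outputs.

Default study conditions: cohorts of 20,000; 75 child-specific + 75
adult-specific variants at effect SD 0.11 (mean instrument F ~ 90; chosen so the
genic variance ~ 0.33 +/- 0.06 stays safely below the unit-variance cap across
effect redraws); gamma = 0.5; d_child = 0; d_adult = 0.6; confounding 0.3.
Relative to real biobanks, per-variant effects are two orders of magnitude too
large: that is the price of genome-wide-significant instruments at desk scale,
and it means passing tests demonstrate estimator correctness and the logic of
the design, not biobank-scale power or winner's-curse behaviour.

A separate haplotype-copy generator (`simulate_ld_panel`) produces reference
panels with block LD (each haplotype allele copies its left neighbour with
probability `copy_prob`) solely to exercise clumping and proxy search; the
cohort simulator itself is deliberately LD-free.

## 2. Recall reconstruction

The 3-level recall category is converted back to a continuous childhood BMI by
sampling from an external reference distribution (normal by default; lognormal
offered because childhood BMI is right-skewed, parameterised by natural-scale
moment inversion) truncated to the stratum between the reference quantiles at
the cumulative category proportions.  Sampling is inverse-CDF on a uniform draw
per individual, independent across individuals.  Default anchor: mean 17.8
kg/m^2, SD 1.97 kg/m^2 (an age-11 BMI scale on which 1 SD ~ 1.97 kg/m^2).

Pooling the three truncated strata at the anchoring proportions reassembles the
parent distribution exactly, so the reconstruction is distributionally faithful.
Information-theoretically, however, it carries exactly the between-category
information: its Spearman correlation with the truth equals
`sum_k p_k (m_k - 1/2)^2 / (1/12)` (~ 0.83 at the default proportions), and a
GWAS on the reconstruction cannot out-perform a GWAS on the raw category codes
at equal n — within-stratum draws are independent noise.  The value of the
reconstruction is the comparable SD scale (the same continuous, rank-normalised
phenotype class as adulthood BMI), not extra statistical power at fixed n; the
tests assert exactly this.

Before association testing phenotypes are rank-inverse-normalised with the Blom
offset: `Phi^-1((rank - 3/8) / (n + 1/4))`, average ranks for ties.

## 3. Association, QC, clumping

GWAS is covariate-residualised least squares: the (rank-normalised) phenotype is
residualised on sex, age and one-hot centre, then regressed on each dosage
vector separately (closed-form simple regression, vectorised; two-sided t test
with df = n - 1 - #covariates).  A linear mixed model is unnecessary because the
simulated cohorts contain no relatedness or structure; this is a deliberate,
documented substitution.  Binary traits use per-variant logistic regression with
covariates in the model and Wald normal p-values; separated or non-converged
fits are flagged and dropped by QC.  Monomorphic variants are emitted with
beta = 0, SE = inf, flagged non-converged.

QC retains `maf_min < EAF < 1 - maf_min` (default 0.01) and INFO > 0.8 where an
INFO column exists, reporting counts removed per rule; it is idempotent.

Clumping is greedy: repeatedly take the smallest-p unassigned variant with
p <= 5e-8 as an index (ties broken by chromosome, position, id) and assign to it
every unassigned variant on the same chromosome strictly within 250 kb **or**
with r^2 > 0.001 against it.  Removal on distance-or-correlation is the stricter
joint reading of the two independence criteria (a distance-window-only rule
would be weaker); r^2 is the squared Pearson correlation of reference-panel
dosages, evaluated within a 1 Mb radius of the index and defined as 0 beyond it
for tractability.  The pairwise-independence invariant of the output is stated
— and tested — under that same radius-limited definition, since raw sample r^2
between truly independent variants in a finite panel exceeds 0.001 with
probability ~ P(chi2_1 > n * 0.001).

## 4. Scores and instrument validation

The GRS is the dosage-weighted sum over clumped instruments, dosages oriented to
each weight's effect allele (swapped pairs flip to 2 - d; unmatchable alleles
are an error naming the variant; missing variants error by default or skip with
a warning behind a flag).  Validation metrics: regression R^2 (squared Pearson
correlation), closed-form variance explained `sum 2 beta^2 MAF (1 - MAF)`,
ROC AUC (rank-based) and a per-SD odds ratio (logistic fit with Wald CI; the
per-SD parameterisation is a documented choice) for predicting the trait lying
more than 1 SD above its mean, and the multi-instrument F-statistic
`(R^2/(1-R^2)) ((n-k-1)/k)` with the per-variant mean (beta/se)^2 exposed as an
alternative.  In the pipeline the outcome cohort doubles as the independent
validation cohort — a third, external validation cohort has no synthetic
counterpart at desk scale.

## 5. The MR engine

**Harmonisation.**  Effects are aligned to one effect allele per variant:
direct allele matches kept, swapped pairs flip beta and EAF, strand complements
resolved, palindromic (A/T, C/G) variants oriented by allele-frequency agreement
when both frequencies are informative (|EAF - 0.5| > 0.08, a documented
threshold) and dropped as ambiguous otherwise.  Drop reasons are recorded.
Instruments missing from the outcome study may be replaced by the best
reference-panel proxy with r^2 > 0.8 within 250 kb, the proxy's effect oriented
through the sign of the panel dosage correlation.

**IVW.**  `sum(w bx by) / sum(w bx^2)` with w = 1/se_Y^2 — weighted regression
through the origin — with fixed-effect SE `sqrt(1/sum(w bx^2))`, matching plain
inverse-variance weighting; a multiplicative random-effects inflation
(max(1, sqrt(Q/(k-1)))) is available but off by default.  A single instrument
degenerates to the Wald ratio, labelled as such rather than erroring.

**MR-Egger.**  The same regression with a free intercept, after re-orienting
variants so all exposure betas are non-negative (required for the intercept to
estimate the average directional pleiotropic effect).  SEs use the
regression-estimated residual scale with t(k-2) tests; with weights 1/se_Y^2 the
transformed errors are iid standard normal under the model, so the intercept
test is exactly calibrated — the Monte-Carlo studies confirm 5% type-I error and
essentially full power against a constant 0.05-SD pleiotropy at 100 instruments.

**MVMR.**  Weighted multiple regression of by on both exposures' betas without
intercept, fixed-effect covariance `(X' W X)^-1`.  An exposure whose beta column
is identically zero is dropped and reported non-identified (the remaining
coefficient then equals univariable IVW exactly); non-zero collinear columns
(condition number > 1e8 on the weighted design) raise a
weak-conditional-instrument error.  The MVMR instrument set is the union of both
exposures' clumped instruments, re-clumped jointly on the smaller p so the union
itself satisfies the independence criteria.

**Steiger filtering.**  A variant is retained iff its exposure variance
explained (2 beta^2 MAF (1-MAF)) is at least its outcome value — equivalently
|bx| >= |by| on the standardised scale.  The same formula is applied to binary
outcomes on the log-OR scale as a documented approximation for case-control
traits.  Exclusions are recorded with both variance values.

**Meta-analysis.**  Fixed-effect inverse-variance pooling across outcome
studies; log-OR results are pooled on the log scale and exponentiated only for
reporting (p and log-scale SE unchanged by the transform).  Mixed scales or
mixed exposures are errors.

No multiple-testing correction is applied anywhere; Egger intercepts are flagged
at p < 0.01 (a configurable reporting threshold, not a correction).

## 6. Pipeline, determinism, reproducibility

Stages (`simulate`, `reconstruct`, `gwas`, `clump`, `grs`, `mr`, `report`) each
read persisted inputs and write persisted outputs (VCF with a DS dosage FORMAT
field; tab-delimited summary statistics with the fixed header SNP CHR BP EA OA
EAF BETA SE P N), so any stage can be re-run bit-for-bit.  All randomness flows
from the single config seed through named `SeedSequence` substreams (panel,
effects, per-cohort genotypes and noise, recall); the two cohorts share the
effect substream and differ in the noise substreams, which is what makes the
design two-sample.  Result files use fixed float formatting, so identical
config + seed reproduces byte-identical outputs; the JSON manifest records the
resolved config, thresholds, per-stage timings and SHA-256 checksums of every
output.

Monte-Carlo scale choices: the parameter-recovery study uses 200 replicates of
the default conditions (~1-2 min on one CPU); the Egger calibration uses 1,000
summary-statistic-level simulations — the calibration of a summary-statistic
estimator is fully determined at that level, so individual-level simulation
would add runtime without information.  The analysis drivers run a smaller
single-realisation study (cohorts of 5,000, 48 variants) for illustration.

## 7. Known limitations

* **Non-null MVMR coverage.**  Exposure-side GWAS sampling error induces the
  classical errors-in-variables attenuation of summary-statistic MR (relative
  bias ~ k/(n h^2), here ~1.5%), aggravated by the correlation between the two
  exposures' beta errors (both GWAS run in the one exposure cohort whose
  child/adult residuals correlate through gamma and the confounder).  Null
  effects are unaffected (bias is proportional to the true effect), so CI
  coverage of zero is nominal, but coverage of a non-null direct effect runs
  below 95% (~0.78 at the default conditions; ~0.87 under the estimated-scale
  SE convention some packages use).  Conditional-F diagnostics and
  bias-corrected MVMR estimators are out of scope; the fixed-effect convention
  is retained and the shortfall is reported, not masked.
* The recall reconstruction cannot add per-individual information beyond the
  category (Section 2); its benefit is scale comparability.
* Binary-outcome effects are non-collapsible marginal log-ORs (Section 1).
* The simulator omits LD (outside the dedicated panel generator), population
  structure, relatedness, assortative mating, recall misclassification, and
  selection effects; real-data behaviour of the pipeline under those features
  is untested by construction.
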