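# Methods

## The estimation problem

The package targets the causal effect θ of standardized years of education
on a standardized mental-health outcome (or its log-odds analogue for a
binary outcome), using a polygenic score (PGS) for education as an
instrument. Three mechanisms can violate the instrument's independence
assumption at the population level while being constant within a sibship:

1. **Dynastic effects / genetic nurture** — parental genotypes affect the
   child's environment. The child's PGS correlates with the mid-parent PGS
   (≈ 0.71 under random mating, higher under assortment), so any direct
   parental-score path to education or the outcome contaminates the
   instrument.
2. **Assortative mating** — spousal phenotype correlation induces
   correlations between parental genotypes and across traits.
3. **Population stratification** — subpopulations differing in allele
   frequency and phenotype means.

Family fixed effects (within-sibship demeaning, or the conditional
logistic likelihood for binary outcomes) remove everything shared by
siblings; the remaining identifying variation is Mendelian segregation at
conception, which is random conditional on the parents.

## Generative model

One simulated cohort is built in four stages (`sibmr.simcohort`):

1. **Parents.** 2·`n_families` parents; per-SNP allele frequencies uniform
   on `maf_range`, with subpopulation-2 frequencies shifted by
   ±`fst_like_shift` (alternating sign across SNPs, clamped to
   [0.05, 0.95]). Each parent's raw score is the weighted dosage sum
   (equal weights by default; half-normal weights optional), and their
   mating phenotype is an education propensity: `delta`·score +
   environmental noise.
2. **Mating.** Within subpopulation, fathers sorted on the mating
   phenotype are matched to mothers sorted on a noised copy of theirs; the
   noise SD solves corr(m, m+e) = `rho_am`, so the realized spousal
   correlation approaches the target (validated to ±0.05 at 5,000
   families) and is monotone in `rho_am`. Rank-matching was chosen over
   iterative swapping for stability and exact reproducibility.
3. **Transmission.** Each offspring allele is an independent
   Bernoulli(g/2) draw per parent; sibships have 2 offspring by default
   (a {2,3} mixture is available for HUNT-like cohorts).
4. **Phenotypes.** With S the standardized child score, S̄ the
   standardized mid-parent score, C a family-level standard-normal
   confounder and I₂ the subpopulation-2 indicator:

   - education*: `delta·S + eta·S̄ + conf_edu·C + pop_shift_edu·I₂ + ε`
   - outcome: `theta·std(edu) + lambda_·S̄ + conf_out·C + pop_shift_out·I₂ + ε'`
   - binary outcome: an independently re-noised copy of the outcome
     liability thresholded at its empirical (1 − `prev_binary`) quantile.

   Each noise variance is 1 minus the sum of squared loadings (floored at
   0.05), so components have near-unit variance, squared loadings read as
   variance shares, and with all channels off the PGS explains `delta²` of
   education variance in expectation. `edu_years` is reported on a
   cosmetic 13 ± 3-year scale; all analyses standardize it first.

Defaults encode the study conditions: 5,000 sibships of two, 50 SNPs,
`delta = √0.03` (PGS r² ≈ 3%, the lower of the two cohorts' reported
instrument strengths), θ = −0.2 (the anxiety-scale effect size),
`prev_binary = 0.085` (psychotropic-medication prevalence), age uniform on
40–70 and 55% female as purely cosmetic covariates with no structural
role. The *biased* scenario used in the separation studies sets genetic
nurture to half the direct effect (`eta = 0.1`, `delta = 0.2`), a direct
mid-parent outcome path `lambda_ = 0.1`, spousal correlation 0.3 and
family confounding 0.3 on both traits. The sign of `lambda_` decides the
direction of population-mode bias (with θ < 0, a positive `lambda_`
attenuates the population estimate toward zero; a negative one inflates
it); the separation property concerns its magnitude, not its sign.

Deliberately not modelled: linkage disequilibrium, X chromosome,
genotyping error, multi-generational pedigrees, non-random missingness.
Passing tests therefore demonstrate estimator correctness under clean
additive genetics, not robustness to real-data artefacts.

## Measurement layer

Scale scores are plain item sums (HADS-A/D 7×0–3, GAD-7 7×0–3, PHQ-9
9×0–3, EPQ-N 6 or 12 binary items); any missing item makes the score
missing — no prorating, and every model is complete-case within its own
variable set. The multiple-imputation pipeline used on the original survey
data is out of scope here, and this is the loudest consequence: analyses
drop incomplete rows. Caseness is strict `score > threshold` with default
10. Standardization is computed on the analysis sample after restriction
to sibships of ≥ 2, uses the population SD, and propagates missing values;
the two EPQ-N lengths are absorbed by within-cohort standardization.

## Estimators

- **Cluster covariance.** All population-mode models use the CR1 sandwich
  with small-sample factor G/(G−1)·(n−1)/(n−k), clusters = sibships;
  singleton clusters reduce it exactly to HC1. CIs are estimate ±
  1.959964·SE and p-values are normal-based throughout.
- **Family fixed effects.** Variables are demeaned within family;
  singleton families are dropped, family-constant columns removed, and the
  absorbed family means are charged to k in the CR1 factor.
- **2SLS.** Stage 1 regresses the exposure on instrument + covariates
  (within-demeaned first in FE mode); stage 2 uses the projected design.
  Residuals for the sandwich are taken at the observed exposure, the
  bread is (D̂'D)⁻¹, and the exposure coefficient is the causal estimate.
  The first-stage F is the cluster-robust Wald statistic of the
  instrument; partial r² is the squared partial correlation given
  covariates. F < 10 raises a warning, never an error.
- **Binary outcomes.** Logistic MLE (statsmodels IRLS) with the same CR1
  score sandwich; separation is detected by fitted probabilities within
  1e-8 of 0/1 or a singular information matrix. The within-family model is
  the conditional logistic likelihood over outcome-discordant sibships
  (concordant families dropped with a count; family-constant covariates
  conditioned out). One-sample MR uses two-stage predictor substitution;
  the resulting odds ratio is approximate and non-collapsible, which is
  documented rather than corrected. Covariate adjustment in population
  mode includes ancestry PCs (default 10) whenever the PGS is in the
  model; in FE mode PCs are family-constant by construction and are
  absorbed.
- **Two-sample MR.** Harmonization flips swapped alleles and drops
  palindromic variants with allele frequency inside
  (`palindrome_maf_limit`, 1 − limit), default limit 0.42. IVW is
  weighted-through-origin least squares with weights 1/se_out²; its SE is
  inflated by √(Q/df) when Q/df > 1 (multiplicative random effects).
  MR-Egger orients pairs to non-negative exposure betas, scales SEs by the
  estimated residual dispersion (plain weighted least squares — this is
  what keeps the intercept test at its nominal 5% size) and uses t tests
  on J−2 df. Weighted median interpolates the inverse-ratio-variance
  weighted CDF at 0.5; weighted mode maximizes a normal-kernel density
  with a MAD-based bandwidth (`bandwidth_factor` is the sensitivity knob);
  both get parametric-bootstrap SEs. Steiger compares
  Σ 2·eaf·(1−eaf)·β² between exposure and outcome via Fisher-z with the
  smaller of the two sample sizes.
- **Meta-analysis.** Fixed-effect inverse variance by default;
  DerSimonian–Laird random effects only when Q's p < 0.05 **and**
  I² > 50% (both required). τ² uses the closed-form DL moment estimator —
  chosen over likelihood-based τ² for exact reproducibility; for strongly
  heterogeneous inputs the two can diverge. Odds ratios pool on the log
  scale. SEs can be recovered from printed CIs via
  (UCI − LCI)/(2·1.959964), on the log scale for ORs.

## Numerical and design choices

- RNG streams are split per simulation stage from one seed sequence, so
  the generating weights are reproducible independently of later stages
  and adding a stage never perturbs another's draws.
- The binary outcome uses a liability threshold at the empirical quantile
  (not a logistic link) so sample prevalence matches the target exactly.
- Missing dosages are mean-imputed per variant (≈ 2·allele frequency);
  more than 50% unusable weight variants aborts score construction.
- PCA runs on centered, unit-variance dosage columns with monomorphic
  columns dropped.
- Rank deficiency raises with the offending columns named (QR diagonal);
  conditional-logit fits use Newton iterations to tolerance 1e-12 so
  closed-form cases are matched to ~1e-6.

## Replicate studies and problem sizes

`sibmr.experiments` fixes the study conditions used by the test suite and
the acceptance script: 200 replicates of the null scenario for parameter
recovery and CI coverage, 100 replicates of the biased scenario for the
bias separation and the within-family attenuation rate (the share of
replicates where the within-family PGS→education slope is below the
population slope), and 400/200 summary-statistic sets for the Egger size
and planted-intercept studies. Monte-Carlo SEs are std/√reps. These sizes
give MC SEs an order of magnitude below the effects being detected while
keeping a full run around a minute.

## Known limitations

- Complete-case handling understates the original analysis sample.
- The two-stage logistic MR estimand is an approximate OR.
- Empirical CI coverage of the clustered 2SLS sits near 93–96% at 5,000
  sibships; the CR1 normal-based interval is mildly anti-conservative.
- The simulator's equal-weight score and LD-free SNPs make the instrument
  cleaner than a real PGS; within-family F statistics are accordingly
  optimistic for a fixed r².
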