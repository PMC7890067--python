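# Methods

## The case-only design

`caseonly` implements a case-only genome-wide interaction scan for genetic
modifiers of breast-cancer risk in *BRCA1*/*BRCA2* pathogenic-variant
carriers.  Two consortium-style cohorts are compared: breast-cancer cases
who carry a mutation (a CIMBA-like carrier cohort) and population
breast-cancer cases unselected for mutation status (a BCAC-like cohort).
For each variant, logistic regression of carrier-cohort membership on
allelic dosage — adjusted for age at diagnosis, country and the first four
ancestry principal components, with a 1-df likelihood-ratio test — yields a
per-allele odds ratio.  Provided genotype and mutation status are
independent in the source population and the disease is rare on the modeled
(age-specific) scale, this OR estimates the carrier-by-SNP interaction: the
ratio of the variant's effect in carriers to its effect in the general
population.

Two safeguards address the independence assumption.  Variants in or within
500 kb of the mutation gene are excluded outright, and a **control-only**
analysis (unaffected carriers vs population controls, same adjustment)
screens the rest: any variant associated with carrier status among
unaffected women at p < 1e-8 is removed, since for such variants the
case-only OR confounds interaction with linkage to the mutation.

Because *BRCA1*-associated tumours are predominantly ER-negative, the
*BRCA1* analysis validates every overall-cases signal against a second
contrast restricted to ER-negative population cases (the carrier side is
never ER-filtered), and additionally allows discovery directly in the
ER-negative contrast.  Thresholds: 1e-8 genome-wide, 1e-7 for the
ER-validation step, 2.7e-4 (a Bonferroni correction over 179 tests, used
as printed) for established susceptibility SNPs with an 0.05 ER step.  All
comparisons are strict (`<`); region chaining ("within 500 kb") is
inclusive.

## Inflation accounting

Genomic-control lambda is the median observed 1-df chi-square over its null
median (0.4549).  Because lambda grows with sample size, it is rescaled to
an equivalent study of 1,000 + 1,000 subjects:

    lambda_1000 = (lambda - 1) * (1/n + 1/m) * 500 + 1,

with n and m the population- and carrier-cohort sizes.  The formula is the
identity at n = m = 1000 and fixes lambda = 1.

## Signal refinement and credible causal variants

Within each surviving region, forward stepwise regression (candidates
restricted to genome-wide-significant variants; conditional LRT; ties
broken by position then id; entry threshold 1e-8) defines conditionally
independent top SNPs.  A collinearity guard (pairwise dosage r² > 0.99)
skips near-duplicate candidates — an addition real dosage data require.
Credible-causal-variant sets follow the conditioning recursion: signal 1 is
the unconditional top SNP plus every variant with p ≤ 100 × p_top (the
two-orders-of-magnitude rule, read inclusively); signal k ≥ 2 rescans
conditional on the previous top SNPs and is formed only while some
conditional p stays below 1e-6.  Stepwise selection and the CCV recursion
are kept as separate operations; they can differ and both are exposed.

## Combined effect sizes

For an established susceptibility SNP showing an interaction, the OR
applicable to carriers is OR_computed = OR(case-only) × OR_BCAC at full
precision, reported alongside a half-up 2-dp rounding.  For SNPs
established in ER-negative disease (and ER-route discoveries) the
ER-negative case-only OR is the factor; this is the only choice that
reproduces the published worked examples.  The direction label compares
log OR_computed with log OR_BCAC: **TT1** when the combined OR is closer to
1 (whichever side of 1 it lands on — the published rows include a
sign-flipping TT1), **ISD** farther from 1 on the same side, **IOD** farther
on the opposite side.  No confidence interval is produced for OR_computed:
no variance-combination rule is defined for the product; both factors' SEs
are carried so users can apply independence-based SE addition on the log
scale, clearly an approximation.

## Target-gene scoring

CCV positions are intersected with annotation tracks: physical chromatin
links (ChIA-PET, Hi-C), computational enhancer–promoter predictions,
super-enhancers, promoter-class histone peaks, enriched regulatory
features, TAD boundaries (used only as a hard constraint: links whose
CCV-to-TSS span crosses a boundary are discarded), coding consequences
(missense/nonsense deleterious when REVEL > 0.5; splice when ada or rf
score > 0.6 — the tools' conventional cutoff, configurable) and eQTL
associations from a covariate-adjusted linear scan over genes within
±2 Mb of the lead variant (expression pre-filtered to nonzero median,
log2-transformed and quantile-normalised upstream; ESR1 expression and,
for tumours, copy number as covariates).

Scores: distal +1 per evidence class present (physical, computational,
eQTL), +1 for enriched-feature overlap, +1 for ≥ 2 independent physical
interactions; promoter 1 point for a hit, 2 for depth, 3 with eQTL
support; coding +1 per change type; non-expressed genes lose a point
(floor 0); breast-cancer driver genes gain a point per category in which
they already score (a bonus never creates evidence from none).  Caps are
8/4/3 and map to confidence levels: Level 1 when distal > 4, promoter ≥ 3
or coding > 1; Level 2 when 1 ≤ distal ≤ 4, promoter ∈ {1, 2} or
coding = 1; Level 3 when any category lies strictly between 0 and 1.  The
published scheme specifies ranges, caps and the named bonuses but not the
full per-evidence point table; the assignment here is a minimal faithful
reconstruction isolated in a single `ScoringTable` so users can
recalibrate.

## The synthetic-data generator

Real carrier-consortium genotype data are access-controlled, so the
package ships a generator that emulates the structure the analysis
assumes — it is first-class, tested code, not a fixture.

* **LD**: haplotypes come from a Gaussian copula.  Within a block, latent
  normals form an AR chain whose lag correlation is *calibrated* (via the
  bivariate-normal orthant probability and root finding) so the realized
  allelic correlation between adjacent SNPs equals `ld_rho`; naive
  thresholding at latent rho = 0.9 would give only ~0.71.  Blocks are
  independent.  Adjacent-pair correlation is the only LD property the
  pipeline's tests rely on, which is why a coalescent simulator was not
  pulled in.
* **Structure**: two ancestral subpopulations whose allele frequencies
  differ by ±`fst_like_shift` (clamped to [0.01, 0.99] with a warning);
  the subpopulation mixture can differ by cohort, which is what makes
  confounding — and its removal by PC adjustment — observable.
* **Disease**: prospective logistic liability with cohort baseline,
  population and carrier-interaction effects, country effects
  (N(0, `country_effect_sd`)) and a linear ancestry term, sampled by
  rejection until the requested case/control counts are met (bounded
  rounds; failure names the stratum).  The baseline log-odds default is
  −4.0 (case probability ≈ 2%, an age-specific incidence scale): the
  case-only contrast equals the interaction OR only under the rare-disease
  approximation, with attenuation roughly proportional to the baseline
  case probability.  At a common-disease baseline (−2.4) the log-OR bias
  is ≈ −0.04 with visibly degraded CI coverage; at −4.0 it is below 0.01.
* **Carrier linkage** is modeled as an allele-frequency offset in carriers
  (alleles toggled with probability delta/(1−f)), exactly the violation
  the control-only screen exists to catch — not haplotype sharing.
* **Phenotypes**: carrier cases are drawn ~16 years younger than
  population cases (means 42.5 vs 58.4, sd 8); ER-negative probability
  0.7 in carriers vs 0.2 in the population cohort, masked to `unknown`
  with probability 0.28; a prevalent-case flag (0.681 carriers / 0.423
  population) is carried as a label only — no survival selection is
  modeled.
* **Imputation metadata**: a configurable fraction of variants is flagged
  genotyped (r² = 1 in both cohorts by convention); the rest draw
  per-cohort r² uniformly from [0.3, 1].  The genotyped fraction defaults
  to 0.3 — higher than a genome-wide array fraction — because at the
  scaled panel sizes used here the PCA stage needs enough genotyped,
  LD-pruned variants to be well-posed.
* **Determinism**: one master seed; per-stage child streams derived with
  fixed spawn keys, so identical configs give byte-identical outputs.

What the generator does *not* emulate — realistic recombination maps,
family-based ascertainment, survival selection of prevalent cases,
X-chromosome dosage — bounds what passing tests show: they validate the
statistical machinery under the stated model, not robustness to every
feature of real consortium data.

## Numerical choices

Logistic fits use Newton/IRLS with step-halving, relative deviance
tolerance 1e-8 and at most 50 iterations; non-convergence flags the result
and warns.  Scans share the covariate-only null fit across variants with
complete dosages and warm-start each full fit from it.  Samples missing a
dosage are dropped from that variant's regression only.  An independent
GLM implementation (statsmodels) serves as the oracle in tests; it is
never the engine.  PCs come from the SVD of the standardized genotyped,
LD-pruned (pairwise r² < 0.1, 500-variant windows, step 250 — standard
practice; the source pipeline's pruning parameters are not public) dosage
matrix, sign-fixed so the largest-magnitude loading is positive.  Country
strata with fewer than 10 carrier-cohort subjects are dropped before
analysis.  Age enters linearly.  Mixed imputation-quality bins use the
stricter (lower-bin) delta-r² threshold, keeping the rule monotone in
imputation quality.  The country-stratified HWE test sums per-country 1-df
chi-squares (df = informative countries); monomorphic strata are
uninformative, and a fully monomorphic variant returns p = 1 with a flag.

## Problem sizes used in the shipped checks

Calibration and recovery experiments run at the scales their properties
are stated for: 2,000 independent null variants at n ≈ 4 × 2,000 for
type-I-error calibration; 100 replicates at n = 4 × 5,000 for recovery of
a planted interaction OR of 1.3 and for the control-only screen's
detection of a +0.10 carrier frequency offset; a 5,000-variant genome at
n = 4 × 2,000 with two planted modifiers (case-only OR 1.6, chosen by a
power calculation for that scale) and one carrier-linked confounder for
the end-to-end run.  Genome-wide discovery at the published scale
(~9 million variants, ~67,000 cases) is out of reach of these synthetic
checks by design; the worked-example tables and count identities cover
that surface instead.

## Known limitations

The per-evidence scoring table is a reconstruction; absolute scores are
not comparable with the original pipeline's, only the ranges, caps, level
cutoffs and named bonuses are.  The case-only OR is attenuated for common
disease (see above).  Carrier-cohort hazard ratios from retrospective
cohort analyses are pass-through metadata, never recomputed.  Genotype
re-imputation is represented as a pipeline stage that swaps in a second
dosage matrix for candidate regions; the imputation itself is external.
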