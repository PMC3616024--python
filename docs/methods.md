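# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions a maintainer would want written
down.

## Data model

Genotypes are stored as counts of the panel's designated **minor** allele
(0/1/2 autosomal, 0/1 on the X chromosome), never as risk-allele counts:
risk orientation is an analysis decision and is applied downstream, so the
stored data stay independent of any analysis choice.  The cohort is
all-male by design (prostate cancer), so X-linked genotypes are hemizygous
and contribute a single allele to frequencies and scores; a stored X
dosage of 2 is rejected at read time.  Missing genotypes are the literal
`NA` on disk; every analysis states its own exclusion rule rather than
imputing at the storage layer.

Age is the study's mixed covariate — age at diagnosis for cases, age at
participation for controls — reproduced as-is because the case-control
design offers no common alternative.  The aggressiveness composite
(Gleason ≥ 7, or at least two of: tumor invasiveness, positive resection
margins, capsule invasion, seminal vesicle involvement, lymph node
involvement) is a pure function of the pathology fields; cases with no
pathology information are *unclassifiable* and are excluded from subtype
analyses only, never from the single-SNP or score analyses.

## Per-SNP association

Each SNP is fitted by unconditional logistic regression of status on
genotype and continuous age (maximum likelihood via statsmodels), with
Wald 95% intervals and two-sided p-values.  Codings: allelic additive
(per-allele OR), codominant (heterozygote and minor-homozygote indicators
against the major-homozygote reference), dominant, recessive.  Fits are
complete-case per SNP, so the effective n varies with that SNP's
missingness.  Age enters linearly by default; spline or categorical age
would be a caller-supplied covariate transformation, deliberately out of
the core path.  Separation or non-convergence (plausible for rare
homozygotes at MAF ≈ 0.03) is reported as `converged=False` with a note,
never silently penalised.  Hardy–Weinberg QC is a 1-df χ² comparing
control genotype counts with the HWE expectation at the sample allele
frequency; monomorphic SNPs are flagged rather than tested.

## Permutation multiplicity procedure

Case/control labels and ages are permuted **jointly** — the (status, age)
pair moves as a unit across subjects while genotype rows stay fixed.
This preserves the age–status relationship, so age-adjusted p-values
computed inside each permutation mean the same thing as in the observed
data; permuting labels alone would break that relationship and change the
null being sampled.  For each of B permutations the additive age-adjusted
model is refitted for all m SNPs; the adjusted p-value for order
statistic k is (1 + #{b : p(k)_b ≤ p(k)_obs}) / (B + 1).  The +1
convention keeps adjusted p-values in (0, 1] and makes the smallest
attainable value 1/(B+1).  B defaults to 10,000; any B ≥ 99 is accepted.

Interpretation matters here: the k-th adjusted value tests the k-th order
statistic individually.  The family-wise (weak-sense) error of the
procedure is carried by the **minimum-p order statistic** — under a
global null, P(adjusted p(1) ≤ 0.05) ≈ 0.05 by construction, which the
test suite verifies by Monte Carlo.  The minimum over all m adjusted
values is *not* an error-controlling quantity (without a step-down
monotonicity enforcement the later order statistics reject their
individual nulls too easily), and the package does not report it as one.
Permutation fits that fail to converge contribute p = 1 (conservative)
and are tallied in the result.

Internally the permutation engine solves all SNP × permutation logistic
fits as stacked 3-parameter Newton problems (`snpburden._glm`), chunked
to bound memory; per-SNP missingness is implemented as zero case weights
so all problems share one rectangular array.  The solver is verified
against statsmodels and a direct scipy likelihood maximisation to 1e-6 in
the test suite.

## Subtype, stratified and interaction analyses

Subtype contrasts use a single multinomial logit of
{control, non-aggressive, aggressive} on genotype and age, control as the
reference outcome, so both case strata share one control group and one
information matrix.  Heterogeneity between strata is the Wald statistic
(β_agg − β_non)² / (Var_agg + Var_non − 2 Cov) on 1 df, with the
covariance taken from the joint fit; two separate binary fits would lose
that covariance and mis-state the variance of the difference.  Stratified
analyses are independent per-stratum fits with thin strata (< 10 complete
rows or a single outcome class) reported absent.  Interaction tests are
likelihood-ratio tests of {g, age, m, g×m} against {g, age, m}; the
additive (1-df) coding is the default, the genotype (2-df) coding an
option.  The syndrome-pattern classifier compares three contrasts at a
chosen α — cases with the family history, cases without it, and controls
with it, each against controls without it — and labels the SNP
syndrome-like, disease-specific (similar ORs defined as a ratio within
20%), other-cancer-linked (this check takes precedence, since a signal in
unaffected carriers of the family history directly implicates the other
cancer), or indeterminate.

## Cumulative risk-allele score

SNPs enter the score if their additive p ≤ 0.05, plus forced borderline
SNPs (defaults: the two panel SNPs at p = 0.055 and 0.057; with the
packaged panel's published values this yields 17 SNPs, 16 autosomal and
one X-linked).  Risk orientation: OR ≥ 1 → minor allele is the risk
allele, OR < 1 → major allele (ties resolved to minor).  The score is the
unweighted risk-allele count; β-weighted scores are deliberately out of
scope.  Subjects missing any selected genotype are excluded
(complete-case, matching how per-quartile denominators behave in the
source design); an expected-dosage fill-in (2f or f from control
frequencies) exists behind a flag for sensitivity analyses but is off by
default.

Quartile categories are cut on the **control** score distribution with
integer cutpoints chosen to minimise the maximum absolute deviation of
the four control bin proportions from 0.25, ties broken by preferring
equal outer bins, then equal inner bins, then the lexicographically
smallest cuts.  "Quartiles" of a discrete integer score admit several
conventions, so this rule is the package's own operationalisation;
applied to the
exact theoretical control distribution of the packaged panel it yields
cuts (13, 15, 17), i.e. bins 8–13 / 14–15 / 16–17 / 18–24.  Quartile ORs
come from a logistic fit on quartile indicators plus age (Q1 reference);
the trend p uses the quartile index 0–3 as one ordinal term — the index,
not the raw score, so the trend statement refers to the published
categories.

The exact score distribution under HWE is the sequential convolution of
Binomial(2, f_risk) pmfs (autosomal) and a Bernoulli(f_risk) term (X).
Its mean Σ 2f_risk + f_risk(X) and variance Σ 2f(1−f) + f(1−f)(X) are
computed analytically and must match the pmf moments to 1e-9; the pmf is
renormalised after convolution to absorb float drift (≤ 1e-12).

## Risk prediction

Three nested logistic models on the identical complete-case subject set:
score only; age + family history of prostate cancer; score + age + family
history.  Discrimination is the apparent (in-sample) AUC, computed as the
Mann–Whitney pair-count statistic via midranks (ties count ½), which
equals the trapezoidal area under the empirical ROC exactly.  No DeLong
or bootstrap inference and no cross-validation: the target analysis
reports apparent AUCs only, and optimism-corrected AUCs would not be
comparable to it.  This is a known limitation, not an oversight.  For the
aggressive-disease variant the contrast is aggressive cases against all
controls.

## Power

Per replicate, control genotypes are Binomial(2, f) and case genotypes
follow the HWE probabilities tilted by OR^g and renormalised — the exact
case genotype distribution a per-allele odds ratio implies under the
rare-disease log-additive model.  An age covariate carrying no signal is
included so the fitted model matches the analysis model.  Power is the
rejection fraction of the two-sided Wald test at α, with a Wilson 95%
interval.  The headline design check uses the successfully genotyped
counts (936 cases / 1,223 controls) rather than enrolment totals: the
genotyped counts are what determine the realised power of an analysis of
the genotyped subjects.  All counts are configurable.  A
closed-form normal-approximation power for the allele-count test is
provided purely as an independent cross-check.

## Synthetic cohort generator

The generator emulates: HWE genotypes at the panel control frequencies
(hemizygous X), disease assigned by logit P = β₀ + Σ βᵢrᵢ with
per-risk-allele log-ORs defaulting to ln(published OR) and the intercept
calibrated by root-finding to the target prevalence (default 10%),
retrospective sampling of the requested case/control counts from a large
simulated population, truncated-normal ages (means 65/68 y, SD 8 y,
floor 40 y — the emulated design fixes the means but not the
dispersions, so the SD is a stated, configurable choice),
status-conditional family history of
prostate cancer (28% cases / 14% controls), other-cancer family history
at status-independent rates (lung 10%, colorectal 8%, breast 15%,
ovarian 3%, bladder 3% — chosen as typical first-degree questionnaire
prevalences), a Gleason mixture of (0.63, 0.25, 0.12) over bands
2–6 / 7 / 8–10 (the bands must sum to 1; "about two thirds" is
implemented as 0.63), pathology features drawn per Gleason band so that
roughly half of classifiable cases meet the aggressiveness composite,
~6% of cases with no pathology report, and per-SNP missingness drawn as
0.01 + 0.10·Beta(1, 9) (support (0.01, 0.11), mean exactly 0.02).

It does **not** emulate: linkage disequilibrium between SNPs, population
substructure or relatedness, genotyping batch effects, age-genotype
dependence (available as an explicit knob for stress-testing the
permutation procedure, off by default), or family-history flags derived
from relatives' actual genotypes — FH is a status-conditional Bernoulli
because the pipeline only consumes it as a covariate/stratifier.  Tests
passing on these synthetic cohorts therefore validate the estimators and
their error control under the design assumptions, not robustness to LD,
stratification or differential genotyping error in real data.

One master seed spawns named substreams (genotypes, disease, sampling,
ages, family history, pathology, missingness), so outputs are
byte-identical across runs and stages can be re-run independently.

## Numerical and test-scale choices

- Wald CIs/p-values throughout, matching replication-study convention;
  likelihood-ratio p-values appear only in the interaction tests, where
  the LRT is the point.
- The batched Newton solver starts at β = 0, step-halves on likelihood
  decrease, converges on max |score| < 1e-8, and flags quasi-separation
  at |linear predictor| > 30 instead of raising.
- Simulation sizes in the test suite (200 recovery replicates at the full
  study size; 500 null datasets of 120 subjects with B = 199 for the
  family-wise error check; 100,000 subjects for distribution-convergence
  checks; 1,500 power replicates) are the package's chosen trade-off
  between Monte-Carlo precision and a single-CPU test run; each assertion
  states a tolerance consistent with its Monte-Carlo standard error.
- The recovery check accepts pooled CI coverage in [0.92, 0.97] rather
  than a symmetric band around 0.95: the generative coefficients are
  conditional log-ORs while the refitted models are marginal single-SNP
  fits, and odds-ratio non-collapsibility attenuates the marginal
  estimates by roughly 4% of β (~0.2 SE at the study size).

## Known limitations

- No LD handling, imputation, genomic control or population-stratification
  correction; the intended setting is a candidate panel of independent
  loci in a relatively homogeneous population.
- Score SNP selection and evaluation are in-sample by design; quartile
  ORs and AUCs are optimistic relative to external validation.
- The X-chromosome convention (hemizygous 0/1, one allele in frequencies
  and scores) is a modelling decision for all-male cohorts; assay
  software that reports male X calls as pseudo-homozygous diploid
  genotypes must be recoded on import.
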