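# Methods

## Phenotype ascertainment

Phenotypes are defined as sets of ICD-10 code atoms: prefixes (`I10`,
`G30.0`) and inclusive 3-character category ranges (`I05`–`I09`).  A
participant is flagged iff at least one condition record matches; the
definition is lifetime, because the analysis is cross-sectional and record
dates carry no information the model would use.  Matching strips dots and
uppercases first, so the `I10.0` and `I100` coding dialects agree, and a
prefix only matches at the category boundary (`I10` matches `I10.x`, never
`I11`).  Records referencing unknown participants and unparseable codes are
excluded and counted in a diagnostics object rather than failing the run.
Phenotypes that are not ICD-derived in a given cohort (e.g.
questionnaire-derived depression in a UK-Biobank-style path) enter as
pass-through boolean columns next to the code-set flags.

## Covariate harmonization

Cleaning is declarative (`HarmonizationPolicy`) and idempotent:

* **Continuous**: missing values imputed with the per-column sample median
  computed on the full analytic table in a single pass (no folds or
  strata); even counts use the mean of the two central order statistics —
  the conventional sample median.  A fully missing column is an error.
* **Categorical**: declined/missing responses collapse to a single
  "Prefer not to answer" level; ethnicity raw levels roll up to broad
  groups via an explicit total map, multi-ethnicity entries become
  "Mixed"; any undeclared raw level raises rather than passing through.
* **Derived scalars**: one BMI per participant (first visit, or the
  arithmetic mean of all reported values) and one age (at assessment, or
  reference_year − birth_year).  Participants with no BMI observations stay
  missing and are handled by median imputation.

Categorical covariates enter models as indicator contrasts against an
explicitly configured reference level, recorded in run metadata.

## Association models

One logistic regression per subtype (11 models), each adjusting for the
full covariate set; subtypes are never modelled jointly and cardiovascular
multimorbidity is deliberately not adjusted for, matching the per-subtype
forest-plot design.  Fitting is Newton maximum likelihood (statsmodels
`Logit`; gradient tolerance 1e-8, at most 100 iterations); the coefficient
covariance is the inverse observed information.  Intervals are 95% Wald on
the log-odds scale — the default of standard logistic fits and consistent
with symmetric published CIs on the log scale; significance means the CI
excludes OR = 1.  No multiple-testing correction is applied across
subtypes, and that choice is stamped into the run metadata.

Exclusion rules: a subtype with fewer than `min_exposed_outcome` (default
5; the real analyses dropped a subtype at 2 cases) exposed-with-outcome
participants, or a non-converged fit (e.g. separation), is emitted as an
excluded result with a reason.

The unadjusted cross-product OR (a·d)/(b·c) with the Woolf interval
exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)) is kept as a closed-form oracle: a
single-exposure logistic model with an intercept reproduces it to 1e-6,
which the suite asserts on every simulated table.  Zero cells raise —
continuity corrections are out of scope.

Display percentages round half away from zero at one decimal; machine
outputs keep full precision.

## Proximity colocalization

Both SNP sets must already be GRCh38; no liftover or build detection is
attempted.  The significance filter is strict (p < 5×10⁻⁸; p equal to the
threshold is removed).  "Within 50 kb" is read as |Δpos| ≤ 50,000 inclusive
— the boundary convention is recorded in run metadata since either reading
is defensible.  Chromosome labels are normalized by stripping `chr` and
uppercasing; X/Y/MT are labels, never compared numerically.  The join is a
per-chromosome sort plus binary-search sweep (near-linear), with duplicate
input records (rsid+trait+side) dropped first so results are invariant to
input order and duplication; an O(n²) all-pairs scan is the test oracle.

Pairing counts per catalog anchor use distinct (biobank rsid, biobank
trait) records by default, so one biobank SNP significant for two traits
counts twice; `count_key="rsid"` collapses trait multiplicity.  This
convention is the package's own choice — published pairing counts do not
spell theirs out — and is configurable for that reason.  Separately,
"unique SNP pairs" counts distinct (catalog rsid, biobank rsid)
combinations.  Report rows need more than 2 pairings by default
(`min_pairings = 3`); unmapped rsids annotate as "NA" and are retained.

## Synthetic biobank generator

The generator emulates the shapes the analysis consumes, not the biology:

* **Outcome model**: Bernoulli draw from the same logistic form the
  analysis fits (correct specification by design), with intercept
  logit(baseline prevalence).  Parameter recovery and CI coverage are
  therefore valid acceptance surfaces; there is no misspecification toggle.
* **Default study conditions** (`default_cohort_config`): the 11 CVD
  subtypes at their published UK Biobank marginal prevalences (hypertension
  0.323 … cerebral infarction 0.021); true log-odds effects set to the
  published adjusted ORs where one is printed (hypotension 2.74, blockage
  1.62, hypertension 1.57, cerebral infarction 1.49, acute MI 1.01) and to
  plausible mid-range values (1.2–1.5) for the rest; baseline AD prevalence
  0.004, which yields an overall prevalence near the published ~0.8% once
  exposure and age effects act; age ~ N(56.5, 8.1²) with a strong
  (1 log-odds/SD) effect, BMI ~ N(27.4, 4.8²) null, sex and smoking
  categorical with small effects and realistic (~0.6%) missingness.
* **Condition records**: each assigned exposure emits its concrete ICD-10
  code, with a random half given a sub-code suffix (`I95.3`) to exercise
  prefix matching; outcome-positive participants emit `G30`.  No dates.
* **Missingness** is applied after the outcome draw, so the outcome never
  depends on masked values (missing completely at random).
* **Correlated exposures**: an optional Gaussian-copula correlation among
  exposure latents (default 0, i.e. independence) — real CVD subtypes
  co-occur, but the analysis deliberately does not adjust for
  multimorbidity, so independence is the cleanest default test bed.
* **Seeding**: one root seed, spawned into per-sub-generator streams
  (exposures, covariates, outcome, record sub-codes), so adding a covariate
  does not perturb exposure draws; identical seeds give byte-identical
  CSV output.

The paired GWAS generator plants shared loci (one SNP per side, same
chromosome, offset uniform in [0, planted_offset_max]) and uniform
background SNPs, optionally kept ≥ 1 Mb clear of planted loci so recovery
tests are unambiguous.  Significant p-values are log-uniform in
[10⁻³⁰, α); a separate non-significant set (p uniform in [α, 1)) exercises
the significance filter.  Configurations whose planted loci would block
more than half the available base-pair space are rejected up front.

What the generator does **not** emulate: LD structure, genotypes,
longitudinal EHR timelines, diagnosis-code noise/miscoding, correlated
covariates, and informative missingness.  Passing tests therefore
demonstrate the pipeline's statistical correctness under a correctly
specified, independent-exposure world — not robustness to the
misclassification and confounding structure of real EHR data.

## Problem sizes and numerical choices

Coverage checks use 200 replicates of n = 100,000 single-exposure cohorts
with true OR 2.5 (baseline outcome prevalence 0.02, exposure prevalence
0.25 — roughly a thousand exposed cases per replicate, enough for the Wald
interval to be in its asymptotic regime); empirical coverage is required to
land in 93–97%.  Brute-force join parity uses 500 SNPs per side over six
chromosomes.  The default pipeline simulates 50,000 participants — large
enough that every subtype has exposed cases, small enough to run in
seconds.  Ties in the window join are broken by the deterministic sort
(chromosome, positions, rsids, traits); report rows tie-break by rsid
within equal pairing counts (stable mergesort).

## Known limitations

* The published covariate-adjusted ORs cannot be reproduced without the
  restricted record-level cohorts; the bundled published counts support
  exact *unadjusted* arithmetic only, and the package keeps that
  distinction explicit.
* Wald intervals can misbehave at very low case counts; the exclusion rule
  is a guard, not a fix (no Firth or exact logistic fallback).
* Proximity pairing is not evidence of shared causal variants; without LD
  or formal colocalization posteriors it can only flag candidate regions.
* The ICD-10 matcher handles prefix/range semantics, not the full ICD-10-CM
  hierarchy (no seventh-character or placeholder logic).
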