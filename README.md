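# heartbrain

Cross-sectional association analysis between cardiovascular disease (CVD)
subtypes and Alzheimer's disease (AD), plus a proximity-based colocalization
of GWAS summary statistics — the heart–brain axis analysed at the biobank
scale, packaged as a tested, reusable pipeline.

## Who this is for

Epidemiologists and biostatisticians who want to reproduce or extend
per-CVD-subtype odds-ratio analyses on EHR-style data (UK Biobank / All of
Us shaped cohorts) without access to the restricted record-level data.  A
synthetic biobank generator with known ground truth stands in for the real
cohorts, so every step — ICD-10 phenotype ascertainment, covariate
harmonization, logistic modelling, 50 kb window colocalization — is
exercised end to end and validated against oracles.

## The model

For each CVD subtype *k* (hypertension I10, hypotension I95, angina
pectoris I20, acute myocardial infarction I21, pulmonary embolism I26,
atrial fibrillation I48, heart failure I50, AV/LBB blockage I44, chronic
rheumatic heart disease I05–I09, chronic ischemic heart disease I25,
cerebral infarction I63), a separate cross-sectional logistic regression

> logit P(AD = 1) = β₀ + β_k · CVD_k + γᵀ·covariates

is fitted; the reported association is OR_k = exp(β_k) with the 95% Wald
interval exp(β_k ± 1.96·SE) and a Wald p-value.  Phenotypes are lifetime
ICD-10 flags (prefix match at the 3-character category boundary, dots
stripped, so `I10.0` ≡ `I100`).  Covariates are harmonized first: median
imputation for continuous values, declined/missing categorical levels
collapsed to "Prefer not to answer", ethnicity rolled up to broad groups
with multi-ethnicity → "Mixed".  Subtypes with too few exposed AD cases
(default < 5) are reported as excluded, never silently dropped.  No
multiple-testing correction is applied across subtypes and multimorbidity
is not adjusted for — one model per subtype, mirroring forest-plot
reporting.

The genetic arm filters two GWAS summary-statistic sets (a catalog side and
a biobank side, both GRCh38) to genome-wide significance (p < 5×10⁻⁸,
strict) and pairs SNPs on the same chromosome within 50 kb (inclusive),
counting pairings per catalog anchor SNP and annotating them with gene
symbols from a local map.  This is proximity colocalization — no LD, no
posterior probabilities.

## Worked example

```bash
python analysis/01_simulate_biobank.py --n 50000 --seed 0
python analysis/02_ascertain_and_associate.py
```

prints (elided):

```
subtype                           OR [95% CI]                true OR
hypertension                      1.55 [1.29, 1.85]             1.57
hypotension                       2.48 [1.84, 3.34]             2.74
acute_myocardial_infarction       1.27 [0.83, 1.96]             1.01
...
11/11 fitted CIs cover the generating OR
```

Each row is one subtype's covariate-adjusted odds ratio for AD in the
synthetic cohort, next to the log-odds effect the generator planted; at
n = 50,000 every 95% interval covers its generating value.  The remaining
drivers run the colocalization arm and the published-count checks:

```bash
python analysis/03_gwas_colocalization.py     # planted shared loci recovered: 30/30
python analysis/04_published_count_checks.py  # hypotension unadjusted OR 5.12 [4.72, 5.55]
```

The published cohort cross-tabulations (bundled as TSVs under
`src/heartbrain/data/`) are exact inputs: every display percentage
reproduces from the raw counts at one-decimal rounding, and the
cross-product odds ratios derived from them are *unadjusted* estimates —
deliberately different from the covariate-adjusted model ORs (UK Biobank
hypotension: 5.12 unadjusted versus 2.74 adjusted in the published model).

The same pipeline is scriptable via the `heartbrain` CLI
(`simulate`, `ascertain`, `associate`, `colocalize`, `report`, `all`) or a
YAML run config (`heartbrain all --config run.yaml`).

## Layout

- `src/heartbrain/` — the library: `synthetic` (cohort + GWAS generators),
  `phenotypes` (ICD-10 ascertainment), `harmonize` (covariate cleaning),
  `association` (logistic ORs, 2×2 oracle, prevalence summaries), `coloc`
  (window join and pairing reports), `reporting`/`pipeline`/`cli`
  (orchestration), `reference` (published count tables).
- `analysis/` — numbered narrative drivers over the library.
- `docs/methods.md` — model, assumptions, parameter choices, limitations.
- `tests/` — unit, property and end-to-end suites.
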