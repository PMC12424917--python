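"""Published reference counts and worked-example arithmetic.

The record-level UK Biobank and All of Us data behind the analysis are
access-restricted, but the published cross-tabulations are not: this module
bundles the per-CVD-subtype counts split by Alzheimer's-disease status and
the demographic count tables for both cohorts, and recomputes the derived
quantities (unadjusted cross-product odds ratios, prevalence percentages,
column-sum conservation) from those counts.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

from heartbrain.association import ContingencyTable2x2, crosstab_or, round_half_away
from heartbrain.phenotypes import CodeSet, parse_code_spec

COHORTS = ("ukb", "aou")


def _data_path(name: str):
    return resources.files("heartbrain").joinpath("data", name)


def load_cvd_counts(cohort: str) -> pd.DataFrame:
    """Per-subtype No/Yes counts, overall and split by AD status, with the
    published display percentages alongside."""
    if cohort not in COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}")
    with resources.as_file(_data_path(f"{cohort}_cvd_ad_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_demographics_counts(cohort: str) -> pd.DataFrame:
    """Categorical demographic counts, overall and split by AD status."""
    if cohort not in COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}")
    with resources.as_file(_data_path(f"{cohort}_demographics_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_code_sets() -> dict:
    """Bundled ICD-10 phenotype definitions.

    Returns a dict with keys ``cvd`` (list of CodeSet for the 11 subtypes,
    in reporting order), ``outcome`` (the AD CodeSet) and ``covariate``
    (CodeSets for covariate conditions such as diabetes).
    """
    with resources.as_file(_data_path("code_sets.yaml")) as p:
        raw = yaml.safe_load(p.read_text())
    order = raw["cvd_subtypes"]
    cvd = [parse_code_spec(raw["phenotypes"][name], name=name) for name in order]
    outcome = [parse_code_spec(spec, name=name) for name, spec in raw["outcome"].items()]
    cov = [parse_code_spec(spec, name=name) for name, spec in raw["covariate_conditions"].items()]
    return {"cvd": cvd, "outcome": outcome[0], "covariate": cov, "subtype_order": order}


def contingency_from_counts(counts: pd.DataFrame, subtype: str) -> ContingencyTable2x2:
    """2x2 exposure x outcome table for one subtype from the count rows."""
    rows = counts[counts["subtype"] == subtype].set_index("cvd_status")
    if set(rows.index) != {"No", "Yes"}:
        raise ValueError(f"subtype {subtype!r} missing No/Yes rows")
    return ContingencyTable2x2(
        a=int(rows.loc["Yes", "n_with_ad"]),
        b=int(rows.loc["Yes", "n_without_ad"]),
        c=int(rows.loc["No", "n_with_ad"]),
        d=int(rows.loc["No", "n_without_ad"]),
    )


def unadjusted_or(cohort: str, subtype: str) -> tuple[float, float, float]:
    """Unadjusted cross-product OR (with Woolf 95% CI) for one subtype,
    recomputed from the published counts.

    This is deliberately the *unadjusted* estimate: the covariate-adjusted
    ORs require record-level data and differ (e.g. UK Biobank hypotension is
    ~5.1 unadjusted versus 2.74 adjusted in the published model).
    """
    return crosstab_or(contingency_from_counts(load_cvd_counts(cohort), subtype))


def recompute_cvd_percentages(counts: pd.DataFrame) -> pd.DataFrame:
    """Recompute each display percentage from the raw counts.

    Overall percentages are against the cohort total (sum of the No+Yes
    column for that subtype); the AD-split percentages are within the
    CVD-status row.  Adds ``computed_pct*`` columns rounded
    half-away-from-zero to one decimal, matching the display convention.
    """
    out = counts.copy()
    totals = out.groupby("subtype")["n"].transform("sum")
    out["computed_pct"] = (100.0 * out["n"] / totals).map(round_half_away)
    out["computed_pct_without"] = (100.0 * out["n_without_ad"] / out["n"]).map(round_half_away)
    out["computed_pct_with"] = (100.0 * out["n_with_ad"] / out["n"]).map(round_half_away)
    return out


def recompute_demographic_percentages(counts: pd.DataFrame) -> pd.DataFrame:
    """Recompute demographic display percentages from the raw counts.

    Denominators are the cohort totals inferred from a covariate whose
    levels partition the cohort (the first covariate in the table, e.g.
    diabetes No/Yes); per-column percentages are against that column's
    total.  NA-count rows for continuous covariates use the same
    denominators.
    """
    out = counts.copy()
    first = out["covariate"].iloc[0]
    base = out[out["covariate"] == first]
    denom_full = base["n_full"].sum()
    denom_without = base["n_without_ad"].sum()
    denom_with = base["n_with_ad"].sum()
    out["computed_pct_full"] = (100.0 * out["n_full"] / denom_full).map(round_half_away)
    out["computed_pct_without"] = (100.0 * out["n_without_ad"] / denom_without).map(round_half_away)
    out["computed_pct_with"] = (100.0 * out["n_with_ad"] / denom_with).map(round_half_away)
    return out


def cohort_total(cohort: str) -> int:
    """Cohort size implied by any subtype's No+Yes column sum."""
    counts = load_cvd_counts(cohort)
    totals = counts.groupby("subtype")["n"].sum().unique()
    if len(totals) != 1:
        raise ValueError(f"inconsistent column sums in {cohort} counts: {totals}")
    return int(totals[0])
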