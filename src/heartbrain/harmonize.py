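"""Covariate harmonization for the cross-sectional analysis table.

Cleaning rules applied before model fitting:

* continuous covariates: missing values imputed with the per-column sample
  median over the full analytic table (even counts: mean of the two central
  order statistics);
* categorical covariates: missing / declined levels collapsed into a single
  "Prefer not to answer"-style level; raw ethnicity levels rolled up to their
  broader classification via an explicit map, with multi-ethnicity entries
  mapped to "Mixed";
* derived scalars: one BMI per participant (first visit, or mean of all
  reported values) and one age (age at assessment, or years since birth
  relative to a reference year).

Harmonization is idempotent and preserves row count and participant ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd


class HarmonizationError(ValueError):
    pass


@dataclass
class HarmonizationPolicy:
    """Declarative cleaning policy for one cohort's raw covariates.

    ``categorical_levels`` maps each categorical column to its allowed final
    level set (the missing-category label is always allowed).  The ethnicity
    collapse map must be total over the raw levels it is asked to handle:
    an undeclared raw level is an error, never a silent pass-through.
    """

    continuous_columns: list[str] = field(default_factory=list)
    categorical_columns: list[str] = field(default_factory=list)
    categorical_levels: dict[str, list[str]] = field(default_factory=dict)
    missing_category_label: str = "Prefer not to answer"
    declined_levels: tuple[str, ...] = ("Prefer not to answer", "Skip", "Do not know")
    ethnicity_column: str | None = None
    ethnicity_collapse_map: dict[str, str] = field(default_factory=dict)
    multi_ethnicity_label: str = "Mixed"
    bmi_mode: Literal["first_visit", "mean_of_all"] = "first_visit"
    age_mode: Literal["at_assessment", "years_since_birth"] = "at_assessment"
    reference_year: int | None = None
    reference_levels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.continuous_columns) & set(self.categorical_columns)
        if overlap:
            raise HarmonizationError(f"columns declared both continuous and categorical: {sorted(overlap)}")
        if self.age_mode == "years_since_birth" and self.reference_year is None:
            raise HarmonizationError("age_mode 'years_since_birth' requires reference_year")


def impute_median(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Replace missing entries in ``columns`` with the per-column median of
    the non-missing values; non-missing entries are unchanged.

    A column with no observed values has no defined median and raises.
    """
    out = table.copy()
    for col in columns:
        vals = out[col]
        if vals.notna().sum() == 0:
            raise HarmonizationError(f"column {col!r} is entirely missing; median undefined")
        out[col] = vals.fillna(vals.median())
    return out


def collapse_categories(table: pd.DataFrame, policy: HarmonizationPolicy) -> pd.DataFrame:
    """Map missing/declined categorical levels to the missing-category label
    and collapse raw ethnicity levels to their broader classification.

    Multi-ethnicity entries (list values, or strings containing ``;``) map to
    the "Mixed" label.  A raw level absent from both the collapse map and the
    declared level set raises, listing the level.
    """
    out = table.copy()
    label = policy.missing_category_label
    for col in policy.categorical_columns:
        vals = out[col]
        if col == policy.ethnicity_column:
            vals = vals.map(lambda v: _collapse_ethnicity(v, policy), na_action="ignore")
        vals = vals.where(~vals.isin(policy.declined_levels), label)
        vals = vals.fillna(label)
        allowed = set(policy.categorical_levels.get(col, [])) | {label}
        if policy.categorical_levels.get(col):
            bad = set(vals.unique()) - allowed
            if bad:
                raise HarmonizationError(f"undeclared levels in {col!r}: {sorted(map(str, bad))}")
        out[col] = vals
    return out


def _collapse_ethnicity(value, policy: HarmonizationPolicy):
    if isinstance(value, (list, tuple)):
        distinct = sorted({str(v) for v in value})
        if len(distinct) > 1:
            return policy.multi_ethnicity_label
        value = distinct[0]
    value = str(value)
    if ";" in value:
        distinct = sorted({p.strip() for p in value.split(";") if p.strip()})
        if len(distinct) > 1:
            return policy.multi_ethnicity_label
        value = distinct[0]
    if value in policy.ethnicity_collapse_map:
        return policy.ethnicity_collapse_map[value]
    # already-collapsed values pass through, keeping the policy idempotent
    if value in set(policy.ethnicity_collapse_map.values()):
        return value
    if value in policy.declined_levels or value == policy.multi_ethnicity_label:
        return value
    allowed = set(policy.categorical_levels.get(policy.ethnicity_column or "", []))
    if value in allowed:
        return value
    raise HarmonizationError(f"undeclared ethnicity level {value!r}")


def derive_scalars(table: pd.DataFrame, policy: HarmonizationPolicy) -> pd.DataFrame:
    """Derive one BMI and one age column per participant.

    BMI observations are taken from columns named ``bmi_*`` (visit order =
    column order) when present, else an existing ``bmi`` column is kept.
    ``mean_of_all`` averages the non-missing observations; a participant with
    none is left missing for :func:`impute_median` to handle.  Age in
    ``years_since_birth`` mode is ``reference_year - birth_year``.
    """
    out = table.copy()
    bmi_cols = [c for c in out.columns if c.startswith("bmi_")]
    if bmi_cols:
        obs = out[bmi_cols]
        if policy.bmi_mode == "mean_of_all":
            out["bmi"] = obs.mean(axis=1)
        else:
            # first non-missing observation in visit order
            out["bmi"] = obs.bfill(axis=1).iloc[:, 0]
    if policy.age_mode == "years_since_birth":
        if "birth_year" not in out.columns:
            raise HarmonizationError("age_mode 'years_since_birth' requires a birth_year column")
        out["age"] = policy.reference_year - out["birth_year"]
    return out


def harmonize(table: pd.DataFrame, policy: HarmonizationPolicy) -> pd.DataFrame:
    """Full policy: derive scalars, collapse categoricals, impute medians."""
    out = derive_scalars(table, policy)
    out = collapse_categories(out, policy)
    out = impute_median(out, policy.continuous_columns)
    return out
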