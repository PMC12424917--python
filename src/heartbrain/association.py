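"""Per-CVD-subtype odds-ratio estimation for a binary outcome.

Each subtype is modeled separately by cross-sectional logistic regression of
the outcome (Alzheimer's disease flag) on the subtype flag plus the full
configured covariate set; the reported odds ratio is ``exp(beta)`` with a
95% Wald interval ``exp(beta +/- 1.96*SE)`` and a Wald p-value.  Subtypes
with too few exposed cases for a stable estimate are reported as excluded
with a reason rather than silently dropped.  No multiple-testing correction
is applied across subtypes; each model stands alone, mirroring per-subtype
forest-plot reporting, and cardiovascular multimorbidity is deliberately not
adjusted for.

The unadjusted cross-product OR on the 2x2 table (:func:`crosstab_or`) is
kept as a closed-form oracle: a single-exposure logistic model with no other
covariates must reproduce it to numerical precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure x outcome counts: a=exposed w/ outcome, b=exposed w/o,
    c=unexposed w/ outcome, d=unexposed w/o."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class AssociationResult:
    subtype: str
    odds_ratio: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p_value: float = float("nan")
    n_total: int = 0
    n_exposed: int = 0
    n_exposed_outcome: int = 0
    excluded: bool = False
    exclusion_reason: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def crosstab_or(t: ContingencyTable2x2) -> tuple[float, float, float]:
    """Unadjusted cross-product odds ratio (a*d)/(b*c) with the Woolf
    log-scale 95% interval exp(ln OR +/- 1.96*sqrt(1/a+1/b+1/c+1/d)).

    All four cells must be positive; continuity corrections for zero cells
    are out of scope here.
    """
    if min(t.a, t.b, t.c, t.d) <= 0:
        raise ValueError(
            "zero cell in 2x2 table; continuity handling is out of scope for this oracle"
        )
    or_ = (t.a * t.d) / (t.b * t.c)
    se = np.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    log_or = np.log(or_)
    return float(or_), float(np.exp(log_or - Z95 * se)), float(np.exp(log_or + Z95 * se))


def fit_logistic(
    outcome: np.ndarray, design: pd.DataFrame | np.ndarray
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Maximum-likelihood logistic fit via Newton iterations.

    Returns ``(coefficients, covariance, converged)`` where the covariance is
    the inverse observed information at the optimum.  The design must already
    include an intercept column.  Separation or other non-convergence is
    reported through the flag, never raised, so callers can mark the result
    excluded downstream.
    """
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim != 2:
        raise ValueError("design must be 2-dimensional")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("outcome must be binary 0/1")
    if np.any(np.all(X == 0, axis=0)):
        raise ValueError("design contains an all-zero column")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
        params = np.asarray(res.params, dtype=float)
        cov = np.asarray(res.cov_params(), dtype=float)
        converged = bool(res.mle_retvals.get("converged", False))
        if not np.all(np.isfinite(params)) or not np.all(np.isfinite(cov)):
            converged = False
    except (np.linalg.LinAlgError, PerfectSeparationError):
        k = X.shape[1]
        return np.full(k, np.nan), np.full((k, k), np.nan), False
    return params, cov, converged


def build_design(
    covariates: pd.DataFrame,
    continuous: list[str],
    categorical: list[str],
    reference_levels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Model matrix: intercept, continuous columns as-is, categoricals as
    indicator contrasts against an explicit reference level per column
    (default: lexicographically first observed level)."""
    refs = reference_levels or {}
    parts = [pd.Series(1.0, index=covariates.index, name="intercept")]
    for col in continuous:
        parts.append(covariates[col].astype(float))
    for col in categorical:
        levels = sorted(covariates[col].astype(str).unique())
        ref = refs.get(col, levels[0])
        for lvl in levels:
            if lvl == ref:
                continue
            parts.append((covariates[col].astype(str) == lvl).astype(float).rename(f"{col}[{lvl}]"))
    return pd.concat(parts, axis=1)


def run_all_subtypes(
    flags: pd.DataFrame,
    covariates: pd.DataFrame,
    subtypes: list[str],
    outcome: str = "AD",
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
    reference_levels: dict[str, str] | None = None,
    min_exposed_outcome: int = 5,
) -> list[AssociationResult]:
    """One adjusted logistic model per subtype.

    ``flags`` carries the outcome and subtype booleans keyed by
    ``participant_id``; ``covariates`` the harmonized adjustment set keyed
    the same way.  A subtype with fewer than ``min_exposed_outcome``
    exposed-with-outcome cases is emitted as excluded ("insufficient cases"),
    as is a model that fails to converge (e.g. separation).
    """
    merged = flags.merge(covariates, on="participant_id", how="inner", validate="1:1")
    if len(merged) != len(flags) or len(merged) != len(covariates):
        only_flags = set(flags["participant_id"]) - set(covariates["participant_id"])
        only_cov = set(covariates["participant_id"]) - set(flags["participant_id"])
        raise ValueError(
            f"participant id mismatch between flags and covariates: "
            f"{len(only_flags)} only in flags, {len(only_cov)} only in covariates"
        )
    y = merged[outcome].astype(float).to_numpy()
    base_design = build_design(merged, continuous or [], categorical or [], reference_levels)

    results: list[AssociationResult] = []
    for subtype in subtypes:
        exposed = merged[subtype].astype(float).to_numpy()
        r = AssociationResult(
            subtype=subtype,
            n_total=len(merged),
            n_exposed=int(exposed.sum()),
            n_exposed_outcome=int((exposed * y).sum()),
        )
        if r.n_exposed_outcome < min_exposed_outcome:
            r.excluded = True
            r.exclusion_reason = (
                f"insufficient cases: {r.n_exposed_outcome} exposed-with-outcome "
                f"< {min_exposed_outcome}"
            )
            results.append(r)
            continue
        design = base_design.copy()
        design.insert(1, subtype, exposed)
        params, cov, converged = fit_logistic(y, design)
        if not converged:
            r.excluded = True
            r.exclusion_reason = "model did not converge (possible separation)"
            results.append(r)
            continue
        beta = params[1]
        se = float(np.sqrt(cov[1, 1]))
        r.odds_ratio = float(np.exp(beta))
        r.ci_low = float(np.exp(beta - Z95 * se))
        r.ci_high = float(np.exp(beta + Z95 * se))
        r.p_value = float(2 * stats.norm.sf(abs(beta / se)))
        results.append(r)
    return results


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (display convention for percentages)."""
    factor = 10.0**ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def prevalence_summaries(flags: pd.DataFrame, outcome: str = "AD") -> pd.DataFrame:
    """Per-phenotype counts and percentages, overall and split by outcome.

    For every non-outcome flag column: the No/Yes counts with percentages of
    the full cohort, and within each phenotype stratum the counts without /
    with the outcome with percentages of that stratum (so a phenotype row's
    without+with percentages sum to ~100).  ``pct_*`` columns carry full
    precision; ``display_pct_*`` are rounded half-away-from-zero to one
    decimal.  Empty strata yield 0.0%, never a division error.
    """
    phenos = [c for c in flags.columns if c not in ("participant_id", outcome)]
    n = len(flags)
    out_flag = flags[outcome].astype(bool)
    rows = []
    for pheno in phenos:
        p = flags[pheno].astype(bool)
        for status, mask in (("No", ~p), ("Yes", p)):
            n_status = int(mask.sum())
            n_with = int((mask & out_flag).sum())
            n_without = n_status - n_with
            pct_overall = 100.0 * n_status / n if n else 0.0
            pct_without = 100.0 * n_without / n_status if n_status else 0.0
            pct_with = 100.0 * n_with / n_status if n_status else 0.0
            rows.append(
                {
                    "phenotype": pheno,
                    "status": status,
                    "n": n_status,
                    "pct_overall": pct_overall,
                    "n_without_outcome": n_without,
                    "pct_without_outcome": pct_without,
                    "n_with_outcome": n_with,
                    "pct_with_outcome": pct_with,
                    "display_pct_overall": round_half_away(pct_overall),
                    "display_pct_without": round_half_away(pct_without),
                    "display_pct_with": round_half_away(pct_with),
                }
            )
    return pd.DataFrame(rows)
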