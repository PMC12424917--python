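"""Demographic summary tables and forest-plot data export."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from heartbrain.association import AssociationResult, round_half_away


def summarize_demographics(
    table: pd.DataFrame,
    outcome: str,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Covariate summary for the full cohort and split by outcome status.

    Continuous covariates are reported as mean (SD) per stratum plus an
    NA-count row (missingness before imputation); categorical covariates as
    count (percent of the stratum column) per level.  Display percentages
    are rounded half-away-from-zero to one decimal; full precision is kept
    in the ``pct_*`` columns.
    """
    continuous = continuous or []
    categorical = categorical or []
    out_flag = table[outcome].astype(bool)
    strata = {"full": pd.Series(True, index=table.index), "without": ~out_flag, "with": out_flag}
    rows = []
    for col in continuous:
        row = {"covariate": col, "level": "mean_sd", "kind": "continuous"}
        na_row = {"covariate": col, "level": "NA", "kind": "continuous_missing"}
        for name, mask in strata.items():
            vals = table.loc[mask, col]
            row[f"mean_{name}"] = float(vals.mean())
            row[f"sd_{name}"] = float(vals.std())
            n_na = int(vals.isna().sum())
            denom = int(mask.sum())
            na_row[f"n_{name}"] = n_na
            na_row[f"pct_{name}"] = 100.0 * n_na / denom if denom else 0.0
            na_row[f"display_pct_{name}"] = round_half_away(na_row[f"pct_{name}"])
        rows.append(row)
        rows.append(na_row)
    for col in categorical:
        levels = [lv for lv in table[col].astype(str).unique()]
        levels.sort()
        for lvl in levels:
            row = {"covariate": col, "level": lvl, "kind": "categorical"}
            is_lvl = table[col].astype(str) == lvl
            for name, mask in strata.items():
                n = int((is_lvl & mask).sum())
                denom = int(mask.sum())
                row[f"n_{name}"] = n
                row[f"pct_{name}"] = 100.0 * n / denom if denom else 0.0
                row[f"display_pct_{name}"] = round_half_away(row[f"pct_{name}"])
            rows.append(row)
    return pd.DataFrame(rows)


def export_forest_data(
    results: list[AssociationResult],
    figure_path: str | Path | None = None,
) -> pd.DataFrame:
    """Plot-ready forest table: one row per subtype with the OR point
    estimate, 95% CI bounds and the exclusion flag.

    Excluded subtypes are kept as rows (flagged) but never plotted.  The
    rendered figure draws a reference line at OR = 1; rendering is
    best-effort and failures never propagate.
    """
    if not any(not r.excluded for r in results):
        raise ValueError("all results are excluded; nothing to plot")
    frame = pd.DataFrame([r.to_dict() for r in results])
    if figure_path is not None:
        try:
            _render_forest(frame, Path(figure_path))
        except Exception:  # rendering is cosmetic; data export is the contract
            pass
    return frame


def _render_forest(frame: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot = frame[~frame["excluded"]].iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.45 * len(plot) + 1.5))
    y = np.arange(len(plot))
    or_ = plot["odds_ratio"].to_numpy()
    ax.errorbar(
        or_, y,
        xerr=[or_ - plot["ci_low"].to_numpy(), plot["ci_high"].to_numpy() - or_],
        fmt="o", color="tab:blue", ecolor="tab:blue", capsize=3,
    )
    ax.axvline(1.0, color="red", linestyle=":")
    ax.set_yticks(y)
    ax.set_yticklabels(plot["subtype"])
    ax.set_xlabel("Odds ratio (95% CI)")
    fig.tight_layout()
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
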