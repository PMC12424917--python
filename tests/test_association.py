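"""Odds-ratio estimation: cross-product oracle, logistic fits, exclusions."""

import numpy as np
import pandas as pd
import pytest

from heartbrain.association import (
    AssociationResult,
    ContingencyTable2x2,
    Z95,
    build_design,
    crosstab_or,
    fit_logistic,
    prevalence_summaries,
    round_half_away,
    run_all_subtypes,
)


class TestCrosstabOr:
    def test_symmetric_table_gives_unit_or(self):
        or_, lo, hi = crosstab_or(ContingencyTable2x2(50, 50, 50, 50))
        assert or_ == 1.0
        assert lo < 1.0 < hi

    def test_zero_cell_raises(self):
        with pytest.raises(ValueError, match="continuity"):
            crosstab_or(ContingencyTable2x2(0, 5, 5, 5))

    def test_ci_widens_when_a_cell_shrinks(self):
        """Shrinking any cell inflates its variance contribution, so the
        log-scale interval can only widen."""
        base = ContingencyTable2x2(100, 200, 300, 400)
        _, lo0, hi0 = crosstab_or(base)
        w0 = np.log(hi0) - np.log(lo0)
        for cell in ("a", "b", "c", "d"):
            kw = {"a": 100, "b": 200, "c": 300, "d": 400}
            kw[cell] = 10
            _, lo, hi = crosstab_or(ContingencyTable2x2(**kw))
            assert np.log(hi) - np.log(lo) > w0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestFitLogistic:
    def test_intercept_only_at_half_prevalence(self):
        y = np.repeat([0.0, 1.0], 500)
        X = np.ones((1000, 1))
        params, cov, converged = fit_logistic(y, X)
        assert converged
        assert params[0] == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_single_exposure_matches_crossproduct(self, seed):
        rng = np.random.default_rng(seed)
        n = 5000
        x = rng.random(n) < 0.3
        p = 1 / (1 + np.exp(-(-2.0 + 0.9 * x)))
        y = (rng.random(n) < p).astype(float)
        a = int((x & (y == 1)).sum())
        b = int((x & (y == 0)).sum())
        c = int((~x & (y == 1)).sum())
        d = int((~x & (y == 0)).sum())
        or_oracle, _, _ = crosstab_or(ContingencyTable2x2(a, b, c, d))
        X = np.column_stack([np.ones(n), x.astype(float)])
        params, cov, converged = fit_logistic(y, X)
        assert converged
        assert np.exp(params[1]) == pytest.approx(or_oracle, abs=1e-6)
        # Wald SE equals the Woolf SE in the saturated single-exposure model
        assert np.sqrt(cov[1, 1]) == pytest.approx(np.sqrt(1/a + 1/b + 1/c + 1/d), abs=1e-6)

    def test_separation_flagged_not_raised(self):
        y = np.array([0.0, 0, 0, 1, 1, 1])
        X = np.column_stack([np.ones(6), y])  # exposure == outcome: separation
        _, _, converged = fit_logistic(y, X)
        assert not converged

    def test_nonbinary_outcome_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            fit_logistic(np.array([0.0, 2.0]), np.ones((2, 1)))


def _flags_and_covariates(n=4000, seed=0, n_exposed_outcome=None):
    rng = np.random.default_rng(seed)
    ids = [f"p{i}" for i in range(n)]
    exposed = rng.random(n) < 0.2
    p = 1 / (1 + np.exp(-(-2.5 + 0.8 * exposed)))
    outcome = rng.random(n) < p
    if n_exposed_outcome is not None:
        # clamp the exposed-case count to an exact value
        outcome = outcome.copy()
        outcome[exposed] = False
        idx = np.flatnonzero(exposed)[:n_exposed_outcome]
        outcome[idx] = True
    flags = pd.DataFrame({"participant_id": ids, "subtype_x": exposed, "AD": outcome})
    cov = pd.DataFrame({"participant_id": ids, "age": rng.normal(56, 8, n)})
    return flags, cov


class TestRunAllSubtypes:
    def test_insufficient_cases_excluded_with_reason(self):
        """A subtype with only two exposed AD cases is reported excluded,
        never silently dropped."""
        flags, cov = _flags_and_covariates(n_exposed_outcome=2)
        (res,) = run_all_subtypes(flags, cov, ["subtype_x"], min_exposed_outcome=5)
        assert res.excluded
        assert "insufficient cases" in res.exclusion_reason
        assert res.n_exposed_outcome == 2
        assert np.isnan(res.odds_ratio)

    def test_unadjusted_model_matches_crosstab_oracle(self):
        flags, cov = _flags_and_covariates(seed=3)
        (res,) = run_all_subtypes(flags, cov[["participant_id"]], ["subtype_x"])
        e = flags["subtype_x"].to_numpy()
        y = flags["AD"].to_numpy()
        t = ContingencyTable2x2(
            int((e & y).sum()), int((e & ~y).sum()), int((~e & y).sum()), int((~e & ~y).sum())
        )
        or_oracle, lo, hi = crosstab_or(t)
        assert res.odds_ratio == pytest.approx(or_oracle, abs=1e-6)
        assert res.ci_low == pytest.approx(lo, abs=1e-6)
        assert res.ci_high == pytest.approx(hi, abs=1e-6)

    def test_counts_consistent_and_ci_brackets_estimate(self):
        flags, cov = _flags_and_covariates(seed=5)
        (res,) = run_all_subtypes(flags, cov, ["subtype_x"], continuous=["age"])
        assert res.n_exposed_outcome <= res.n_exposed <= res.n_total
        assert res.ci_low <= res.odds_ratio <= res.ci_high

    def test_join_mismatch_raises_with_diagnostics(self):
        flags, cov = _flags_and_covariates(n=100)
        with pytest.raises(ValueError, match="id mismatch"):
            run_all_subtypes(flags, cov.iloc[:50], ["subtype_x"])


class TestPrevalenceSummaries:
    def test_percentages_against_correct_denominators(self):
        flags = pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(10)],
                "pheno": [True] * 4 + [False] * 6,
                "AD": [True, False, False, False, True, False, False, False, False, False],
            }
        )
        out = prevalence_summaries(flags).set_index("status")
        assert out.loc["Yes", "pct_overall"] == pytest.approx(40.0)
        assert out.loc["Yes", "pct_with_outcome"] == pytest.approx(25.0)  # 1 of 4
        assert out.loc["No", "pct_with_outcome"] == pytest.approx(100 / 6)

    def test_no_yes_counts_sum_to_roster(self):
        flags = pd.DataFrame(
            {"participant_id": ["a", "b", "c"], "pheno": [True, False, False],
             "AD": [False, True, False]}
        )
        out = prevalence_summaries(flags)
        assert out["n"].sum() == 3

    def test_empty_stratum_no_division_error(self):
        flags = pd.DataFrame(
            {"participant_id": ["a", "b"], "pheno": [False, False], "AD": [False, True]}
        )
        out = prevalence_summaries(flags).set_index("status")
        assert out.loc["Yes", "pct_with_outcome"] == 0.0


def test_round_half_away_from_zero():
    assert round_half_away(2.25, 1) == 2.3
    assert round_half_away(2.24, 1) == 2.2
    assert round_half_away(-2.25, 1) == -2.3


def test_build_design_reference_levels():
    cov = pd.DataFrame({"smoking": ["Never", "Current", "Previous"], "age": [50.0, 60.0, 70.0]})
    X = build_design(cov, ["age"], ["smoking"], {"smoking": "Never"})
    assert "smoking[Never]" not in X.columns
    assert {"smoking[Current]", "smoking[Previous]"} <= set(X.columns)
    assert (X["intercept"] == 1.0).all()
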