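import math

import numpy as np
import pandas as pd
import pytest

from periopscreen.analytics import (
    build_model_frame,
    compare_groups,
    compute_cohort_metrics,
    fit_adherence_model,
    proportion_with_ci,
    provider_distribution,
)


def wilson_reference(k, n, z=1.959963984540054):
    """Textbook Wilson score interval, coded independently."""
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = (z / denom) * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
    return center - half, center + half


class TestProportion:
    def test_printed_cohort_counts(self):
        est = proportion_with_ci(5424, 10592)
        assert round(100 * est.proportion, 1) == 51.2
        assert est.denominator - est.numerator == 5168

    def test_wilson_matches_closed_form(self):
        est = proportion_with_ci(57, 100, method="wilson")
        lo, hi = wilson_reference(57, 100)
        assert est.ci_low == pytest.approx(lo, abs=1e-9)
        assert est.ci_high == pytest.approx(hi, abs=1e-9)

    def test_zero_numerator(self):
        est = proportion_with_ci(0, 50)
        assert est.proportion == 0.0 and est.ci_low == 0.0

    def test_normal_method_clipped_to_unit_interval(self):
        est = proportion_with_ci(1, 200, method="normal")
        assert 0 <= est.ci_low <= est.proportion <= est.ci_high <= 1

    @pytest.mark.parametrize("num, den", [(1, 0), (5, 4), (-1, 10)])
    def test_invalid_counts_rejected(self, num, den):
        with pytest.raises(ValueError):
            proportion_with_ci(num, den)


def _outcome_row(i, status, team="full_team", attending="A1", roc=True, dispo="pacu"):
    return {
        "case_id": f"C{i}", "status": status, "rocuronium_given": roc,
        "disposition": dispo, "attending_id": attending, "team": team,
    }


@pytest.fixture
def ten_case_fixture():
    """Hand-built cohort: 2 misallocated alerts, 1 ICU transfer, 4 enrolled
    of the 7 appropriately allocated cases."""
    rows = [
        _outcome_row(0, "misallocated_exclusion"),
        _outcome_row(1, "misallocated_exclusion"),
        _outcome_row(2, "icu_disposition", dispo="icu_unplanned_transfer"),
        _outcome_row(3, "enrolled"),
        _outcome_row(4, "enrolled"),
        _outcome_row(5, "enrolled"),
        _outcome_row(6, "enrolled"),
        _outcome_row(7, "nonadherent_stock_sugammadex"),
        _outcome_row(8, "nonadherent_no_study_drug", roc=False),
        _outcome_row(9, "nonadherent_stock_sugammadex"),
    ]
    return pd.DataFrame(rows)


class TestCohortMetrics:
    def test_hand_counted_fixture(self, ten_case_fixture):
        m = compute_cohort_metrics(ten_case_fixture)
        assert m.misallocation_rate.proportion == pytest.approx(0.2)
        assert m.icu_share.proportion == pytest.approx(0.1)
        assert m.adherence_overall.proportion == pytest.approx(4 / 7)
        assert m.allocation_accuracy_all.proportion == pytest.approx(7 / 10)
        assert m.allocation_accuracy_pacu.proportion == pytest.approx(7 / 9)
        assert m.rocuronium_share_pacu.proportion == pytest.approx(6 / 7)

    def test_all_enrolled_cohort(self):
        df = pd.DataFrame([_outcome_row(i, "enrolled") for i in range(5)])
        m = compute_cohort_metrics(df)
        assert m.adherence_overall.proportion == 1.0
        assert m.misallocation_rate.proportion == 0.0

    def test_accuracy_pacu_dominates_when_icu_present(self, ten_case_fixture):
        m = compute_cohort_metrics(ten_case_fixture)
        assert m.allocation_accuracy_pacu.proportion >= m.allocation_accuracy_all.proportion

    def test_empty_cohort_sentinel(self):
        m = compute_cohort_metrics(pd.DataFrame(columns=["status", "rocuronium_given", "team"]))
        assert m.empty and m.adherence_overall is None

    def test_row_order_and_relabel_invariance(self, ten_case_fixture):
        m1 = compute_cohort_metrics(ten_case_fixture)
        shuffled = ten_case_fixture.sample(frac=1, random_state=3).reset_index(drop=True)
        shuffled["case_id"] = [f"X{i}" for i in range(len(shuffled))]
        m2 = compute_cohort_metrics(shuffled)
        assert m1.adherence_overall == m2.adherence_overall
        assert m1.icu_share == m2.icu_share


class TestProviderDistribution:
    def test_single_attending_adherence(self):
        rows = [_outcome_row(i, "enrolled" if i < 2 else "nonadherent_no_study_drug")
                for i in range(4)]
        summaries, _ = provider_distribution(pd.DataFrame(rows), min_cases=1)
        assert len(summaries) == 1
        assert summaries[0].adherence == pytest.approx(0.5)
        assert summaries[0].dominant_team == "full_team"

    def test_quartiles_match_sorted_reference(self):
        """Team box-plot quartiles agree with a naive sort-based
        order-statistics computation (linear interpolation)."""
        rng = np.random.default_rng(7)
        rows = []
        i = 0
        adherences = {}
        for a in range(12):
            p = rng.uniform(0.1, 0.9)
            k, n = 0, 10
            for j in range(n):
                enrolled = rng.random() < p
                k += enrolled
                rows.append(_outcome_row(i, "enrolled" if enrolled else
                                         "nonadherent_no_study_drug",
                                         attending=f"A{a}"))
                i += 1
            adherences[f"A{a}"] = k / n
        _, team_stats = provider_distribution(pd.DataFrame(rows), min_cases=5)
        vals = sorted(adherences.values())

        def interp_quantile(sorted_vals, q):
            pos = (len(sorted_vals) - 1) * q
            lo, frac = int(pos), pos - int(pos)
            if lo + 1 < len(sorted_vals):
                return sorted_vals[lo] * (1 - frac) + sorted_vals[lo + 1] * frac
            return sorted_vals[lo]

        row = team_stats.iloc[0]
        assert row["median"] == pytest.approx(interp_quantile(vals, 0.5))
        assert row["q1"] == pytest.approx(interp_quantile(vals, 0.25))
        assert row["q3"] == pytest.approx(interp_quantile(vals, 0.75))

    def test_bimodal_solo_propensities_widen_solo_iqr(self):
        """With the default generator behavior model (bimodal solo mixture),
        the solo-attending IQR of provider adherence exceeds the full-team
        IQR."""
        from periopscreen.simulate import SimConfig, simulate_cohort
        from periopscreen.bpa import run_alert_polls, classify_enrollment, outcomes_frame
        from periopscreen.criteria import screen_cases
        from periopscreen.bpa import AvailabilityConfig

        cohort = simulate_cohort(SimConfig(
            n_patients=4000, seed=31,
            team_mix={"full_team": 0.5, "attending_crna": 0.0,
                      "attending_resident": 0.0, "solo_attending": 0.5},
        ))
        decisions = {d.case_id: d for d in screen_cases(cohort.patients, cohort.cases)}
        config = AvailabilityConfig(eligible_sites=frozenset({"main_campus", "west_campus"}))
        ledger, _ = run_alert_polls(cohort.cases, decisions, config)
        cases_by_id = {c.case_id: c for c in cohort.cases}
        outcomes = [
            classify_enrollment(cases_by_id[cid], ledger.for_case(cid))
            for cid in sorted(ledger.case_ids())
        ]
        df = outcomes_frame(outcomes, cases_by_id)
        _, team_stats = provider_distribution(df, min_cases=5)
        stats = team_stats.set_index("team")
        solo_iqr = stats.loc["solo_attending", "q3"] - stats.loc["solo_attending", "q1"]
        full_iqr = stats.loc["full_team", "q3"] - stats.loc["full_team", "q1"]
        assert solo_iqr > full_iqr


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(1)
        base = pd.DataFrame({
            "age": rng.normal(60, 10, 200),
            "los": rng.lognormal(4, 0.4, 200),
            "flag": rng.random(200) < 0.3,
        })
        table = compare_groups(base, base.copy(),
                               {"age": "continuous_normal", "los": "continuous_skewed",
                                "flag": "categorical"})
        assert (table["p_value"].dropna() > 0.9).all()

    def test_balanced_2x2_chi_square_p_is_1(self):
        a = pd.DataFrame({"flag": [True] * 10 + [False] * 10})
        b = pd.DataFrame({"flag": [True] * 10 + [False] * 10})
        table = compare_groups(a, b, {"flag": "categorical"})
        row = table.iloc[0]
        assert row["test"] == "chi_square"
        assert row["p_value"] == pytest.approx(1.0)

    def test_fisher_selected_for_sparse_2x2(self):
        a = pd.DataFrame({"flag": [True] * 2 + [False] * 8})
        b = pd.DataFrame({"flag": [True] * 1 + [False] * 9})
        table = compare_groups(a, b, {"flag": "categorical"})
        assert table.iloc[0]["test"] == "fisher_exact"

    def test_small_continuous_group_skipped(self):
        a = pd.DataFrame({"age": [50.0]})
        b = pd.DataFrame({"age": [60.0, 61.0, 62.0]})
        table = compare_groups(a, b, {"age": "continuous_normal"})
        assert table.iloc[0]["test"] == "skipped"

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError, match="unknown variable role"):
            compare_groups(pd.DataFrame({"x": [1]}), pd.DataFrame({"x": [2]}), {"x": "weird"})


class TestAdherenceModel:
    def test_balanced_2x2_matches_closed_form_odds_ratio(self):
        """Single-covariate logistic fit on a saturated 2x2 design equals the
        table odds ratio (ad/bc)."""
        a, b, c, d = 60, 40, 30, 70  # exposed-enrolled, exposed-not, unexposed-enrolled, unexposed-not
        rows = (
            [{"x": 1, "status": "enrolled"}] * a
            + [{"x": 1, "status": "nonadherent_no_study_drug"}] * b
            + [{"x": 0, "status": "enrolled"}] * c
            + [{"x": 0, "status": "nonadherent_no_study_drug"}] * d
        )
        df = pd.DataFrame(rows)
        res = fit_adherence_model(df, covariates=("x",), apply_subset=False)
        assert res.converged
        assert res.odds_ratio("x") == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_separation_is_reported_not_raised(self):
        rows = (
            [{"x": 1, "status": "enrolled"}] * 20
            + [{"x": 0, "status": "nonadherent_no_study_drug"}] * 20
        )
        res = fit_adherence_model(pd.DataFrame(rows), covariates=("x",), apply_subset=False)
        assert res.warnings  # separation flagged

    def test_subset_rule_restricts_to_pacu_rocuronium(self, small_cohort):
        from periopscreen.bpa import (
            AvailabilityConfig, classify_enrollment, outcomes_frame, run_alert_polls,
        )
        from periopscreen.criteria import screen_cases

        decisions = {d.case_id: d for d in screen_cases(small_cohort.patients, small_cohort.cases)}
        config = AvailabilityConfig(eligible_sites=frozenset({"main_campus", "west_campus"}))
        ledger, _ = run_alert_polls(small_cohort.cases, decisions, config)
        cases_by_id = {c.case_id: c for c in small_cohort.cases}
        outcomes = [
            classify_enrollment(cases_by_id[cid], ledger.for_case(cid))
            for cid in sorted(ledger.case_ids())
        ]
        df = outcomes_frame(outcomes, cases_by_id)
        frame = build_model_frame(df, cases_by_id, decisions, small_cohort.patients)
        res = fit_adherence_model(frame)
        expected_n = int(
            (frame["rocuronium_given"] & (frame["disposition"] == "pacu")
             & frame["status"].isin(["enrolled", "nonadherent_stock_sugammadex",
                                     "nonadherent_no_study_drug"])).sum()
        )
        assert res.n_fit == expected_n
        assert (res.terms["odds_ratio"] > 0).all()
        assert (res.terms["ci_low"] <= res.terms["odds_ratio"]).all()
        assert (res.terms["odds_ratio"] <= res.terms["ci_high"]).all()
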