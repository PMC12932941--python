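"""System-performance and adherence analytics.

Metric definitions (denominators are always reported alongside):

* allocation accuracy (PACU) — appropriately allocated alerts / alerts to
  non-ICU cases; allocation accuracy (all) — the same numerator over every
  alert, so it can only be lower when ICU dispositions exist;
* misallocation rate — alerts that violated an exclusion / all alerts;
* ICU share — alerted cases with an ICU disposition / all alerts;
* adherence — enrolled / appropriately allocated PACU-recovering alerts
  (an "all alerted" variant is also exposed, since published cohort counts
  use both conventions);
* rocuronium share — rocuronium receipt among appropriately allocated
  PACU alerts.

Confidence intervals default to Wilson score intervals (better small-sample
behavior); a normal-approximation option is provided for comparison with
conventionally reported intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.proportion import proportion_confint

from .bpa import EnrollmentStatus
from .types import Disposition, TeamCategory

__all__ = [
    "ProportionEstimate",
    "proportion_with_ci",
    "CohortMetrics",
    "compute_cohort_metrics",
    "ProviderSummary",
    "provider_distribution",
    "compare_groups",
    "AdherenceModelResult",
    "fit_adherence_model",
    "build_model_frame",
]

_NONADHERENT = {
    EnrollmentStatus.nonadherent_stock_sugammadex.value,
    EnrollmentStatus.nonadherent_no_study_drug.value,
}
_APPROPRIATE = {EnrollmentStatus.enrolled.value} | _NONADHERENT


@dataclass(frozen=True)
class ProportionEstimate:
    numerator: int
    denominator: int
    proportion: float
    ci_low: float
    ci_high: float
    ci_method: str

    def __post_init__(self) -> None:
        if not 0 <= self.ci_low <= self.proportion <= self.ci_high <= 1:
            raise ValueError(
                f"CI ordering violated: {self.ci_low}, {self.proportion}, {self.ci_high}"
            )

    def __str__(self) -> str:
        return (
            f"{100 * self.proportion:.1f}% "
            f"(95% CI {100 * self.ci_low:.1f}%-{100 * self.ci_high:.1f}%; "
            f"{self.numerator}/{self.denominator})"
        )


def proportion_with_ci(
    numerator: int, denominator: int, method: str = "wilson"
) -> ProportionEstimate:
    """Point estimate and 95% CI for a binomial proportion.

    ``method`` is ``"wilson"`` (default) or ``"normal"``. Raises
    ``ValueError`` for a zero denominator or counts out of order.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    if method not in ("wilson", "normal"):
        raise ValueError(f"unknown CI method {method!r}")
    p = numerator / denominator
    lo, hi = proportion_confint(numerator, denominator, alpha=0.05, method=method)
    # normal approximation can overshoot [0,1] or invert at the extremes
    lo = min(max(float(lo), 0.0), p)
    hi = max(min(float(hi), 1.0), p)
    return ProportionEstimate(
        numerator=numerator,
        denominator=denominator,
        proportion=p,
        ci_low=lo,
        ci_high=hi,
        ci_method=method,
    )


@dataclass(frozen=True)
class CohortMetrics:
    """Alert-funnel metrics over one classified cohort.

    All fields are ``None`` for an empty cohort (or when a stratum has an
    empty denominator), never a division error.
    """

    n_alerted_cases: int
    adherence_overall: Optional[ProportionEstimate]
    adherence_all_alerted: Optional[ProportionEstimate]
    adherence_by_team: Mapping[str, ProportionEstimate]
    allocation_accuracy_pacu: Optional[ProportionEstimate]
    allocation_accuracy_all: Optional[ProportionEstimate]
    misallocation_rate: Optional[ProportionEstimate]
    icu_share: Optional[ProportionEstimate]
    rocuronium_share_pacu: Optional[ProportionEstimate]

    @property
    def empty(self) -> bool:
        return self.n_alerted_cases == 0


def _maybe(num: int, den: int, method: str) -> Optional[ProportionEstimate]:
    return proportion_with_ci(num, den, method) if den > 0 else None


def compute_cohort_metrics(outcomes: pd.DataFrame, ci_method: str = "wilson") -> CohortMetrics:
    """Compute the metric set from an outcomes table.

    ``outcomes`` must have one row per alerted case with columns ``status``,
    ``rocuronium_given`` and ``team`` (see ``bpa.outcomes_frame``). Invariant
    to row order and case-id relabeling.
    """
    n = len(outcomes)
    if n == 0:
        return CohortMetrics(0, None, None, {}, None, None, None, None, None)
    status = outcomes["status"]
    n_mis = int((status == EnrollmentStatus.misallocated_exclusion.value).sum())
    n_icu = int((status == EnrollmentStatus.icu_disposition.value).sum())
    appropriate = outcomes[status.isin(_APPROPRIATE)]
    n_appropriate = len(appropriate)
    n_enrolled = int((appropriate["status"] == EnrollmentStatus.enrolled.value).sum())
    by_team: dict[str, ProportionEstimate] = {}
    for team, group in appropriate.groupby("team", sort=True):
        by_team[str(team)] = proportion_with_ci(
            int((group["status"] == EnrollmentStatus.enrolled.value).sum()),
            len(group),
            ci_method,
        )
    return CohortMetrics(
        n_alerted_cases=n,
        adherence_overall=_maybe(n_enrolled, n_appropriate, ci_method),
        adherence_all_alerted=_maybe(n_enrolled, n, ci_method),
        adherence_by_team=by_team,
        allocation_accuracy_pacu=_maybe(n_appropriate, n - n_icu, ci_method),
        allocation_accuracy_all=_maybe(n_appropriate, n, ci_method),
        misallocation_rate=_maybe(n_mis, n, ci_method),
        icu_share=_maybe(n_icu, n, ci_method),
        rocuronium_share_pacu=_maybe(
            int(appropriate["rocuronium_given"].sum()), n_appropriate, ci_method
        ),
    )


@dataclass(frozen=True)
class ProviderSummary:
    attending_id: str
    cases: int
    adherence: float
    dominant_team: str
    below_minimum: bool

    def __post_init__(self) -> None:
        if not 0 <= self.adherence <= 1:
            raise ValueError("adherence must lie in [0, 1]")


def _five_number(values: np.ndarray) -> dict[str, float]:
    """Median/quartiles (linear interpolation) and 1.5-IQR whiskers."""
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # type-7 linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return {
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "n_outliers": int(((values < lo_fence) | (values > hi_fence)).sum()),
        "n_providers": int(values.size),
    }


def provider_distribution(
    outcomes: pd.DataFrame, min_cases: int = 5
) -> tuple[list[ProviderSummary], pd.DataFrame]:
    """Attending-level adherence and team-stratified box-plot statistics.

    Adherence is computed over each attending's alerted, appropriately
    allocated cases. Team five-number summaries are taken over per-
    (attending, team) adherence values restricted to attendings with at
    least ``min_cases`` cases in that stratum; attendings below the minimum
    overall are flagged in their summary.
    """
    appropriate = outcomes[outcomes["status"].isin(_APPROPRIATE)].copy()
    appropriate["enrolled"] = appropriate["status"] == EnrollmentStatus.enrolled.value
    summaries: list[ProviderSummary] = []
    for attending, grp in appropriate.groupby("attending_id", sort=True):
        summaries.append(
            ProviderSummary(
                attending_id=str(attending),
                cases=len(grp),
                adherence=float(grp["enrolled"].mean()),
                dominant_team=str(grp["team"].mode().iloc[0]),
                below_minimum=len(grp) < min_cases,
            )
        )
    team_rows = []
    per_pair = appropriate.groupby(["team", "attending_id"], sort=True).agg(
        cases=("enrolled", "size"), adherence=("enrolled", "mean")
    )
    for team in sorted(appropriate["team"].unique()):
        vals = per_pair.loc[team]
        vals = vals[vals["cases"] >= min_cases]["adherence"].to_numpy(dtype=float)
        if vals.size == 0:
            continue
        team_rows.append({"team": team, **_five_number(vals)})
    return summaries, pd.DataFrame(team_rows)


def compare_groups(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    variables: Mapping[str, str],
    labels: tuple[str, str] = ("adherent", "non_adherent"),
) -> pd.DataFrame:
    """Per-variable bias comparison between two cohorts.

    ``variables`` maps column name to a declared role: ``continuous_normal``
    (mean ± SD, Welch t-test), ``continuous_skewed`` (median [IQR],
    Mann-Whitney U) or ``categorical`` (counts/%; chi-square, or Fisher's
    exact when any expected cell of a 2x2 table is below 5). Two-sided
    p-values; no multiple-testing adjustment is applied, and the table says
    so via the ``note`` column. Continuous tests with fewer than two
    observations in a group are skipped and flagged.
    """
    rows = []
    for var, role in variables.items():
        a = group_a[var].dropna()
        b = group_b[var].dropna()
        row: dict[str, object] = {"variable": var, "role": role, "test": "", "p_value": np.nan,
                                  "note": "unadjusted"}
        if role in ("continuous_normal", "continuous_skewed"):
            if len(a) < 2 or len(b) < 2:
                row["test"] = "skipped"
                row["note"] = "fewer than 2 observations in a group"
                rows.append(row)
                continue
            a_num = a.astype(float)
            b_num = b.astype(float)
            if role == "continuous_normal":
                row[f"summary_{labels[0]}"] = f"{a_num.mean():.2f} ± {a_num.std(ddof=1):.2f}"
                row[f"summary_{labels[1]}"] = f"{b_num.mean():.2f} ± {b_num.std(ddof=1):.2f}"
                row["test"] = "t"
                row["p_value"] = float(stats.ttest_ind(a_num, b_num, equal_var=False).pvalue)
            else:
                for lab, x in zip(labels, (a_num, b_num)):
                    q1, med, q3 = np.percentile(x, [25, 50, 75])
                    row[f"summary_{lab}"] = f"{med:.1f} [{q1:.1f}-{q3:.1f}]"
                row["test"] = "mann_whitney"
                row["p_value"] = float(
                    stats.mannwhitneyu(a_num, b_num, alternative="two-sided").pvalue
                )
        elif role == "categorical":
            table = pd.crosstab(
                pd.concat([a, b], ignore_index=True),
                pd.Series([labels[0]] * len(a) + [labels[1]] * len(b), name="group"),
            )
            for lab in labels:
                counts = table[lab] if lab in table else pd.Series(0, index=table.index)
                total = max(int(counts.sum()), 1)
                row[f"summary_{lab}"] = "; ".join(
                    f"{idx}: {int(c)} ({100 * c / total:.1f}%)" for idx, c in counts.items()
                )
            obs = table.to_numpy()
            if obs.size == 0 or obs.sum() == 0:
                row["test"] = "skipped"
                row["note"] = "no observations"
            else:
                expected = stats.contingency.expected_freq(obs)
                if obs.shape == (2, 2) and (expected < 5).any():
                    row["test"] = "fisher_exact"
                    row["p_value"] = float(stats.fisher_exact(obs).pvalue)
                else:
                    row["test"] = "chi_square"
                    if (expected < 5).any():
                        row["note"] = "unadjusted; expected cell < 5 in non-2x2 table"
                    row["p_value"] = float(stats.chi2_contingency(obs).pvalue)
        else:
            raise ValueError(f"unknown variable role {role!r} for {var!r}")
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AdherenceModelResult:
    """Odds ratios for provider adherence from a multivariable logistic fit."""

    terms: pd.DataFrame  # covariate, odds_ratio, ci_low, ci_high, p_value
    n_fit: int
    subset_rule: str
    converged: bool
    warnings: tuple[str, ...] = ()
    reference_levels: Mapping[str, str] = field(default_factory=dict)

    def odds_ratio(self, covariate: str) -> float:
        match = self.terms[self.terms["covariate"].str.contains(covariate, regex=False)]
        if match.empty:
            raise KeyError(covariate)
        return float(match["odds_ratio"].iloc[0])

    def summary(self) -> str:
        lines = [
            f"Adherence model (n = {self.n_fit}; subset: {self.subset_rule};"
            f" converged: {self.converged})",
            self.terms.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
        if self.reference_levels:
            refs = ", ".join(f"{k}={v}" for k, v in self.reference_levels.items())
            lines.append(f"reference levels: {refs}")
        lines.extend(f"warning: {w}" for w in self.warnings)
        return "\n".join(lines)


def build_model_frame(
    outcomes: pd.DataFrame,
    cases: dict,
    decisions: dict,
    patients: dict | None = None,
) -> pd.DataFrame:
    """Merge outcomes with case/decision covariates for adherence modeling.

    Emits the workflow and clinical covariates the adherence model uses:
    team category, delay flags, long-surgery flag and scheduled duration,
    service, low-hemoglobin and low-SpO2 criterion flags, BMI category,
    age in years, and ASA status where recorded.
    """
    from .criteria import CriterionId, _age_years  # local import avoids a cycle

    rows = []
    for rec in outcomes.to_dict("records"):
        case = cases[rec["case_id"]]
        decision = decisions[rec["case_id"]]
        met = {r.criterion_id: r.met for r in decision.criterion_results}
        delays = {d.value for d in case.delays}
        bmi_cat = (
            "over_40"
            if met[CriterionId.bmi_over_40]
            else "35_to_40" if met[CriterionId.bmi_over_35] else "under_35"
        )
        row = dict(rec)
        row.update(
            long_surgery=met[CriterionId.long_surgery],
            scheduled_duration_min=case.scheduled_duration_min,
            delay_patient_related="patient_related" in delays,
            delay_scheduling="scheduling" in delays,
            delay_staff_related="staff_related" in delays,
            service=case.service or "unknown",
            low_hemoglobin=met[CriterionId.low_hemoglobin],
            low_preop_spo2=met[CriterionId.low_preop_spo2],
            bmi_category=bmi_cat,
            asa_status=case.asa_status,
        )
        if patients is not None:
            patient = patients[case.patient_id]
            row["age_years"] = _age_years(patient.birth_date, case.scheduled_start.date())
        rows.append(row)
    return pd.DataFrame(rows)


DEFAULT_COVARIATES = (
    "C(team, Treatment('full_team'))",
    "long_surgery",
    "delay_patient_related",
    "delay_scheduling",
    "delay_staff_related",
    "low_hemoglobin",
    "low_preop_spo2",
)


def fit_adherence_model(
    frame: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    apply_subset: bool = True,
) -> AdherenceModelResult:
    """Fit the multivariable logistic model of provider adherence.

    The fit is restricted (``apply_subset=True``) to alerted cases that
    received rocuronium and recovered in the PACU, with outcome enrolled vs
    non-adherent, so that postoperative disposition cannot confound the
    adherence estimates. Odds ratios use Wald 95% CIs from maximum
    likelihood. Complete separation or non-convergence is reported in
    ``warnings`` rather than raised.
    """
    df = frame
    subset_rule = "rocuronium_given and PACU recovery; enrolled vs non-adherent"
    if apply_subset:
        df = df[
            df["rocuronium_given"]
            & (df["disposition"] == Disposition.pacu.value)
            & df["status"].isin(_APPROPRIATE)
        ].copy()
    df = df.copy()
    df["enrolled"] = (df["status"] == EnrollmentStatus.enrolled.value).astype(int)
    for col in df.columns:
        if df[col].dtype == bool:
            df[col] = df[col].astype(int)
    formula = "enrolled ~ " + " + ".join(covariates)
    warn_msgs: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.logit(formula, data=df)
        try:
            res = model.fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception as exc:  # e.g. perfect separation raised as error
            warn_msgs.append(f"fit failed: {exc}")
            res = model.fit(disp=0, method="bfgs", maxiter=500)
            converged = bool(res.mle_retvals.get("converged", False))
    for w in caught:
        if "separation" in str(w.message).lower() or "converge" in str(w.message).lower():
            warn_msgs.append(str(w.message))
    params = res.params.drop(labels=["Intercept"], errors="ignore")
    conf = res.conf_int().drop(index=["Intercept"], errors="ignore")
    pvals = res.pvalues.drop(labels=["Intercept"], errors="ignore")
    for name, coef in params.items():
        if abs(coef) > 15:
            warn_msgs.append(f"possible complete separation on {name} (|coef| > 15)")
    with np.errstate(over="ignore"):  # separation can push a CI bound to inf
        terms = pd.DataFrame(
            {
                "covariate": params.index,
                "odds_ratio": np.exp(params.to_numpy()),
                "ci_low": np.exp(conf[0].to_numpy()),
                "ci_high": np.exp(conf[1].to_numpy()),
                "p_value": pvals.to_numpy(),
            }
        ).reset_index(drop=True)
    refs = {"team": TeamCategory.full_team.value}
    return AdherenceModelResult(
        terms=terms,
        n_fit=int(len(df)),
        subset_rule=subset_rule,
        converged=converged,
        warnings=tuple(warn_msgs),
        reference_levels=refs,
    )
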