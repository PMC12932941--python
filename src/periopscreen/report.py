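"""Cohort report: funnel, metrics with CIs, stratified adherence, provider
box-plot statistics, bias table and adherence-model odds ratios.

Emits a human-readable markdown report plus machine-readable CSV/JSON of
every table, and optionally a box-plot figure of attending-level adherence
stratified by team composition (whiskers at 1.5 x IQR).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd

from .analytics import (
    AdherenceModelResult,
    CohortMetrics,
    ProportionEstimate,
    provider_distribution,
)

__all__ = ["write_report"]


def _est_row(name: str, est: Optional[ProportionEstimate]) -> dict:
    if est is None:
        return {"metric": name, "value": None, "ci_low": None, "ci_high": None,
                "numerator": None, "denominator": None, "ci_method": None}
    return {
        "metric": name,
        "value": est.proportion,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "numerator": est.numerator,
        "denominator": est.denominator,
        "ci_method": est.ci_method,
    }


def metrics_table(metrics: CohortMetrics) -> pd.DataFrame:
    rows = [
        _est_row("adherence_overall", metrics.adherence_overall),
        _est_row("adherence_all_alerted", metrics.adherence_all_alerted),
        _est_row("allocation_accuracy_pacu", metrics.allocation_accuracy_pacu),
        _est_row("allocation_accuracy_all", metrics.allocation_accuracy_all),
        _est_row("misallocation_rate", metrics.misallocation_rate),
        _est_row("icu_share", metrics.icu_share),
        _est_row("rocuronium_share_pacu", metrics.rocuronium_share_pacu),
    ]
    rows += [
        _est_row(f"adherence_team_{team}", est)
        for team, est in metrics.adherence_by_team.items()
    ]
    return pd.DataFrame(rows)


def write_report(
    outdir: str | Path,
    funnel: dict[str, int],
    metrics: CohortMetrics,
    outcomes: pd.DataFrame,
    bias_table: Optional[pd.DataFrame] = None,
    model_result: Optional[AdherenceModelResult] = None,
    min_provider_cases: int = 5,
    make_figure: bool = True,
) -> Path:
    """Write report.md plus machine-readable tables; returns the report path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mt = metrics_table(metrics)
    mt.to_csv(outdir / "metrics.csv", index=False)
    (outdir / "metrics.json").write_text(
        json.dumps(mt.where(mt.notna(), None).to_dict("records"), indent=2) + "\n",
        encoding="utf-8",
    )
    providers, team_stats = provider_distribution(outcomes, min_cases=min_provider_cases)
    provider_df = pd.DataFrame([vars(p) for p in providers])
    provider_df.to_csv(outdir / "providers.csv", index=False)
    team_stats.to_csv(outdir / "team_boxplot_stats.csv", index=False)
    if bias_table is not None:
        bias_table.to_csv(outdir / "bias_table.csv", index=False)
    if model_result is not None:
        model_result.terms.to_csv(outdir / "model_odds_ratios.csv", index=False)

    lines = ["# Cohort report", "", "## Funnel", "",
             "| stage | cases |", "|---|---|"]
    lines += [f"| {stage} | {count} |" for stage, count in funnel.items()]
    lines += ["", "## Metrics (95% CI; denominators shown)", ""]
    if metrics.empty:
        lines.append("Empty cohort: no alerted cases; metrics not defined.")
    else:
        lines += ["| metric | estimate |", "|---|---|"]
        for row in mt.to_dict("records"):
            if row["value"] is None:
                lines.append(f"| {row['metric']} | (empty denominator) |")
            else:
                lines.append(
                    f"| {row['metric']} | {100 * row['value']:.1f}% "
                    f"({100 * row['ci_low']:.1f}-{100 * row['ci_high']:.1f}%; "
                    f"{row['numerator']}/{row['denominator']}) |"
                )
    if not team_stats.empty:
        lines += ["", "## Provider adherence by team (attending-level, 1.5 x IQR whiskers)",
                  "", team_stats.to_markdown(index=False)]
    if bias_table is not None and not bias_table.empty:
        lines += ["", "## Adherent vs non-adherent comparison (unadjusted p-values)",
                  "", bias_table.to_markdown(index=False)]
    if model_result is not None:
        lines += ["", "## Adherence model", "", "```", model_result.summary(), "```"]
    report_path = outdir / "report.md"
    report_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    if make_figure and not outcomes.empty:
        _boxplot_figure(outcomes, outdir / "provider_adherence.png", min_provider_cases)
    return report_path


def _boxplot_figure(outcomes: pd.DataFrame, path: Path, min_cases: int) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .analytics import _APPROPRIATE

    appropriate = outcomes[outcomes["status"].isin(_APPROPRIATE)].copy()
    if appropriate.empty:
        return
    appropriate["enrolled"] = (appropriate["status"] == "enrolled").astype(float)
    per_pair = appropriate.groupby(["team", "attending_id"]).agg(
        cases=("enrolled", "size"), adherence=("enrolled", "mean")
    )
    order = ["full_team", "attending_crna", "attending_resident", "solo_attending"]
    data, labels = [], []
    for team in order:
        if team not in per_pair.index.get_level_values(0):
            continue
        vals = per_pair.loc[team]
        vals = vals[vals["cases"] >= min_cases]["adherence"]
        if len(vals):
            data.append(vals.to_numpy())
            labels.append(team.replace("_", "\n"))
    if not data:
        return
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.boxplot(data, tick_labels=labels, whis=1.5)
    ax.set_ylabel("attending adherence rate")
    ax.set_title("Provider adherence to BPA-prompted study ordering by team")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
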