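"""Batch pipeline: simulate -> screen -> alerts -> classify -> report.

Each stage reads files written by the previous one (so stages can be run
standalone and replayed) and every run writes a ``RunManifest`` recording
the command, config hash, seeds, code-set resource version, input/output
paths and per-stage row counts. Stage failures halt the pipeline with an
error naming the stage.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, time, timedelta
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError

from . import analytics
from .bpa import (
    AlertContext,
    AlertLedger,
    AvailabilityConfig,
    BpaAlert,
    classify_enrollment,
    outcomes_frame,
    run_alert_polls,
)
from .config import default_criteria_config
from .criteria import decisions_frame, evaluate_exclusions, screen_cases
from .errors import ConfigError, DataValidationError, StageError
from .io import read_dataset
from .report import write_report
from .simulate import SimConfig, simulate_cohort, write_fixture
from .types import Dataset

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "run_workflow",
           "stage_simulate", "stage_screen", "stage_alerts", "stage_classify", "stage_report"]


def run_workflow(
    dataset: Dataset, availability: Optional[AvailabilityConfig] = None
) -> tuple[dict, AlertLedger, pd.DataFrame]:
    """In-memory screen -> alerts -> classify over a loaded dataset.

    Returns the decision map (case_id -> EligibilityDecision), the alert
    ledger, and the classified-outcomes frame for the alerted cases.
    """
    availability = availability or AvailabilitySettings().to_config()
    decisions = {d.case_id: d for d in screen_cases(dataset.patients, dataset.cases)}
    ledger, _ = run_alert_polls(dataset.cases, decisions, availability)
    cases_by_id = {c.case_id: c for c in dataset.cases}
    outcomes = []
    for case_id in sorted(ledger.case_ids()):
        case = cases_by_id[case_id]
        current = evaluate_exclusions(dataset.patients[case.patient_id], case)
        outcomes.append(classify_enrollment(case, ledger.for_case(case_id), current))
    return decisions, ledger, outcomes_frame(outcomes, cases_by_id)


class AvailabilitySettings(BaseModel):
    eligible_sites: list[str] = Field(default_factory=lambda: ["main_campus", "west_campus"])
    pharmacy_open: str = "07:00"
    pharmacy_close: str = "22:00"
    preop_lead_days: int = 7

    def to_config(self) -> AvailabilityConfig:
        try:
            return AvailabilityConfig(
                eligible_sites=frozenset(self.eligible_sites),
                pharmacy_open=time.fromisoformat(self.pharmacy_open),
                pharmacy_close=time.fromisoformat(self.pharmacy_close),
                preop_lead=timedelta(days=self.preop_lead_days),
            )
        except ValueError as exc:
            raise ConfigError(f"invalid availability settings: {exc}") from exc


class PipelineConfig(BaseModel):
    seed: int = 0
    format: str = "jsonl"
    sim: dict = Field(default_factory=dict)  # SimConfig overrides
    availability: AvailabilitySettings = Field(default_factory=AvailabilitySettings)
    min_provider_cases: int = 5
    make_figure: bool = True

    def sim_config(self) -> SimConfig:
        try:
            return SimConfig(**{"seed": self.seed, **self.sim})
        except (ValidationError, ValueError) as exc:
            raise ConfigError(f"invalid sim config: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
            return cls(**raw)
        except FileNotFoundError as exc:
            raise ConfigError(f"config file not found: {path}") from exc
        except (ValidationError, yaml.YAMLError, TypeError) as exc:
            raise ConfigError(f"invalid pipeline config {path}: {exc}") from exc


@dataclass
class RunManifest:
    command: str
    config_hash: str
    seeds: dict[str, int]
    code_set_version: str
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    row_counts: dict[str, int] = field(default_factory=dict)
    started_at: str = ""
    finished_at: str = ""

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n",
                              encoding="utf-8")


def _manifest(command: str, config: PipelineConfig) -> RunManifest:
    return RunManifest(
        command=command,
        config_hash=config.sim_config().config_hash(),
        seeds={"master": config.seed},
        code_set_version=default_criteria_config().version,
        started_at=datetime.now().isoformat(timespec="seconds"),
    )


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DataValidationError(f"stage '{stage}': missing input {path}")
    return path


# --------------------------------------------------------------- stages


def stage_simulate(config: PipelineConfig, outdir: Path) -> Dataset:
    cohort = simulate_cohort(config.sim_config())
    write_fixture(outdir, cohort, format=config.format)
    return cohort.dataset


def stage_screen(data_dir: Path, out_path: Path, format: str) -> pd.DataFrame:
    dataset = read_dataset(_require(data_dir, "screen"), format=format)
    decisions = screen_cases(dataset.patients, dataset.cases)
    frame = decisions_frame(decisions)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    if format == "jsonl":
        frame.to_json(out_path, orient="records", lines=True)
    else:
        frame.to_csv(out_path, index=False)
    return frame


def stage_alerts(
    data_dir: Path, out_dir: Path, availability: AvailabilityConfig, format: str
) -> tuple[AlertLedger, pd.DataFrame]:
    dataset = read_dataset(_require(data_dir, "alerts"), format=format)
    decisions = {d.case_id: d for d in screen_cases(dataset.patients, dataset.cases)}
    ledger, poll_log = run_alert_polls(dataset.cases, decisions, availability)
    out_dir.mkdir(parents=True, exist_ok=True)
    alerts_df = pd.DataFrame(
        [
            {"case_id": a.case_id, "context": a.context.value,
             "fired_at": a.fired_at.isoformat()}
            for a in ledger.alerts()
        ],
        columns=["case_id", "context", "fired_at"],
    )
    alerts_df.to_csv(out_dir / "alerts.csv", index=False)
    poll_log.to_csv(out_dir / "poll_log.csv", index=False)
    return ledger, alerts_df


def stage_classify(data_dir: Path, alerts_path: Path, out_path: Path, format: str) -> pd.DataFrame:
    dataset = read_dataset(_require(data_dir, "classify"), format=format)
    _require(alerts_path, "classify")
    alerts_df = pd.read_csv(alerts_path, dtype={"case_id": str})
    cases_by_id = {c.case_id: c for c in dataset.cases}
    decisions = {d.case_id: d for d in screen_cases(dataset.patients, dataset.cases)}
    unknown = set(alerts_df["case_id"]) - set(cases_by_id)
    if unknown:
        raise DataValidationError(
            f"alert ledger references unknown cases: {sorted(unknown)[:5]}"
        )
    outcomes = []
    for case_id, group in alerts_df.groupby("case_id", sort=True):
        case = cases_by_id[str(case_id)]
        alerts = [
            BpaAlert(
                case_id=str(case_id),
                fired_at=datetime.fromisoformat(row["fired_at"]),
                context=AlertContext(row["context"]),
                decision_snapshot=decisions[str(case_id)],
            )
            for row in group.to_dict("records")
        ]
        current_exclusions = evaluate_exclusions(dataset.patients[case.patient_id], case)
        outcomes.append(classify_enrollment(case, alerts, current_exclusions))
    frame = outcomes_frame(outcomes, cases_by_id)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out_path, index=False)
    return frame


def stage_report(
    data_dir: Path,
    outcomes_path: Path,
    eligibility_path: Path,
    out_dir: Path,
    config: PipelineConfig,
) -> Path:
    dataset = read_dataset(_require(data_dir, "report"), format=config.format)
    _require(outcomes_path, "report")
    outcomes = pd.read_csv(
        outcomes_path, dtype={"case_id": str, "attending_id": str}
    )
    if not outcomes.empty:
        outcomes["rocuronium_given"] = outcomes["rocuronium_given"].astype(bool)
    decisions = {d.case_id: d for d in screen_cases(dataset.patients, dataset.cases)}
    n_eligible = sum(1 for d in decisions.values() if d.included)
    n_alertable = sum(1 for d in decisions.values() if d.included and not d.excluded)
    funnel = {
        "patients": len(dataset.patients),
        "cases": len(dataset.cases),
        "rule_eligible": n_eligible,
        "eligible_not_excluded": n_alertable,
        "alerted": int(outcomes["case_id"].nunique()) if not outcomes.empty else 0,
        "enrolled": int((outcomes["status"] == "enrolled").sum()) if not outcomes.empty else 0,
    }
    metrics = analytics.compute_cohort_metrics(outcomes)
    bias_table = model_result = None
    if not outcomes.empty:
        cases_by_id = {c.case_id: c for c in dataset.cases}
        frame = analytics.build_model_frame(outcomes, cases_by_id, decisions, dataset.patients)
        adherent = frame[frame["status"] == "enrolled"]
        nonadherent = frame[frame["status"].str.startswith("nonadherent")]
        if len(adherent) >= 2 and len(nonadherent) >= 2:
            bias_table = analytics.compare_groups(
                adherent, nonadherent,
                {"age_years": "continuous_skewed", "scheduled_duration_min": "continuous_skewed",
                 "low_hemoglobin": "categorical", "bmi_category": "categorical",
                 "team": "categorical"},
            )
            subset = frame[
                frame["rocuronium_given"].astype(bool) & (frame["disposition"] == "pacu")
            ]
            if subset["status"].isin(["enrolled"]).any() and len(subset) > 50:
                model_result = analytics.fit_adherence_model(frame)
    return write_report(
        out_dir,
        funnel=funnel,
        metrics=metrics,
        outcomes=outcomes,
        bias_table=bias_table,
        model_result=model_result,
        min_provider_cases=config.min_provider_cases,
        make_figure=config.make_figure,
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> RunManifest:
    """Execute all stages in order; each stage's output feeds the next.

    Any stage failure raises :class:`StageError` naming the stage (config
    and data-validation errors propagate unchanged).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _manifest("pipeline", config)
    data_dir = outdir / "data"
    eligibility = outdir / "screen" / ("eligibility.jsonl" if config.format == "jsonl"
                                       else "eligibility.csv")
    alerts_dir = outdir / "alerts"
    outcomes_path = outdir / "classify" / "outcomes.csv"
    report_dir = outdir / "report"

    stages = [
        ("simulate", lambda: stage_simulate(config, data_dir)),
        ("screen", lambda: stage_screen(data_dir, eligibility, config.format)),
        ("alerts", lambda: stage_alerts(data_dir, alerts_dir,
                                        config.availability.to_config(), config.format)),
        ("classify", lambda: stage_classify(data_dir, alerts_dir / "alerts.csv",
                                            outcomes_path, config.format)),
        ("report", lambda: stage_report(data_dir, outcomes_path, eligibility,
                                        report_dir, config)),
    ]
    results: dict[str, object] = {}
    for name, fn in stages:
        try:
            results[name] = fn()
        except (ConfigError, DataValidationError):
            raise
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, str(exc)) from exc

    dataset: Dataset = results["simulate"]  # type: ignore[assignment]
    screen_df: pd.DataFrame = results["screen"]  # type: ignore[assignment]
    _, alerts_df = results["alerts"]  # type: ignore[misc]
    outcomes_df: pd.DataFrame = results["classify"]  # type: ignore[assignment]
    manifest.inputs = {"config": "inline"}
    manifest.outputs = {
        "data": str(data_dir), "eligibility": str(eligibility),
        "alerts": str(alerts_dir / "alerts.csv"), "outcomes": str(outcomes_path),
        "report": str(results["report"]),
    }
    manifest.row_counts = {
        "patients": len(dataset.patients),
        "cases": len(dataset.cases),
        "eligible": int(screen_df["included"].sum()) if not screen_df.empty else 0,
        "alerted": int(alerts_df["case_id"].nunique()) if not alerts_df.empty else 0,
        "classified": len(outcomes_df),
    }
    manifest.finished_at = datetime.now().isoformat(timespec="seconds")
    manifest.write(outdir / "manifest.json")
    return manifest
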