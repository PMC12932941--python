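"""Loader for the externalized criterion-definition resource.

The rule set (code sets, thresholds, lookback windows, surgical-site text
rules) ships as a versioned YAML resource so it can be audited and diffed
independently of the engine code. :func:`load_criteria_config` parses and
validates it into a :class:`CriteriaConfig`; code-set token errors surface
at load time as :class:`~periopscreen.errors.ConfigError`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .codes import CodeSet
from .errors import ConfigError

__all__ = ["CriteriaConfig", "load_criteria_config", "default_criteria_config"]


@dataclass(frozen=True)
class SurgicalSiteRule:
    excluded_service: str
    transplant_token: str
    service_tokens: Mapping[str, tuple[str, ...]]
    head_neck_service: str
    head_neck_forbidden_tokens: tuple[str, ...]
    head_neck_rule: str  # "both" | "either"
    cpt_codes: frozenset[str]


@dataclass(frozen=True)
class CriteriaConfig:
    version: str
    code_sets: Mapping[str, CodeSet]
    acute_infection_days: int
    hemoglobin_days: int
    spo2_hours: float
    spo2_mean_pct: float
    bmi_major: float
    bmi_minor: float
    hemoglobin_g_dl: float
    long_surgery_min: int
    ventilator_hours: float
    intubation_attempts: int
    gfr_exclusion: float
    adult_age_years: int
    surgical_site: SurgicalSiteRule


def load_criteria_config(path: str | Path | None = None) -> CriteriaConfig:
    """Load and validate a criterion-definition file (default: the bundled
    resource)."""
    if path is None:
        text = (
            resources.files("periopscreen.resources")
            .joinpath("criteria.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"criteria config is not valid YAML: {exc}") from exc
    try:
        code_sets = {
            name: CodeSet(name=name, tokens=tuple(str(t) for t in tokens))
            for name, tokens in raw["code_sets"].items()
        }
        win = raw["windows"]
        thr = raw["thresholds"]
        ss = raw["surgical_site"]
        rule = str(ss.get("head_neck_rule", "both"))
        if rule not in ("both", "either"):
            raise ConfigError(f"head_neck_rule must be 'both' or 'either', got {rule!r}")
        site = SurgicalSiteRule(
            excluded_service=str(ss["excluded_service"]),
            transplant_token=str(ss["transplant_token"]),
            service_tokens={
                svc: tuple(str(t) for t in toks)
                for svc, toks in ss["service_tokens"].items()
            },
            head_neck_service=str(ss["head_neck_service"]),
            head_neck_forbidden_tokens=tuple(
                str(t) for t in ss["head_neck_forbidden_tokens"]
            ),
            head_neck_rule=rule,
            cpt_codes=frozenset(str(c) for c in ss["cpt_codes"]),
        )
        return CriteriaConfig(
            version=str(raw["version"]),
            code_sets=code_sets,
            acute_infection_days=int(win["acute_infection_days"]),
            hemoglobin_days=int(win["hemoglobin_days"]),
            spo2_hours=float(win["spo2_hours"]),
            spo2_mean_pct=float(thr["spo2_mean_pct"]),
            bmi_major=float(thr["bmi_major"]),
            bmi_minor=float(thr["bmi_minor"]),
            hemoglobin_g_dl=float(thr["hemoglobin_g_dl"]),
            long_surgery_min=int(thr["long_surgery_min"]),
            ventilator_hours=float(thr["ventilator_hours"]),
            intubation_attempts=int(thr["intubation_attempts"]),
            gfr_exclusion=float(thr["gfr_exclusion"]),
            adult_age_years=int(thr["adult_age_years"]),
            surgical_site=site,
        )
    except ConfigError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"criteria config is malformed: {exc!r}") from exc


_DEFAULT: CriteriaConfig | None = None


def default_criteria_config() -> CriteriaConfig:
    """The bundled rule set, loaded once per process."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_criteria_config()
    return _DEFAULT
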