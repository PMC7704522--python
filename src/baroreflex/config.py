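"""Pipeline configuration (YAML-backed, strictly validated).

Unknown keys are rejected; every numeric setting is bounds-checked.
The config hash (sha256 of the canonical JSON dump, first 12 hex
digits) is stamped into every output table.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .extract import ExtractionSettings
from .planning import PlanSpec
from .simulate import BolusSchedule, ConditionParams, SubjectSpec


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ExtractionConfig(_Strict):
    baseline_beats: int = Field(10, ge=2, le=100)
    peak_window_s: float = Field(60.0, gt=0, le=300)
    peak_run_length: int = Field(3, ge=1, le=20)
    r_threshold: float = Field(0.5, ge=0, lt=1)
    min_pairs: int = Field(5, ge=2, le=100)
    lag: Literal[0, 1, 2] = 1
    onset_sd_multiplier: float = Field(2.0, ge=0, le=10)

    def to_settings(self) -> ExtractionSettings:
        return ExtractionSettings(**self.model_dump())


class StatsConfig(_Strict):
    alpha: float = Field(0.05, gt=0, lt=1)
    test_variant: Literal["welch", "pooled"] = "welch"
    holm_correction: bool = False


class ScheduleConfig(_Strict):
    n_boli: int = Field(20, ge=1, le=200)
    interval_s: float = Field(240.0, gt=60)
    dose_ug: float = Field(50.0, gt=0)
    first_bolus_s: float = Field(120.0, gt=0)

    def to_schedule(self) -> BolusSchedule:
        return BolusSchedule(**self.model_dump())


class ConditionConfig(_Strict):
    label: Literal["normoxia", "hypoxia"]
    sbp_baseline: float = Field(133.0, gt=0)
    hr_baseline: float = Field(63.0, gt=0)
    brs_true: float = Field(19.9, ge=0)
    dsbp_true: float = Field(22.0, ge=0)
    brs_bolus_sd: float = Field(5.0, ge=0)
    dsbp_bolus_sd: float = Field(5.0, ge=0)
    rri_noise_sd: float = Field(10.0, ge=0)
    sbp_noise_sd: float = Field(2.0, ge=0)
    spo2: float = Field(98.1, gt=0, le=100)
    ve: float = Field(11.9, gt=0)
    vt: float = Field(0.77, gt=0)
    rr_breaths: float = Field(16.0, gt=0)
    etco2: float = Field(38.3, gt=0)
    rsa_amplitude_ms: float = Field(0.0, ge=0)

    def to_params(self) -> ConditionParams:
        return ConditionParams(**self.model_dump())


class SubjectConfig(_Strict):
    subject_id: str
    first_condition: Literal["normoxia", "hypoxia"] = "normoxia"
    normoxia: ConditionConfig
    hypoxia: ConditionConfig


class PlanConfig(_Strict):
    effect_mean: float = 6.0
    effect_sd: float = Field(3.0, ge=0)
    bolus_sd: Optional[float] = Field(None, gt=0)  # None -> derived from reference table
    n_grid: list[int] = [2, 4, 6, 8, 10, 12, 15, 20]
    n_sim: int = Field(2000, ge=100, le=100000)
    alpha: float = Field(0.05, gt=0, lt=1)
    target_sensitivity: float = Field(0.9, gt=0, lt=1)
    method: Literal["ttest_power", "roc_mean_classifier"] = "ttest_power"

    def to_spec(self, seed: int) -> PlanSpec:
        from .planning import default_plan_spec

        kwargs = self.model_dump()
        bolus_sd = kwargs.pop("bolus_sd")
        kwargs["n_grid"] = tuple(kwargs["n_grid"])
        if bolus_sd is None:
            return default_plan_spec(seed=seed, **kwargs)
        return PlanSpec(bolus_sd=bolus_sd, seed=seed, **kwargs)


class PipelineConfig(_Strict):
    """Top-level run configuration: simulate → extract → analyze → plan."""

    seed: int = Field(0, ge=0, lt=2**31)
    extraction: ExtractionConfig = ExtractionConfig()
    stats: StatsConfig = StatsConfig()
    schedule: ScheduleConfig = ScheduleConfig()
    plan: PlanConfig = PlanConfig()
    cohort: Optional[list[SubjectConfig]] = None  # None -> bundled default cohort
    randomize_order: bool = False

    def subject_specs(self) -> list[SubjectSpec]:
        from .simulate import default_cohort

        schedule = self.schedule.to_schedule()
        if self.cohort is None:
            return [
                SubjectSpec(
                    subject_id=s.subject_id,
                    normoxia=s.normoxia,
                    hypoxia=s.hypoxia,
                    schedule=schedule,
                    first_condition=s.first_condition,
                )
                for s in default_cohort(schedule)
            ]
        return [
            SubjectSpec(
                subject_id=s.subject_id,
                normoxia=s.normoxia.to_params(),
                hypoxia=s.hypoxia.to_params(),
                schedule=schedule,
                first_condition=s.first_condition,
            )
            for s in self.cohort
        ]


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def dump_config(config: PipelineConfig, path: str | Path | None = None) -> str:
    text = yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
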