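"""Schema-validated pipeline configuration (YAML-backed, unknown keys rejected)."""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import List, Literal, Optional, Tuple

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .containers import BL, MA, ConfigurationError
from .simulate import (
    EffectSpec,
    HRFParams,
    NoiseSpec,
    ParadigmSpec,
    default_effect,
    null_effect,
    scaled_noise,
    strong_effect,
)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParadigmConfig(_Strict):
    n_runs_per_paradigm: int = 3
    reps_per_run: int = 20
    task_duration: float = 15.0
    rest_range: Tuple[float, float] = (20.0, 25.0)
    instruction_duration: float = 3.0
    lead_rest: float = 75.0
    trail_rest: float = 60.0
    fs: float = 15.6

    def to_spec(self, paradigm: str) -> ParadigmSpec:
        return ParadigmSpec(paradigm=paradigm, **self.model_dump())


class HRFConfig(_Strict):
    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    ratio: float = 6.0


class EffectConfig(_Strict):
    preset: Literal["default", "null", "strong"] = "default"
    strong_channel: int = 3
    hbo_amp_ma: Optional[List[float]] = None
    hbo_amp_bl: Optional[List[float]] = None
    hbr_amp_ma: Optional[List[float]] = None
    hbr_amp_bl: Optional[List[float]] = None
    trial_amplitude_jitter: Optional[float] = None
    hrf: HRFConfig = Field(default_factory=HRFConfig)

    def to_spec(self, n_channels: int) -> EffectSpec:
        if self.preset == "null":
            spec = null_effect(n_channels)
        elif self.preset == "strong":
            spec = strong_effect(n_channels, channel=self.strong_channel)
        else:
            spec = default_effect(n_channels)
        amps = {
            ("hbo_amp", MA): self.hbo_amp_ma, ("hbo_amp", BL): self.hbo_amp_bl,
            ("hbr_amp", MA): self.hbr_amp_ma, ("hbr_amp", BL): self.hbr_amp_bl,
        }
        for (attr, cond), values in amps.items():
            if values is not None:
                if len(values) != n_channels:
                    raise ConfigurationError(
                        f"{attr}[{cond}] must list {n_channels} channel amplitudes"
                    )
                getattr(spec, attr)[cond] = np.asarray(values, dtype=float)
        if self.trial_amplitude_jitter is not None:
            spec.trial_amplitude_jitter = self.trial_amplitude_jitter
        spec.hrf_params = HRFParams(**self.hrf.model_dump())
        return spec


class NoiseConfig(_Strict):
    scale: float = 1.0
    drift_amp: Optional[float] = None
    mayer_freq: Optional[float] = None
    mayer_amp: Optional[float] = None
    resp_freq: Optional[float] = None
    resp_amp: Optional[float] = None
    cardiac_freq: Optional[float] = None
    cardiac_amp: Optional[float] = None
    white_sd: Optional[float] = None

    def to_spec(self) -> NoiseSpec:
        spec = scaled_noise(self.scale)
        for name in ("drift_amp", "mayer_freq", "mayer_amp", "resp_freq",
                     "resp_amp", "cardiac_freq", "cardiac_amp", "white_sd"):
            value = getattr(self, name)
            if value is not None:
                setattr(spec, name, value)
        return spec


class FilterConfig(_Strict):
    order: int = 6
    band: Tuple[float, float] = (0.01, 0.2)
    stopband_attenuation: float = 40.0
    zero_phase: bool = True


class EpochConfig(_Strict):
    window: Tuple[float, float] = (-8.0, 25.0)
    baseline: Tuple[float, float] = (-2.0, 0.0)


class WindowConfig(_Strict):
    analysis_range: Tuple[float, float] = (-5.0, 25.0)
    width: float = 3.0
    step: float = 1.0
    slope_kind: Literal["ols", "endpoint"] = "ols"


class CVConfig(_Strict):
    n_folds: int = 5
    n_repeats: int = 10
    classifiers: List[Literal["lda", "svm"]] = Field(default_factory=lambda: ["lda", "svm"])
    chromo_sets: List[Literal["hbr", "hbo", "both"]] = Field(
        default_factory=lambda: ["hbr", "hbo", "both"]
    )
    svm_cost: float = 1.0
    inner_folds: Optional[int] = 5


class ReportConfig(_Strict):
    make_figures: bool = True
    peak_window: Tuple[float, float] = (9.0, 13.0)
    max_range: Tuple[float, float] = (5.0, 25.0)


class PipelineConfig(_Strict):
    """Full configuration of an end-to-end synthetic-cohort analysis."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    n_subjects: int = 2
    paradigms: List[Literal["EO", "EC"]] = Field(default_factory=lambda: ["EO", "EC"])
    write_snirf: bool = False
    paradigm: ParadigmConfig = Field(default_factory=ParadigmConfig)
    effect: EffectConfig = Field(default_factory=EffectConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    filter: FilterConfig = Field(default_factory=FilterConfig)
    epochs: EpochConfig = Field(default_factory=EpochConfig)
    windows: WindowConfig = Field(default_factory=WindowConfig)
    cv: CVConfig = Field(default_factory=CVConfig)
    report: ReportConfig = Field(default_factory=ReportConfig)

    @model_validator(mode="after")
    def _check_feasibility(self) -> "PipelineConfig":
        trials_per_class = self.paradigm.reps_per_run // 2 * self.paradigm.n_runs_per_paradigm
        if self.cv.n_folds > trials_per_class:
            raise ValueError(
                f"cv.n_folds={self.cv.n_folds} exceeds trials per class "
                f"({trials_per_class}); reduce folds or add trials"
            )
        lo, hi = self.epochs.window
        if self.windows.analysis_range[0] - self.windows.width < lo - 1e-9:
            raise ValueError("epoch window too short for the first feature window")
        if self.windows.analysis_range[1] > hi + 1e-9:
            raise ValueError("epoch window too short for the last feature window")
        if not (lo <= self.epochs.baseline[0] < self.epochs.baseline[1] <= hi):
            raise ValueError("baseline interval must lie inside the epoch window")
        return self

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path: Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)

    def digest(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
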