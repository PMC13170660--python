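"""Pipeline configuration: validated parameters, TOML round-trip.

A :class:`PipelineConfig` collects the tunables of every stage, validated
against the stages' preconditions at load time via pydantic.  Configs are
stored as TOML (one section per stage) and round-trip read→write→read
identically.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from pydantic import BaseModel, Field, field_validator

from .exceptions import FormatError

__all__ = ["PipelineConfig", "load_config", "save_config"]


class TraceParams(BaseModel):
    window_s: float = Field(60.0, gt=0)


class DetectionParams(BaseModel):
    similarity_threshold: float = Field(0.75, ge=-1.0, le=1.0)
    min_amplitude: float = Field(0.01, ge=0.0)
    rise_taus: list[float] = [0.05, 0.1, 0.2]
    decay_taus: list[float] = [0.3, 0.6, 1.2]
    template_len_s: float = Field(3.0, gt=0)

    @field_validator("rise_taus", "decay_taus")
    @classmethod
    def _positive(cls, v):
        if not v or any(x <= 0 for x in v):
            raise ValueError("taus must be positive and non-empty")
        return v


class SimulationParams(BaseModel):
    duration_s: float = Field(180.0, gt=0)
    sampling_rate: float = Field(8.0, gt=0)
    n_neurons: int = Field(50, ge=1)
    rate_mean: float = Field(1.0 / 30.0, ge=0)  # events/s (= 2 spikes/min)
    rate_sigma: float = Field(0.5, ge=0)
    baseline_F: float = Field(100.0, gt=0)
    noise_sd: float = Field(2.0, ge=0)
    bleach_rate: float = Field(0.0, ge=0)
    kernel_rise_tau: float = Field(0.1, gt=0)
    kernel_decay_tau: float = Field(0.6, gt=0)
    kernel_amplitude: float = Field(0.5, gt=0)


class SegmentationParams(BaseModel):
    smoothing_sigma: float = Field(1.0, ge=0)
    threshold_method: str = "otsu"
    min_area_px: int = Field(2, ge=1)
    nucleus_min_area_px: int = Field(20, ge=1)


class BindingParams(BaseModel):
    variant: str = "one_site"
    concentration_unit: str = "ug/ml"


class PipelineConfig(BaseModel):
    master_seed: int = 0
    log_level: str = "INFO"
    traces: TraceParams = TraceParams()
    detection: DetectionParams = DetectionParams()
    simulation: SimulationParams = SimulationParams()
    segmentation: SegmentationParams = SegmentationParams()
    binding: BindingParams = BindingParams()


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, list):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise FormatError(f"cannot serialize {type(v)} to TOML")


def save_config(config: PipelineConfig, path) -> None:
    lines = []
    data = config.model_dump()
    for key, val in data.items():
        if not isinstance(val, dict):
            lines.append(f"{key} = {_toml_value(val)}")
    for section, val in data.items():
        if isinstance(val, dict):
            lines.append(f"\n[{section}]")
            for k, v in val.items():
                lines.append(f"{k} = {_toml_value(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path) -> PipelineConfig:
    path = Path(path)
    try:
        data = tomllib.loads(path.read_text())
    except tomllib.TOMLDecodeError as exc:
        raise FormatError(f"{path.name}: invalid TOML: {exc}") from exc
    try:
        return PipelineConfig(**data)
    except ValueError as exc:
        raise FormatError(f"{path.name}: invalid configuration: {exc}") from exc
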