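"""Run configuration: schema-validated YAML/JSON describing a full analysis.

Every stochastic stage carries its own integer seed; a configuration is
rejected if any seed is missing, so a run is reproducible end to end.  The
``"vlbw-vancomycin"`` model preset holds the package's reference estimates.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .cohort import CohortSpec, SamplingDesign
from .dosing import DOSE_GRID, INTERVAL_GRID, TargetPolicy
from .errors import ConfigurationError
from .model import PopulationModel, Regimen

__all__ = ["RunConfig", "MODEL_PRESETS", "load_config", "save_config", "default_config"]

#: Named fixed-effect/variability presets.
MODEL_PRESETS: dict[str, dict] = {
    "vlbw-vancomycin": {},  # dataclass defaults ARE the reference estimates
}


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n: int = 236
    seed: int = 101
    overrides: dict = Field(default_factory=dict)

    def build(self) -> CohortSpec:
        return CohortSpec(n=self.n, seed=self.seed, **self.overrides)


class SamplingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 202
    reference: Literal["neofax", "lexicomp_age", "lexicomp_renal"] = "neofax"
    second_trough_fraction: float = 0.32
    peak_fraction: float = 0.10
    lloq: Optional[float] = None

    def build(self) -> SamplingDesign:
        return SamplingDesign(
            second_trough_fraction=self.second_trough_fraction,
            peak_fraction=self.peak_fraction,
            lloq=self.lloq,
        )


class ModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    preset: str = "vlbw-vancomycin"
    overrides: dict = Field(default_factory=dict)

    @field_validator("preset")
    @classmethod
    def _known(cls, v: str) -> str:
        if v not in MODEL_PRESETS:
            raise ValueError(f"unknown model preset {v!r}")
        return v

    def build(self) -> PopulationModel:
        return PopulationModel(**{**MODEL_PRESETS[self.preset], **self.overrides})


class EstimationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 303
    include_scr: bool = True
    include_maturation: bool = True
    error_model: Literal["proportional", "constant", "combined"] = "proportional"
    maxfev: Optional[int] = None
    rse_method: Literal["bootstrap", "fisher", "none"] = "none"
    n_boot: int = 40


class DiagnosticsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 404
    n_sim_vpc: int = 1000
    n_sim_npde: int = 1000


class DoseSimConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 505
    replicate: int = 40
    doses: list[float] = Field(default_factory=lambda: list(DOSE_GRID))
    intervals: list[float] = Field(default_factory=lambda: list(INTERVAL_GRID))
    infusion_duration: float = 1.0
    metric: Literal["initiation", "steady_state"] = "initiation"
    use_model: Literal["fitted", "preset"] = "fitted"

    def grid(self) -> list[Regimen]:
        return [
            Regimen(dose_per_kg=d, interval=i, infusion_duration=self.infusion_duration)
            for d in self.doses
            for i in self.intervals
        ]


class PolicyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    target: Literal["narrow", "wide"] = "narrow"
    efficacy_floor: Optional[float] = None
    toxicity_cap: float = 10.0

    def build(self) -> TargetPolicy:
        band = (400.0, 600.0) if self.target == "narrow" else (400.0, 800.0)
        floor = self.efficacy_floor
        if floor is None:
            floor = 60.0 if self.target == "narrow" else 80.0
        return TargetPolicy(auc_band=band, efficacy_floor=floor,
                            toxicity_cap=self.toxicity_cap)


class RunConfig(BaseModel):
    """Top-level pipeline configuration (round-trips losslessly)."""

    model_config = ConfigDict(extra="forbid")
    name: str = "vlbw-vancomycin-analysis"
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    sampling: SamplingConfig = Field(default_factory=SamplingConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    estimation: EstimationConfig = Field(default_factory=EstimationConfig)
    diagnostics: DiagnosticsConfig = Field(default_factory=DiagnosticsConfig)
    dose_sim: DoseSimConfig = Field(default_factory=DoseSimConfig)
    policy: PolicyConfig = Field(default_factory=PolicyConfig)
    split_fraction: float = 0.7
    split_seed: int = 606

    @field_validator("split_fraction")
    @classmethod
    def _frac(cls, v: float) -> float:
        if not 0 < v < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        return v


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path) -> RunConfig:
    """Load a YAML or JSON run configuration, validating the schema."""
    path = Path(path)
    text = path.read_text()
    try:
        payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    return RunConfig.model_validate(payload)


def save_config(config: RunConfig, path) -> None:
    path = Path(path)
    payload = config.model_dump(mode="json")
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
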