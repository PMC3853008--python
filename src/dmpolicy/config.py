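"""Run configuration: validated schema, YAML loading, hashing."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .parameters import (
    DIAGNOSED_SHARE_DEFAULT,
    EpidemiologicParameters,
    PrevalenceInputs,
)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParametersBlock(_Strict):
    lambda_normal: float = 0.003
    lambda_ifg: float = 0.024
    lambda_ifgigt: float = 0.039
    rr_undiag: float = 1.77
    rr_diag: float = 2.11
    incidence_growth: float = 1.0


class AnchorsBlock(_Strict):
    years: list[int] = [2007, 2010, 2015, 2020, 2025, 2030]
    prevalence_millions: list[float] = [27.8, 33.1, 41.2, 48.7, 55.3, 60.7]
    prevalence_rates: list[float] = [0.129, 0.148, 0.175, 0.197, 0.215, 0.227]
    cumulative_incidence_millions: list[float] = [2.3, 6.8, 17.9, 29.1, 40.3, 51.7]

    @field_validator("prevalence_rates")
    @classmethod
    def _rates_in_unit_interval(cls, v):
        if any(not 0 < r < 1 for r in v):
            raise ValueError("prevalence rates must lie in (0, 1)")
        return v


class CalibrationBlock(_Strict):
    anchors: AnchorsBlock = Field(default_factory=AnchorsBlock)
    diagnosed_share_of_dm: float = DIAGNOSED_SHARE_DEFAULT
    prevalence_dm_2007: float = 0.129
    prevalence_ifg_any_2007: float = 0.267
    prevalence_ifg_igt_2007: float = 0.083


class ScenarioBlock(_Strict):
    name: str
    targeted_effectiveness: float = 0.125
    population_effectiveness: float = 0.02


class SensitivityBlock(_Strict):
    targeted_grid: list[float] = [0.0625, 0.125, 0.25]
    population_grid: list[float] = [0.01, 0.02, 0.04]
    background_rate_increase_pp: float = 3.5


class EmulatorBlock(_Strict):
    grid_size: int = 5
    spread: float = 2.0
    n_samples: int = 10_000
    seed: int = 0


class RunConfig(_Strict):
    parameters: ParametersBlock = Field(default_factory=ParametersBlock)
    calibration: CalibrationBlock = Field(default_factory=CalibrationBlock)
    scenarios: list[ScenarioBlock] = Field(
        default_factory=lambda: [
            ScenarioBlock(name=n)
            for n in ("none", "high_risk", "moderate_risk", "population", "combined")
        ]
    )
    end_year: int = 2030
    sensitivity: SensitivityBlock = Field(default_factory=SensitivityBlock)
    emulator: EmulatorBlock | None = Field(default_factory=EmulatorBlock)
    output_dir: str = "results"

    def content_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = self.model_dump()
        payload.pop("output_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]

    def epidemiologic_parameters(self) -> EpidemiologicParameters:
        p = self.parameters
        return EpidemiologicParameters(
            lambda_normal=p.lambda_normal,
            lambda_ifg=p.lambda_ifg,
            lambda_ifgigt=p.lambda_ifgigt,
            rr_undiag=p.rr_undiag,
            rr_diag=p.rr_diag,
            incidence_growth=p.incidence_growth,
        )

    def prevalence_inputs(self) -> PrevalenceInputs:
        c = self.calibration
        return PrevalenceInputs(
            total_dm_rate=c.prevalence_dm_2007,
            ifg_rate_any=c.prevalence_ifg_any_2007,
            ifg_igt_rate=c.prevalence_ifg_igt_2007,
            diagnosed_share_of_dm=c.diagnosed_share_of_dm,
        )


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config; defaults when no path is given."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)
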