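"""Flat, validated run configuration.

A :class:`RunConfig` mirrors the simulation parameters and experiment
design as one human-editable document (YAML file and/or CLI flags; CLI
flags win). Unknown keys are rejected outright — a typo never silently
falls back to a default — and every default equals the reference study
conditions: 51 x 51 grid, mutation probability 1e-3, reproduction
probability 0.9, 1000-step recording window, transfer coefficients
{0, 0.5, 1}, doses {1, 0.75, 0.5}, 10 replicates.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .cells import CellRates
from .engine import SimulationParams
from .experiment import ExperimentDesign
from .lattice import LatticeConfig

__all__ = ["RunConfig", "parse_config", "ConfigError"]


class ConfigError(ValueError):
    pass


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    width: int = Field(51, ge=1)
    height: int = Field(51, ge=1)
    transfer_coefficient: float = Field(1.0, ge=0.0, le=1.0)
    dose: float = Field(1.0, ge=0.0, le=1.0)
    transfer_values: tuple[float, ...] = (0.0, 0.5, 1.0)
    dose_values: tuple[float, ...] = (1.0, 0.75, 0.5)
    replicates: int = Field(10, ge=1)
    seed: int = 0
    reproduction_probability: float = Field(0.90, ge=0.0, le=1.0)
    mutation_probability: float = Field(1e-3, ge=0.0, le=1.0)
    release_amount: float = Field(1.0, gt=0.0)
    resistance_cost: float = Field(0.0, ge=0.0)
    record_window: int = Field(1000, ge=1)
    max_burn_in: int = Field(100_000, ge=1)
    field_persistence: float = Field(0.0, ge=0.0, le=1.0)
    time_step_minutes: float = Field(40.0, gt=0.0)
    output_directory: str = "out"
    log_level: str = Field("info", pattern="^(debug|info|warning)$")

    def rates(self) -> CellRates:
        return CellRates(
            reproduction_probability=self.reproduction_probability,
            mutation_probability=self.mutation_probability,
            release_amount=self.release_amount,
            resistance_cost=self.resistance_cost,
        )

    def simulation_params(self) -> SimulationParams:
        return SimulationParams(
            lattice=LatticeConfig(width=self.width, height=self.height),
            transfer_coefficient=self.transfer_coefficient,
            dose=self.dose,
            rates=self.rates(),
            record_window=self.record_window,
            max_burn_in=self.max_burn_in,
            field_persistence=self.field_persistence,
            seed=self.seed,
            time_step_minutes=self.time_step_minutes,
        )

    def experiment_design(self) -> ExperimentDesign:
        return ExperimentDesign(
            transfer_values=tuple(self.transfer_values),
            dose_values=tuple(self.dose_values),
            replicates=self.replicates,
            base_seed=self.seed,
            params_template=self.simulation_params(),
        )

    def echo(self, directory: Path) -> Path:
        """Write the effective configuration (with the code version)
        into the output directory for provenance."""
        directory.mkdir(parents=True, exist_ok=True)
        path = directory / "config.json"
        doc = self.model_dump()
        doc["pubgoodsim_version"] = __version__
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
        return path


def parse_config(
    file: Optional[str | Path] = None, overrides: Optional[dict] = None
) -> RunConfig:
    """Build a validated config from an optional YAML file plus
    overrides (typically CLI flags; ``None`` values are ignored)."""
    doc: dict = {}
    if file is not None:
        loaded = yaml.safe_load(Path(file).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {file} must contain a mapping")
        doc.update(loaded)
    for key, value in (overrides or {}).items():
        if value is not None:
            doc[key] = value
    try:
        return RunConfig(**doc)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
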