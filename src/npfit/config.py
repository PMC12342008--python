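"""Run configuration: a strict, round-trippable YAML schema.

Every stage of the tool (cohort generation, sensitivity analysis, cohort
fitting, evaluation) reads one :class:`RunConfig`.  Unknown keys are
rejected by name, omitted optional keys fall back to documented defaults,
and ``save_config(load_config(p))`` is the identity on every field.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any, Mapping

import yaml

from .engine import EngineConfig
from .pipeline import PipelineConfig
from .surrogate import (
    DEFAULT_BIOMARKERS,
    DEFAULT_FIT_PARAMS,
    DEFAULT_GRID,
    DEFAULT_REFERENCE,
    SimulatorSpec,
)

__all__ = ["ConfigError", "CohortConfig", "SensitivityConfig", "RunConfig", "load_config", "save_config"]


class ConfigError(ValueError):
    """Malformed run configuration."""


@dataclass(frozen=True)
class CohortConfig:
    """Synthetic-cohort generation settings (defaults: study conditions)."""

    n_patients: int = 20
    pop_scale: float = 0.35
    biomarker_dropout: float = 0.2
    timepoint_dropout: float = 0.2
    noise_scale_range: tuple[float, float] = (0.05, 0.2)

    def __post_init__(self) -> None:
        object.__setattr__(self, "noise_scale_range", tuple(self.noise_scale_range))
        if self.n_patients < 1:
            raise ConfigError("cohort.n_patients must be >= 1")
        if self.pop_scale < 0:
            raise ConfigError("cohort.pop_scale must be >= 0")


@dataclass(frozen=True)
class SensitivityConfig:
    range_fraction: float = 0.3
    n_base: int = 1024
    output_weeks: tuple[float, ...] = (4.0, 12.0, 24.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "output_weeks", tuple(self.output_weeks))
        if not 0 < self.range_fraction < 1:
            raise ConfigError("sensitivity.range_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration for every CLI stage."""

    simulator: SimulatorSpec = field(default_factory=SimulatorSpec)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    sensitivity: SensitivityConfig = field(default_factory=SensitivityConfig)
    seed: int = 0


_SECTION_FIELDS: dict[str, tuple[type, tuple[str, ...]]] = {
    "simulator": (SimulatorSpec, ("parameter_names", "reference", "biomarker_names", "observation_grid", "solver_abs_tol", "solver_rel_tol")),
    "cohort": (CohortConfig, ("n_patients", "pop_scale", "biomarker_dropout", "timepoint_dropout", "noise_scale_range")),
    "sensitivity": (SensitivityConfig, ("range_fraction", "n_base", "output_weeks")),
}
_PIPELINE_FIELDS = ("mode", "batch_size", "engine", "prior_scale", "noise_loc", "n_posterior_samples", "fit_names", "seed")
_ENGINE_FIELDS = (
    "n_rounds",
    "n_sims_per_round",
    "n_atoms",
    "density_estimator",
    "hidden_units",
    "seed",
    "learning_rate",
    "max_epochs",
    "patience",
    "train_batch_size",
    "val_fraction",
)


def _check_keys(section: str, data: Mapping[str, Any], allowed: tuple[str, ...]) -> None:
    unknown = sorted(set(data) - set(allowed))
    if unknown:
        raise ConfigError(f"unknown key(s) in {section}: {', '.join(unknown)}")


def _tupled(value: Any) -> Any:
    return tuple(value) if isinstance(value, list) else value


def load_config(path: str) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys("config", raw, ("simulator", "cohort", "pipeline", "sensitivity", "seed"))
    try:
        kwargs: dict[str, Any] = {}
        for section, (cls, allowed) in _SECTION_FIELDS.items():
            data = raw.get(section, {})
            _check_keys(section, data, allowed)
            kwargs[section] = cls(**{k: _tupled(v) for k, v in data.items()})
        pdata = dict(raw.get("pipeline", {}))
        _check_keys("pipeline", pdata, _PIPELINE_FIELDS)
        edata = pdata.pop("engine", {})
        _check_keys("pipeline.engine", edata, _ENGINE_FIELDS)
        pdata = {k: _tupled(v) for k, v in pdata.items()}
        kwargs["pipeline"] = PipelineConfig(engine=EngineConfig(**edata), **pdata)
        kwargs["seed"] = int(raw.get("seed", 0))
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def save_config(config: RunConfig, path: str) -> None:
    """Serialize a run configuration to YAML (lossless round trip)."""
    data = {
        "simulator": asdict(config.simulator),
        "cohort": asdict(config.cohort),
        "pipeline": asdict(config.pipeline),
        "sensitivity": asdict(config.sensitivity),
        "seed": config.seed,
    }

    def _listify(obj: Any) -> Any:
        if isinstance(obj, tuple):
            return [_listify(v) for v in obj]
        if isinstance(obj, list):
            return [_listify(v) for v in obj]
        if isinstance(obj, dict):
            return {k: _listify(v) for k, v in obj.items()}
        return obj

    with open(path, "w") as handle:
        yaml.safe_dump(_listify(data), handle, sort_keys=False)


def default_config() -> RunConfig:
    """All-defaults configuration (documented on the dataclasses)."""
    return RunConfig()


# re-exported so a config file can be written from scratch programmatically
DEFAULTS = {
    "reference": DEFAULT_REFERENCE,
    "biomarkers": DEFAULT_BIOMARKERS,
    "grid": DEFAULT_GRID,
    "fit_names": DEFAULT_FIT_PARAMS,
}
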