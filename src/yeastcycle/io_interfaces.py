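"""Run configuration, provenance logging and format interfaces.

A run is described by a single YAML file (times in minutes, abundances in
molecules/cell) that round-trips losslessly through
:func:`load_config`/:func:`save_config`.  SBML import/export lives in
:mod:`yeastcycle._sbml` and is re-exported here.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field

import yaml

from ._sbml import SBMLError, export_sbml, import_sbml, structural_report
from .model_core import ModelDefinition, build_reference_model
from .perturbation import SignalSchedule
from .simulation import IntegratorSettings, read_trajectory_csv

__all__ = [
    "RunConfig", "load_config", "save_config", "build_model_from_config",
    "import_sbml", "export_sbml", "structural_report", "SBMLError",
    "read_trajectory_csv", "model_checksum", "log_run",
]

logger = logging.getLogger("yeastcycle")


@dataclass(frozen=True)
class RunConfig:
    """Complete description of a simulation run."""

    model_source: str = "native"          # "native" or a path to an SBML file
    pheromone_intervals: tuple[tuple[float, float], ...] = ()
    osmostress_intervals: tuple[tuple[float, float], ...] = ()
    nutrition_factor: float = 1.0
    t_end: float = 1220.0
    output_step: float = 0.5
    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10
    experiment: str | None = None
    experiment_options: dict = field(default_factory=dict)
    output_dir: str = "."

    def schedule(self) -> SignalSchedule:
        return SignalSchedule(
            pheromone_intervals=self.pheromone_intervals,
            osmostress_intervals=self.osmostress_intervals,
            nutrition_factor=self.nutrition_factor,
        )

    def integrator(self) -> IntegratorSettings:
        return IntegratorSettings(method=self.method, rtol=self.rtol,
                                  atol=self.atol)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pheromone_intervals"] = [list(i) for i in self.pheromone_intervals]
        d["osmostress_intervals"] = [list(i) for i in self.osmostress_intervals]
        return d


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as handle:
        raw = yaml.safe_load(handle) or {}
    unknown = set(raw) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("pheromone_intervals", "osmostress_intervals"):
        if key in raw:
            raw[key] = tuple(tuple(map(float, pair)) for pair in raw[key])
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(config.to_dict(), handle, sort_keys=False)


def build_model_from_config(config: RunConfig) -> ModelDefinition:
    if config.model_source == "native":
        return build_reference_model()
    return import_sbml(config.model_source)


def model_checksum(model: ModelDefinition) -> str:
    """Stable digest of the model structure, parameters and initial state."""
    h = hashlib.sha256()
    for entry in model.inventory.entries:
        h.update(repr((entry.name, entry.role, entry.pools)).encode())
    for name in model.parameter_order:
        h.update(f"{name}={model.parameters[name]:.17g};".encode())
    for reaction in model.rate_laws:
        h.update(repr((reaction.name, sorted(reaction.stoichiometry.items()),
                       reaction.rate)).encode())
    h.update(model.initial_state.tobytes())
    return h.hexdigest()[:16]


def log_run(config: RunConfig, model: ModelDefinition) -> None:
    """Record settings, model checksum and event times for provenance."""
    from . import __version__

    logger.info("yeastcycle %s", __version__)
    logger.info("model %s checksum %s", config.model_source,
                model_checksum(model))
    logger.info("integrator %s rtol=%g atol=%g output_step=%g",
                config.method, config.rtol, config.atol, config.output_step)
    schedule = config.schedule()
    logger.info("events: %s",
                schedule.switch_times(0.0, config.t_end) or "none")
    logger.info("nutrition factor %g", config.nutrition_factor)
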