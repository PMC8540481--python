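"""Run configuration: validated loading of user config files.

A single YAML or JSON file describes a whole run — targets, instrument
constraints, capillary geometry, fluid, synthetic-detector models, noise,
replicates and seed.  Unknown keys are rejected by name so typos fail
loudly instead of silently falling back to defaults.

Documented keys (all optional; defaults are the reference method)::

    vial: pcr | nano
    targets: [6.25, 12.5, ...]        # µg/mL
    stock: 100.0                      # µg/mL
    include_undiluted: true           # add the stock as top calibrator
    mode: R | F
    replicates: 3
    seed: 42
    constraints: {p_min, p_max, p_quantum, t_default, t_max, t_quantum}
    geometry: {total_length_cm, effective_length_cm, id_um}
    fluid: {viscosity_mpas, name}
    noise: {area_cv, migration_drift_cv, baseline_sd}
    analytes: [{name, migration_time_min, response_factor,
                peak_width_sigma_min}, ...]
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from . import profiles
from .physics import CapillaryGeometry, Fluid
from .scheduler import InstrumentConstraints
from .simulate import AnalyteModel, NoiseModel

__all__ = ["ConfigError", "RunConfig"]


class ConfigError(ValueError):
    """A configuration file failed validation."""


def _check_keys(section: str, data: dict, allowed: set[str]) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {section}: {', '.join(sorted(unknown))}"
        )


def _build(section: str, cls, data: dict, allowed: set[str]):
    _check_keys(section, data, allowed)
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {section}: {exc}") from exc


@dataclass(frozen=True)
class RunConfig:
    """Everything an end-to-end run needs, validated on construction."""

    vial: str = "pcr"
    targets: tuple[float, ...] = profiles.CALIBRATION_TARGETS
    stock: float = profiles.STOCK_CONCENTRATION
    include_undiluted: bool = True
    mode: str = "R"
    replicates: int = 3
    seed: int = 42
    constraints: InstrumentConstraints | None = None
    geometry: CapillaryGeometry = profiles.REFERENCE_GEOMETRY
    fluid: Fluid = profiles.WATER
    noise: NoiseModel = profiles.DEFAULT_NOISE
    analytes: tuple[AnalyteModel, ...] = profiles.DEFAULT_ANALYTES

    def __post_init__(self) -> None:
        if self.vial not in ("pcr", "nano"):
            raise ConfigError(f"vial must be 'pcr' or 'nano', got {self.vial!r}")
        if self.mode not in ("R", "F"):
            raise ConfigError(f"mode must be 'R' or 'F', got {self.mode!r}")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if not self.targets:
            raise ConfigError("targets must be non-empty")

    @property
    def effective_constraints(self) -> InstrumentConstraints:
        return self.constraints or profiles.constraints_for_vial(self.vial)

    @property
    def budget(self) -> float:
        return profiles.budget_for_vial(self.vial)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        _check_keys("config", data, {f.name for f in fields(cls)})
        if "constraints" in data:
            data["constraints"] = _build(
                "constraints", InstrumentConstraints, data["constraints"],
                {"p_min", "p_max", "p_quantum", "t_default", "t_max", "t_quantum"},
            )
        if "geometry" in data:
            _check_keys(
                "geometry", data["geometry"],
                {"total_length_cm", "effective_length_cm", "id_um"},
            )
            try:
                data["geometry"] = CapillaryGeometry.from_cm_um(**data["geometry"])
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid geometry: {exc}") from exc
        if "fluid" in data:
            _check_keys("fluid", data["fluid"], {"viscosity_mpas", "name"})
            try:
                data["fluid"] = Fluid.from_mpas(**data["fluid"])
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid fluid: {exc}") from exc
        if "noise" in data:
            data["noise"] = _build(
                "noise", NoiseModel, data["noise"],
                {"area_cv", "migration_drift_cv", "baseline_sd", "seed"},
            )
        if "analytes" in data:
            data["analytes"] = tuple(
                _build(
                    "analyte", AnalyteModel, a,
                    {"name", "migration_time_min", "response_factor",
                     "peak_width_sigma_min"},
                )
                for a in data["analytes"]
            )
        if "targets" in data:
            data["targets"] = tuple(float(t) for t in data["targets"])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_file(cls, path: "str | Path") -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"{path} does not contain a mapping")
        return cls.from_dict(data)
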