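"""Configuration schema, defaults and YAML/JSON loading.

All tunable parameters of the simulator live in four sections -- ``plant``,
``hardware``, ``controller``, ``supervisor`` -- plus an optional
``scenario`` section.  Files are validated with pydantic: unknown or
ill-typed keys fail loudly with the offending key named.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Any

import yaml
from pydantic import TypeAdapter

from .control import ControllerConfig
from .exchange import CarrierChemistry, LungConfig
from .hardware import BlowerConfig, SensorConfig
from .supervisor import SupervisorConfig


@dataclass(frozen=True)
class PlantConfig:
    """Physical parameters of the test circuit.

    ``beta`` and ``gas_resistance_tall`` are the two calibrated plant
    constants: the resistance (with the blower source pressure) sets the
    7 L/min tall-lung sweep ceiling, and ``beta`` sets where in the sweep
    range each EGCO2 operating point falls.
    """

    volume_l: float = 18.93              # 5 US gallon reservoir
    alpha_water: float = 0.03            # mmol/(L*mmHg)
    blood_k1: float = 2.2
    blood_k2: float = 0.40
    beta: float = 0.8                   # L/min, AL gas-side equilibration
    gas_resistance_tall: float = 10.0    # mmHg/(L/min)
    lung_variant: str = "tall"
    efficiency_conditioning: float = 0.5
    dead_volume_l: float = 0.05
    ambient_mmhg: float = 760.0
    temp_k: float = 310.0
    dt_s: float = 0.1                    # integration step

    def chem(self) -> CarrierChemistry:
        return CarrierChemistry(alpha_water=self.alpha_water,
                                blood_k1=self.blood_k1,
                                blood_k2=self.blood_k2)

    def lung(self) -> LungConfig:
        r = self.gas_resistance_tall
        if self.lung_variant == "short":
            r = r / 2.0     # short lung: half the gas-side resistance
        return LungConfig(variant=self.lung_variant, gas_resistance=r,
                          beta=self.beta, dead_volume=self.dead_volume_l)


@dataclass(frozen=True)
class SimSetup:
    """Everything but the scenario: plant, actuators, sensors, supervisor."""

    plant: PlantConfig = field(default_factory=PlantConfig)
    blower: BlowerConfig = field(default_factory=BlowerConfig)
    sensor: SensorConfig = field(default_factory=SensorConfig)
    supervisor: SupervisorConfig = field(default_factory=SupervisorConfig)


_SECTION_TYPES: dict[str, Any] = {
    "plant": PlantConfig,
    "blower": BlowerConfig,
    "sensor": SensorConfig,
    "supervisor": SupervisorConfig,
    "controller": ControllerConfig,
}


def _validate(cls, raw: Any):
    """Validate ``raw`` into ``cls``; unknown keys fail loudly by name."""
    if isinstance(raw, dict):
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(
                f"unknown key(s) {sorted(unknown)} in section "
                f"{cls.__name__}; valid keys: {sorted(known)}")
    return TypeAdapter(cls).validate_python(raw)


def build_setup(raw: dict[str, Any]) -> SimSetup:
    """Validate a nested dict (parsed YAML/JSON) into a :class:`SimSetup`."""
    kwargs = {}
    hardware = raw.get("hardware", {})
    sections = dict(raw)
    # Accept either a flat `hardware:` holding blower+sensor or separate keys.
    if hardware:
        sections.setdefault("blower", hardware.get("blower", {}))
        sections.setdefault("sensor", hardware.get("sensor", {}))
    for name in ("plant", "blower", "sensor", "supervisor"):
        cls = _SECTION_TYPES[name]
        kwargs[name] = _validate(cls, sections.get(name, {}))
    return SimSetup(**kwargs)


def build_controller(raw: dict[str, Any]) -> ControllerConfig:
    return _validate(ControllerConfig, raw)


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a YAML or JSON config file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".json"}:
        return json.loads(text)
    return yaml.safe_load(text) or {}


def setup_to_dict(setup: SimSetup,
                  controller: ControllerConfig | None = None
                  ) -> dict[str, Any]:
    """Fully-materialized config dict (for the provenance sidecar)."""
    out = {
        "plant": asdict(setup.plant),
        "blower": asdict(setup.blower),
        "sensor": asdict(setup.sensor),
        "supervisor": asdict(setup.supervisor),
    }
    if controller is not None:
        d = asdict(controller)
        d["mode"] = str(d["mode"].value if hasattr(d["mode"], "value")
                        else d["mode"])
        out["controller"] = d
    return out
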