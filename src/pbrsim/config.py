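"""Simulation configuration: TOML sections, validation, defaults, round-trip.

An empty file (or no file) yields the default configuration, which is the
Almería pilot plant: 400 m × 0.09 m loop, 3.5 m × 0.4 m bubble column,
0.9 m/s culture velocity, 80 L/min air, manual CO2 control.  Unknown keys
are rejected with an error naming the key and section.
"""

from __future__ import annotations

import tomllib
from typing import List, Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError


class ConfigError(ValueError):
    """A configuration file failed validation."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SimulationSection(_Section):
    duration_days: float = Field(1.0, gt=0)
    dt_s: float = Field(1.0, gt=0)
    start_day: int = Field(172, ge=1, le=365)
    output_stride: int = Field(60, ge=1)
    random_seed: int = 0


class GeometrySection(_Section):
    tube_length_m: float = Field(400.0, gt=0)
    tube_diameter_m: float = Field(0.09, gt=0)
    column_height_m: float = Field(3.5, gt=0)
    column_diameter_m: float = Field(0.4, gt=0)
    n_elements: int = Field(50, ge=1)
    liquid_fraction_column: float = Field(0.9, gt=0, le=1)


class KineticsSection(_Section):
    r_o2_max: float = Field(4.2e-6, gt=0)
    i_half_Wm2: float = Field(150.0, gt=0)
    hill_n: float = Field(1.8, gt=0)
    o2_inhibition_mol_m3: float = Field(1.2, gt=0)
    inhibition_exponent: float = Field(4.0, gt=0)
    c_half_mol_m3: float = Field(1.2, gt=0)
    extinction_m2_g: float = Field(0.06, gt=0)
    yield_g_per_mol_o2: float = Field(26.0, gt=0)
    photosynthetic_quotient: float = Field(1.0, gt=0)
    respiration_mol_g_s: float = Field(2.0e-8, ge=0)
    dark_biomass_decay: bool = False


class ChemistrySection(_Section):
    k1_mol_m3: float = Field(4.467e-4, gt=0)
    k2_mol_m3: float = Field(4.677e-8, gt=0)
    kw_mol2_m6: float = Field(1.0e-8, gt=0)
    alkalinity_mol_m3: float = Field(2.5, ge=0)
    henry_o2: float = Field(1.23, gt=0)
    henry_co2: float = Field(34.0, gt=0)
    kla_o2_per_s: float = Field(0.02, ge=0)
    kla_co2_per_s: float = Field(0.04, ge=0)


class ThermalSection(_Section):
    u_wall_W_m2K: float = Field(15.0, gt=0)
    absorptivity: float = Field(0.35, ge=0, le=1)
    hx_UA_W_K: float = Field(2000.0, gt=0)
    n_thermal_volumes: Optional[int] = Field(None, ge=1)  # None = same as n_elements
    cooling_water_inlet_C: float = 15.0
    cooling_max_flow_kg_s: float = Field(0.5, gt=0)
    ambient_mean_C: float = 22.0
    ambient_amplitude_C: float = 6.0
    ambient_peak_hour: float = 15.0


class OperationSection(_Section):
    velocity_m_s: float = Field(0.9, ge=0)
    air_flow_L_min: float = Field(80.0, ge=0)
    co2_max_flow_L_min: float = Field(5.0, gt=0)
    co2_absorption_efficiency: float = Field(1.0, gt=0, le=1)
    initial_biomass_g_m3: float = Field(1000.0, ge=0)
    initial_ph: float = Field(8.0, gt=2, lt=12)
    initial_do2_mol_m3: float = Field(0.258, ge=0)
    initial_temperature_C: float = 22.0
    column_light_factor: float = Field(0.0, ge=0, le=1)


class EnvironmentSection(_Section):
    latitude: float = Field(36.8, ge=-90, le=90)
    longitude: float = Field(-2.4, ge=-180, le=180)
    clearness_index: float = Field(0.8, ge=0, le=1)
    profile_csv: Optional[str] = None  # recorded forcing instead of the model


class LoopControlSection(_Section):
    mode: Literal["manual", "onoff", "pi_time", "pi_event"] = "manual"
    setpoint: float = 0.0
    manual_value: float = 0.0  # command units in [0, 1]
    kp: float = 1.0
    ti_s: float = Field(100.0, gt=0)
    ts_s: float = Field(30.0, gt=0)
    delta: float = Field(0.05, gt=0)
    hysteresis: float = Field(0.0, ge=0)
    direction: Literal[-1, 1] = 1
    # manual-mode schedule [[time_h, physical value], ...] (pH loop: L/min CO2)
    schedule: Optional[List[List[float]]] = None
    actuator_gain: Optional[float] = None  # None = loop-specific default
    actuator_tau_s: float = Field(2.0, ge=0)


def _default_ph_loop() -> LoopControlSection:
    return LoopControlSection(
        mode="manual", setpoint=7.5, manual_value=0.6,  # 0.6*5 = 3 L/min rotameter
        kp=-1.0, ti_s=600.0, ts_s=900.0, delta=0.03, hysteresis=0.1, direction=1,
        actuator_tau_s=2.0,
    )


def _default_velocity_loop() -> LoopControlSection:
    return LoopControlSection(
        mode="manual", setpoint=0.9, manual_value=0.9,  # gain 1 m/s per command
        kp=1.0, ti_s=20.0, ts_s=1.0, delta=0.02, hysteresis=0.02, direction=-1,
        actuator_tau_s=5.0,
    )


def _default_temperature_loop() -> LoopControlSection:
    return LoopControlSection(
        mode="manual", setpoint=25.0, manual_value=0.0,
        kp=0.2, ti_s=900.0, ts_s=60.0, delta=0.25, hysteresis=0.5, direction=1,
        actuator_tau_s=5.0,
    )


class ControlSection(_Section):
    ph: LoopControlSection = Field(default_factory=_default_ph_loop)
    velocity: LoopControlSection = Field(default_factory=_default_velocity_loop)
    temperature: LoopControlSection = Field(default_factory=_default_temperature_loop)


class HarvestSection(_Section):
    time_h: float = Field(..., ge=0)
    fraction: float = Field(..., ge=0, le=1)


class SimulationConfig(_Section):
    simulation: SimulationSection = Field(default_factory=SimulationSection)
    geometry: GeometrySection = Field(default_factory=GeometrySection)
    kinetics: KineticsSection = Field(default_factory=KineticsSection)
    chemistry: ChemistrySection = Field(default_factory=ChemistrySection)
    thermal: ThermalSection = Field(default_factory=ThermalSection)
    operation: OperationSection = Field(default_factory=OperationSection)
    environment: EnvironmentSection = Field(default_factory=EnvironmentSection)
    control: ControlSection = Field(default_factory=ControlSection)
    harvest: List[HarvestSection] = Field(default_factory=list)


def _format_validation_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        parts.append(f"[{loc}]: {err['msg']}")
    return "invalid configuration: " + "; ".join(parts)


def config_from_dict(data: dict) -> SimulationConfig:
    try:
        return SimulationConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from exc


def read_config(path: str | None = None) -> SimulationConfig:
    """Read and validate a TOML configuration; ``None`` or empty → defaults."""
    if path is None:
        return SimulationConfig()
    with open(path, "rb") as fh:
        try:
            data = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"{path}: not valid TOML: {exc}") from exc
    return config_from_dict(data)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, list):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)}")


def _emit_table(lines: list, name: str, data: dict) -> None:
    scalar = {k: v for k, v in data.items() if not isinstance(v, dict) and v is not None}
    nested = {k: v for k, v in data.items() if isinstance(v, dict)}
    if scalar or not nested:
        lines.append(f"[{name}]")
        for k, v in scalar.items():
            lines.append(f"{k} = {_toml_value(v)}")
        lines.append("")
    for k, v in nested.items():
        _emit_table(lines, f"{name}.{k}", v)


def write_config(cfg: SimulationConfig, path: str) -> None:
    """Serialize a configuration back to TOML; read_config(write) is identity."""
    data = cfg.model_dump()
    harvest = data.pop("harvest", [])
    lines: list = []
    for section, content in data.items():
        _emit_table(lines, section, content)
    for entry in harvest:
        lines.append("[[harvest]]")
        for k, v in entry.items():
            lines.append(f"{k} = {_toml_value(v)}")
        lines.append("")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines).rstrip() + "\n")
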