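"""Lumped-volume temperature model of the loop and column.

Each lumped volume carries one first-law ODE: advection from the upstream
volume, combined wall conduction + external convection to ambient, absorbed
solar radiation on the projected tube area, and (for the column volume) a
heat-exchanger sink fed with cooling water.  The loop volumes are chained in
flow order; the column outlet feeds loop volume 1 and the last loop volume
returns to the column, so the adiabatic closed configuration conserves
enthalpy exactly.

The empirical internal-convection correlations of the physical plant are
collapsed into a single combined wall conductance ``wall_conductance``
(W/m2/K per unit outer tube area); long-wave radiative exchange is omitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

WATER_DENSITY = 1000.0  # kg/m3
WATER_CP = 4186.0  # J/(kg K)

__all__ = [
    "ThermalParams",
    "ThermalState",
    "ThermalGrid",
    "volume_energy_rate",
    "heat_exchanger_duty",
    "step_thermal",
]


@dataclass(frozen=True)
class ThermalParams:
    fluid_density: float = WATER_DENSITY  # kg/m3
    fluid_heat_capacity: float = WATER_CP  # J/(kg K)
    wall_conductance: float = 15.0  # W/(m2 K), tube wall + outside convection
    solar_absorptivity: float = 0.35  # fraction of intercepted radiation absorbed
    hx_UA: float = 2000.0  # W/K, heat-exchanger overall conductance
    cooling_water_cp: float = WATER_CP

    def __post_init__(self) -> None:
        for name in ("fluid_density", "fluid_heat_capacity", "wall_conductance", "hx_UA"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.solar_absorptivity <= 1.0:
            raise ValueError("solar_absorptivity must be in [0, 1]")


@dataclass
class ThermalState:
    """Temperatures of the loop volumes plus the column (last entry)."""

    volume_temperatures: np.ndarray  # degC, length n_loop + 1
    cooling_water_inlet: float = 15.0  # degC
    cooling_water_flow: float = 0.0  # kg/s

    def __post_init__(self) -> None:
        self.volume_temperatures = np.asarray(self.volume_temperatures, float)
        if not np.all(np.isfinite(self.volume_temperatures)):
            raise ValueError("temperatures must be finite")

    @property
    def column_temperature(self) -> float:
        return float(self.volume_temperatures[-1])

    @property
    def loop_temperatures(self) -> np.ndarray:
        return self.volume_temperatures[:-1]


@dataclass(frozen=True)
class ThermalGrid:
    """Precomputed per-volume geometry for the thermal solve.

    ``n_loop`` tube volumes of equal length followed by the column volume.
    The projected (radiation-intercepting) area of a tube volume is
    ``diameter × length``; the column is treated as shaded (projected area 0).
    """

    n_loop: int
    tube_length: float
    tube_diameter: float
    column_liquid_volume: float
    column_height: float
    column_diameter: float

    def volumes(self) -> np.ndarray:
        seg = self.tube_length / self.n_loop
        v_tube = math.pi * (self.tube_diameter / 2.0) ** 2 * seg
        return np.array([v_tube] * self.n_loop + [self.column_liquid_volume])

    def outer_areas(self) -> np.ndarray:
        seg = self.tube_length / self.n_loop
        a_tube = math.pi * self.tube_diameter * seg
        a_col = math.pi * self.column_diameter * self.column_height
        return np.array([a_tube] * self.n_loop + [a_col])

    def projected_areas(self) -> np.ndarray:
        seg = self.tube_length / self.n_loop
        return np.array([self.tube_diameter * seg] * self.n_loop + [0.0])


def volume_energy_rate(
    t_i: float,
    t_upstream: float,
    mass_flow: float,
    irradiance: float,
    ambient: float,
    volume: float,
    outer_area: float,
    projected_area: float,
    params: ThermalParams,
    extra_sink_W: float = 0.0,
) -> float:
    """First-law temperature rate (K/s) of one lumped volume.

    dT/dt = [m_dot cp (T_up - T) + U A_out (T_amb - T) + alpha A_proj G - Q_sink]
            / (rho V cp)
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    rho, cp = params.fluid_density, params.fluid_heat_capacity
    q = (
        mass_flow * cp * (t_upstream - t_i)
        + params.wall_conductance * outer_area * (ambient - t_i)
        + params.solar_absorptivity * projected_area * irradiance
        - extra_sink_W
    )
    return q / (rho * volume * cp)


def heat_exchanger_duty(
    t_column: float, t_cool_in: float, cooling_flow: float, params: ThermalParams
) -> float:
    """Heat removed from the column by the cooling coil (W, effectiveness-NTU).

    Q = eps m_dot_c cp_w (T_column - T_cool_in), eps = 1 - exp(-UA/(m_dot_c cp_w));
    zero at zero flow, sign follows (T_column - T_cool_in).
    """
    if cooling_flow < 0:
        raise ValueError("cooling flow must be >= 0")
    if cooling_flow == 0.0:
        return 0.0
    c_dot = cooling_flow * params.cooling_water_cp
    eff = 1.0 - math.exp(-params.hx_UA / c_dot)
    return eff * c_dot * (t_column - t_cool_in)


def step_thermal(
    state: ThermalState,
    grid: ThermalGrid,
    params: ThermalParams,
    irradiance: float,
    ambient: float,
    mass_flow: float,
    dt: float,
) -> ThermalState:
    """Advance all volume temperatures by ``dt`` (explicit Euler, sub-stepped).

    The sub-step is held below half the fastest volume time constant
    (advection + wall exchange) so the explicit update stays stable; a step
    producing |dT| > 5 K in one sub-step raises, pointing at the step size.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    temps = state.volume_temperatures.copy()
    vols = grid.volumes()
    a_out = grid.outer_areas()
    a_proj = grid.projected_areas()
    rho, cp = params.fluid_density, params.fluid_heat_capacity
    heat_cap = rho * vols * cp  # J/K

    # stability: rate coefficient per volume (1/s)
    coeff = (mass_flow * cp + params.wall_conductance * a_out) / heat_cap
    max_coeff = float(np.max(coeff)) if coeff.size else 0.0
    dt_sub = dt if max_coeff == 0.0 else min(dt, 0.5 / max_coeff)
    n_sub = max(1, int(math.ceil(dt / dt_sub)))
    dt_sub = dt / n_sub

    q_solar = params.solar_absorptivity * a_proj * irradiance
    ua = params.wall_conductance * a_out
    for _ in range(n_sub):
        upstream = np.roll(temps, 1)  # column (last) feeds loop volume 1 (first)
        q_hx = heat_exchanger_duty(
            float(temps[-1]), state.cooling_water_inlet, state.cooling_water_flow, params
        )
        sink = np.zeros_like(temps)
        sink[-1] = q_hx
        dT = (
            (mass_flow * cp * (upstream - temps) + ua * (ambient - temps) + q_solar - sink)
            / heat_cap
            * dt_sub
        )
        if np.any(np.abs(dT) > 5.0):
            raise RuntimeError(
                f"thermal step unstable: |dT| up to {np.max(np.abs(dT)):.2f} K "
                f"in one {dt_sub:.3f} s sub-step; reduce dt"
            )
        temps = temps + dT
    return ThermalState(
        volume_temperatures=temps,
        cooling_water_inlet=state.cooling_water_inlet,
        cooling_water_flow=state.cooling_water_flow,
    )
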