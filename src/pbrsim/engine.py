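"""Simulation orchestration: operator-split time stepping over all modules.

Step order within one ``dt``: forcing → controllers (at their sampling or
event instants) → actuators → reaction/transfer derivatives → advection →
thermal update → carbonate-chemistry update → harvest events → logging.
Controllers act before the plant update, matching sampled-data control of a
continuous plant.

Carbon and oxygen bookkeeping is accumulated flux-by-flux with the same
discrete increments the integrator applies, so the closure audits hold to
rounding and validate the operator splitting end to end.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig
from .control import ActuatorModel, ActuatorState, ControlLoop, OnOffConfig, PIConfig, SSODConfig, actuator_step
from .culture import (
    AIR_Y_CO2,
    AIR_Y_O2,
    ChemistryParams,
    ColumnState,
    KineticParams,
    LoopState,
    PBRGeometry,
    carbonate_h_newton,
    carbonate_speciation,
    column_derivatives,
    ct_for_ph,
    gas_flow_mol_s,
    loop_derivatives,
    solve_h,
)
from .harvest import HarvestEvent, apply_harvest
from .solar import AmbientModel, EnvironmentForcing, SolarLocation, generate_forcing, load_profile
from .thermal import ThermalGrid, ThermalParams, ThermalState, step_thermal

logger = logging.getLogger("pbrsim")

GAS_CONSTANT = 8.314462618  # J/(mol K)
ATM_PA = 101325.0

#: output CSV schema, in order; units are embedded in the names
RESULT_COLUMNS = [
    "time_s",
    "global_Wm2",
    "ph_preinjection",
    "ph_tube_mid",
    "ph_column_entry",
    "temp_loop_start_C",
    "temp_loop_mid_C",
    "temp_loop_end_C",
    "temp_column_C",
    "do2_column_mol_m3",
    "do2_loop_end_mol_m3",
    "biomass_g_m3",
    "gas_y_o2",
    "gas_y_co2",
    "co2_injection_mol_s",
    "co2_injected_cum_mol",
    "co2_losses_cum_mol",
    "o2_production_mol_s",
    "u_co2",
    "co2_flow_L_min",
    "u_velocity",
    "velocity_m_s",
    "u_cooling",
    "cooling_flow_kg_s",
    "co2_events_cum",
]


@dataclass
class SimulationResult:
    """Logged time series at the sensor locations plus closure audits."""

    frame: pd.DataFrame
    config: SimulationConfig
    audits: dict
    meta: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.frame[key]


class SimulationError(RuntimeError):
    """Numerical failure during a run, annotated with step/time context."""


def _config_hash(cfg: SimulationConfig) -> str:
    payload = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _build_loop(section, actuator_default_gain: float) -> tuple:
    """ControlLoop + actuator from one [control.*] config section."""
    gain = section.actuator_gain if section.actuator_gain is not None else actuator_default_gain
    pi = PIConfig(kp=section.kp, ti=section.ti_s, ts=section.ts_s, u_min=0.0, u_max=1.0)
    schedule = None
    if section.schedule is not None:
        # schedule entries are [time_h, physical value]; commands are value/gain
        schedule = [(t_h * 3600.0, value / gain) for t_h, value in section.schedule]
    loop = ControlLoop(
        mode=section.mode,
        setpoint=section.setpoint,
        manual_value=min(max(section.manual_value, 0.0), 1.0),
        pi=pi,
        ssod=SSODConfig(delta=section.delta),
        onoff=OnOffConfig(hysteresis=section.hysteresis, direction=section.direction),
        schedule=schedule,
    )
    model = ActuatorModel(gain=gain, time_constant=section.actuator_tau_s,
                          out_min=0.0, out_max=gain)
    return loop, model


def run_simulation(config: SimulationConfig | None = None,
                   forcing: EnvironmentForcing | None = None) -> SimulationResult:
    """Run the full plant simulation described by ``config``.

    Deterministic for a fixed config (the only randomness hook is the seed
    reserved for optional sensor noise, which is off).  Returns the logged
    time series and the carbon/oxygen closure audits.
    """
    cfg = config or SimulationConfig()
    sim = cfg.simulation
    geom = PBRGeometry(
        tube_length=cfg.geometry.tube_length_m,
        tube_diameter=cfg.geometry.tube_diameter_m,
        column_height=cfg.geometry.column_height_m,
        column_diameter=cfg.geometry.column_diameter_m,
        n_elements=cfg.geometry.n_elements,
        liquid_fraction_column=cfg.geometry.liquid_fraction_column,
    )
    kin = KineticParams(
        r_o2_max=cfg.kinetics.r_o2_max,
        i_half=cfg.kinetics.i_half_Wm2,
        hill_n=cfg.kinetics.hill_n,
        o2_inhibition_conc=cfg.kinetics.o2_inhibition_mol_m3,
        inhibition_exponent=cfg.kinetics.inhibition_exponent,
        c_half=cfg.kinetics.c_half_mol_m3,
        extinction_coeff=cfg.kinetics.extinction_m2_g,
        yield_x_per_o2=cfg.kinetics.yield_g_per_mol_o2,
        photosynthetic_quotient=cfg.kinetics.photosynthetic_quotient,
        respiration_rate=cfg.kinetics.respiration_mol_g_s,
        dark_biomass_decay=cfg.kinetics.dark_biomass_decay,
    )
    chem = ChemistryParams(
        k1=cfg.chemistry.k1_mol_m3,
        k2=cfg.chemistry.k2_mol_m3,
        kw=cfg.chemistry.kw_mol2_m6,
        alkalinity=cfg.chemistry.alkalinity_mol_m3,
        henry_o2=cfg.chemistry.henry_o2,
        henry_co2=cfg.chemistry.henry_co2,
        kla_o2_column=cfg.chemistry.kla_o2_per_s,
        kla_co2_column=cfg.chemistry.kla_co2_per_s,
    )
    thermal_params = ThermalParams(
        wall_conductance=cfg.thermal.u_wall_W_m2K,
        solar_absorptivity=cfg.thermal.absorptivity,
        hx_UA=cfg.thermal.hx_UA_W_K,
    )
    n_th = cfg.thermal.n_thermal_volumes or geom.n_elements
    grid = ThermalGrid(
        n_loop=n_th,
        tube_length=geom.tube_length,
        tube_diameter=geom.tube_diameter,
        column_liquid_volume=geom.column_liquid_volume,
        column_height=geom.column_height,
        column_diameter=geom.column_diameter,
    )

    dt = sim.dt_s
    n_steps = int(round(sim.duration_days * 86400.0 / dt))
    ambient = AmbientModel(
        mean_C=cfg.thermal.ambient_mean_C,
        amplitude_C=cfg.thermal.ambient_amplitude_C,
        peak_hour=cfg.thermal.ambient_peak_hour,
    )
    location = SolarLocation(
        latitude=cfg.environment.latitude,
        longitude=cfg.environment.longitude,
        clearness_index=cfg.environment.clearness_index,
    )
    if forcing is None:
        if cfg.environment.profile_csv:
            forcing = load_profile(cfg.environment.profile_csv, location,
                                   start_day=sim.start_day, ambient=ambient)
        else:
            forcing = generate_forcing(location, start_day=sim.start_day,
                                       n_days=sim.duration_days, step=min(60.0, dt * 60),
                                       ambient=ambient)
    t_grid = np.arange(n_steps + 1) * dt
    irr = np.interp(t_grid, forcing.time, forcing.global_irradiance)
    tamb = np.interp(t_grid, forcing.time, forcing.ambient_temperature)

    # ---------------- initial state ----------------
    op = cfg.operation
    ct0 = ct_for_ph(op.initial_ph, chem)
    n = geom.n_elements
    loop_state = LoopState(
        biomass=np.full(n, op.initial_biomass_g_m3),
        dissolved_o2=np.full(n, op.initial_do2_mol_m3),
        tic=np.full(n, ct0),
        temperature=np.full(n, op.initial_temperature_C),
    )
    holdup = ATM_PA * geom.column_gas_volume / (GAS_CONSTANT * 298.15)
    col = ColumnState(
        biomass=op.initial_biomass_g_m3,
        dissolved_o2=op.initial_do2_mol_m3,
        tic=ct0,
        temperature=op.initial_temperature_C,
        gas_y_o2=AIR_Y_O2,
        gas_y_co2=AIR_Y_CO2,
        gas_molar_holdup=max(holdup, 1e-6),
    )
    thermal_state = ThermalState(
        volume_temperatures=np.full(n_th + 1, op.initial_temperature_C),
        cooling_water_inlet=cfg.thermal.cooling_water_inlet_C,
        cooling_water_flow=0.0,
    )
    h0 = solve_h(ct0, chem)
    h_loop = np.full(n, h0)
    h_col = h0

    # ---------------- control loops & actuators ----------------
    ph_loop, co2_model = _build_loop(cfg.control.ph, op.co2_max_flow_L_min)
    vel_loop, pump_model = _build_loop(cfg.control.velocity, 1.0)
    temp_loop, cool_model = _build_loop(cfg.control.temperature, cfg.thermal.cooling_max_flow_kg_s)
    co2_act = ActuatorState(output=0.0)
    pump_act = ActuatorState(output=op.velocity_m_s)
    cool_act = ActuatorState(output=0.0)
    if vel_loop.mode == "manual" and cfg.control.velocity.schedule is None:
        vel_loop.manual_value = min(op.velocity_m_s / pump_model.gain, 1.0)

    harvest_events = sorted(
        (
            HarvestEvent(time=h.time_h * 3600.0, fraction=h.fraction,
                         medium_tic=ct_for_ph(8.0, chem),
                         medium_o2=chem.henry_o2 * AIR_Y_O2)
            for h in cfg.harvest
        ),
        key=lambda e: e.time,
    )
    next_harvest = 0

    # ---------------- bookkeeping ----------------
    v_el = geom.element_volume
    v_col = geom.column_liquid_volume
    injected_cum = 0.0
    losses_inj_cum = 0.0
    fixed_c_cum = 0.0  # mol C consumed by net photosynthesis
    transfer_co2_cum = 0.0  # mol, liquid -> gas
    vent_co2_cum = 0.0
    air_in_co2_cum = 0.0
    o2_net_cum = 0.0  # mol net photosynthetic O2
    transfer_o2_cum = 0.0
    vent_o2_cum = 0.0
    air_in_o2_cum = 0.0
    clip_ct = 0.0  # mol restored by negativity clips (should stay ~0)
    clip_o2 = 0.0
    harvested_biomass = 0.0
    harvest_dco2 = 0.0  # mol O2 swapped in by harvest make-up medium
    harvest_dct = 0.0

    ct_stock0 = float(np.sum(loop_state.tic) * v_el + col.tic * v_col)
    o2_stock0 = float(np.sum(loop_state.dissolved_o2) * v_el + col.dissolved_o2 * v_col)
    gas_co2_0 = col.gas_y_co2 * col.gas_molar_holdup
    gas_o2_0 = col.gas_y_o2 * col.gas_molar_holdup

    stride = sim.output_stride
    n_logs = (n_steps - 1) // stride + 2  # strided rows plus the final state
    log = {c: np.zeros(n_logs) for c in RESULT_COLUMNS}
    log_i = 0

    eff = op.co2_absorption_efficiency
    mid = n // 2

    def record(i_step: int, t: float, g: float, inj_rate: float, o2_prod: float,
               co2_flow: float, velocity: float, cooling: float) -> None:
        nonlocal log_i
        row = log_i
        log["time_s"][row] = t
        log["global_Wm2"][row] = g
        log["ph_preinjection"][row] = 3.0 - math.log10(h_col)
        log["ph_tube_mid"][row] = 3.0 - math.log10(h_loop[mid])
        log["ph_column_entry"][row] = 3.0 - math.log10(h_loop[-1])
        th = thermal_state.volume_temperatures
        log["temp_loop_start_C"][row] = th[0]
        log["temp_loop_mid_C"][row] = th[n_th // 2]
        log["temp_loop_end_C"][row] = th[n_th - 1]
        log["temp_column_C"][row] = th[-1]
        log["do2_column_mol_m3"][row] = col.dissolved_o2
        log["do2_loop_end_mol_m3"][row] = loop_state.dissolved_o2[-1]
        total_b = np.sum(loop_state.biomass) * v_el + col.biomass * v_col
        log["biomass_g_m3"][row] = total_b / geom.total_liquid_volume
        log["gas_y_o2"][row] = col.gas_y_o2
        log["gas_y_co2"][row] = col.gas_y_co2
        log["co2_injection_mol_s"][row] = inj_rate
        log["co2_injected_cum_mol"][row] = injected_cum
        log["co2_losses_cum_mol"][row] = losses_inj_cum + vent_co2_cum - air_in_co2_cum
        log["o2_production_mol_s"][row] = o2_prod
        log["u_co2"][row] = ph_loop.command
        log["co2_flow_L_min"][row] = co2_flow
        log["u_velocity"][row] = vel_loop.command
        log["velocity_m_s"][row] = velocity
        log["u_cooling"][row] = temp_loop.command
        log["cooling_flow_kg_s"][row] = cooling
        log["co2_events_cum"][row] = ph_loop.event_count
        log_i += 1

    rho_cp_flow = thermal_params.fluid_density

    for i in range(n_steps + 1):
        t = i * dt
        g = float(irr[i])
        t_amb = float(tamb[i])

        # --- measurements & controllers ---
        ph_meas = 3.0 - math.log10(h_col)
        u_co2 = ph_loop.update(t, ph_meas)
        u_vel = vel_loop.update(t, pump_act.output)
        u_cool = temp_loop.update(t, thermal_state.column_temperature)

        # --- actuators ---
        co2_flow = actuator_step(u_co2, co2_act, co2_model, dt)
        velocity = actuator_step(u_vel, pump_act, pump_model, dt)
        cooling = actuator_step(u_cool, cool_act, cool_model, dt)
        thermal_state.cooling_water_flow = cooling

        if i == n_steps:
            record(i, t, g, eff * gas_flow_mol_s(co2_flow), 0.0, co2_flow, velocity, cooling)
            break

        # --- culture reaction / transfer / advection ---
        supplied = gas_flow_mol_s(co2_flow)
        inj_dissolved = eff * supplied
        inj_losses = supplied - inj_dissolved

        q_liq = velocity * geom.tube_cross_section
        co2_loop, _, _ = carbonate_speciation(loop_state.tic, h_loop, chem)
        co2_col, _, _ = carbonate_speciation(col.tic, h_col, chem)

        n_sub = max(1, int(math.ceil(velocity * dt / geom.element_length)))
        dts = dt / n_sub
        o2_prod_step = 0.0
        for _ in range(n_sub):
            ld = loop_derivatives(
                loop_state, velocity,
                (col.biomass, col.dissolved_o2, col.tic),
                inj_dissolved, g, geom, kin, co2_aq=co2_loop, dt=dts,
            )
            cd = column_derivatives(
                col, (loop_state.biomass[-1], loop_state.dissolved_o2[-1], loop_state.tic[-1]),
                q_liq, op.air_flow_L_min, geom, chem, kin, float(co2_col),
                surface_irradiance=g, column_light_factor=op.column_light_factor,
            )
            loop_state.biomass += dts * ld.d_biomass
            loop_state.dissolved_o2 += dts * ld.d_dissolved_o2
            loop_state.tic += dts * ld.d_tic
            col.biomass += dts * cd.d_biomass
            col.dissolved_o2 += dts * cd.d_dissolved_o2
            col.tic += dts * cd.d_tic
            col.gas_y_o2 += dts * cd.d_y_o2
            col.gas_y_co2 += dts * cd.d_y_co2

            # bookkeeping with exactly the applied increments
            net_loop = float(np.sum(ld.net_o2) * v_el)
            o2_net_cum += dts * (net_loop + cd.net_o2_mol_s)
            fixed_c_cum += dts * (net_loop + cd.net_o2_mol_s) / kin.photosynthetic_quotient
            transfer_co2_cum += dts * cd.transfer_co2
            transfer_o2_cum += dts * cd.transfer_o2
            vent_co2_cum += dts * cd.vent_co2
            vent_o2_cum += dts * cd.vent_o2
            air_in_co2_cum += dts * cd.air_in_co2
            air_in_o2_cum += dts * cd.air_in_o2
            injected_cum += dts * inj_dissolved
            losses_inj_cum += dts * inj_losses
            o2_prod_step = net_loop + cd.net_o2_mol_s

        # --- positivity floors (tracked in the audits) ---
        neg = loop_state.dissolved_o2 < 0
        if np.any(neg):
            clip_o2 += -float(np.sum(loop_state.dissolved_o2[neg])) * v_el
            loop_state.dissolved_o2[neg] = 0.0
        if col.dissolved_o2 < 0:
            clip_o2 += -col.dissolved_o2 * v_col
            col.dissolved_o2 = 0.0
        neg = loop_state.tic < 0
        if np.any(neg):
            clip_ct += -float(np.sum(loop_state.tic[neg])) * v_el
            loop_state.tic[neg] = 0.0
        if col.tic < 0:
            clip_ct += -col.tic * v_col
            col.tic = 0.0
        if not (np.all(np.isfinite(loop_state.tic)) and math.isfinite(col.tic)):
            raise SimulationError(f"non-finite state at step {i} (t={t:.1f} s); reduce dt")

        # --- thermal ---
        thermal_state = step_thermal(
            thermal_state, grid, thermal_params, g, t_amb,
            rho_cp_flow * q_liq, dt,
        )
        loop_state.temperature[:] = np.interp(
            np.linspace(0.5 / n, 1 - 0.5 / n, n),
            np.linspace(0.5 / n_th, 1 - 0.5 / n_th, n_th),
            thermal_state.volume_temperatures[:-1],
        )
        col.temperature = thermal_state.column_temperature

        # --- carbonate chemistry update (warm-started Newton) ---
        h_loop = carbonate_h_newton(h_loop, loop_state.tic, chem)
        h_col = float(carbonate_h_newton(h_col, col.tic, chem))

        # --- harvest events ---
        while next_harvest < len(harvest_events) and harvest_events[next_harvest].time <= t + dt:
            ev = harvest_events[next_harvest]
            ct_before = float(np.sum(loop_state.tic) * v_el + col.tic * v_col)
            o2_before = float(np.sum(loop_state.dissolved_o2) * v_el + col.dissolved_o2 * v_col)
            harvested_biomass += apply_harvest(loop_state, col, v_el, v_col, ev)
            harvest_dct += float(np.sum(loop_state.tic) * v_el + col.tic * v_col) - ct_before
            harvest_dco2 += float(np.sum(loop_state.dissolved_o2) * v_el
                                  + col.dissolved_o2 * v_col) - o2_before
            h_loop = np.array([solve_h(c, chem) for c in loop_state.tic])
            h_col = solve_h(col.tic, chem)
            logger.info("harvest at t=%.1f s: fraction %.2f", ev.time, ev.fraction)
            next_harvest += 1

        if i % stride == 0:
            record(i, t, g, inj_dissolved, o2_prod_step, co2_flow, velocity, cooling)

    # ---------------- audits ----------------
    ct_stock = float(np.sum(loop_state.tic) * v_el + col.tic * v_col)
    o2_stock = float(np.sum(loop_state.dissolved_o2) * v_el + col.dissolved_o2 * v_col)
    gas_co2 = col.gas_y_co2 * col.gas_molar_holdup
    gas_o2 = col.gas_y_o2 * col.gas_molar_holdup

    carbon_in = injected_cum + air_in_co2_cum + harvest_dct + clip_ct
    carbon_out = (ct_stock - ct_stock0) + (gas_co2 - gas_co2_0) + vent_co2_cum + fixed_c_cum
    carbon_scale = max(abs(carbon_in), abs(ct_stock0), 1e-9)
    oxygen_in = o2_net_cum + air_in_o2_cum + harvest_dco2 + clip_o2
    oxygen_out = (o2_stock - o2_stock0) + (gas_o2 - gas_o2_0) + vent_o2_cum
    oxygen_scale = max(abs(oxygen_in), abs(o2_stock0), 1e-9)
    audits = {
        "carbon_in_mol": carbon_in,
        "carbon_out_mol": carbon_out,
        "carbon_closure_rel": abs(carbon_in - carbon_out) / carbon_scale,
        "oxygen_in_mol": oxygen_in,
        "oxygen_out_mol": oxygen_out,
        "oxygen_closure_rel": abs(oxygen_in - oxygen_out) / oxygen_scale,
        "co2_injected_mol": injected_cum,
        "co2_injection_losses_mol": losses_inj_cum,
        "co2_vented_net_mol": vent_co2_cum - air_in_co2_cum,
        "carbon_fixed_mol": fixed_c_cum,
        "o2_net_produced_mol": o2_net_cum,
        "clip_ct_mol": clip_ct,
        "clip_o2_mol": clip_o2,
        "harvested_biomass_g": harvested_biomass,
    }

    frame = pd.DataFrame({c: log[c][:log_i] for c in RESULT_COLUMNS})
    meta = {
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": sim.random_seed,
        "n_steps": n_steps,
        "dt_s": dt,
    }
    return SimulationResult(frame=frame, config=cfg, audits=audits, meta=meta)


def write_timeseries(result: SimulationResult, path: str) -> None:
    """Write the logged series as CSV with '#'-prefixed metadata lines."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# pbrsim {result.meta.get('version', '?')}\n")
        fh.write(f"# config_hash: {result.meta.get('config_hash', '?')}\n")
        fh.write(f"# seed: {result.meta.get('seed', 0)}\n")
        # 17 significant digits: reading the file back reproduces every
        # value bit for bit
        result.frame.to_csv(fh, index=False, float_format="%.17g")


def read_timeseries(path: str) -> pd.DataFrame:
    """Read back a CSV produced by :func:`write_timeseries`."""
    return pd.read_csv(path, comment="#", float_precision="round_trip")
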