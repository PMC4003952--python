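"""Canonical experiment scenarios and time-series analysis helpers.

The manual CO2-step experiment and its closed-loop (time-based and
event-based PI) counterparts are the reference experiments of the simulated
plant: the injected-gas CO2 flow is stepped 0 → 2.16 L/min at t = 4.15 h and
2.16 → 0.72 L/min at t = 12.8 h under manual control, producing two culture
pH plateaus; the PI experiments regulate pH with the same 2.16 L/min
rotameter-limited line.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimulationConfig

#: manual CO2 schedule of the reference experiment: (time_h, flow_L_min)
MANUAL_CO2_SCHEDULE = [[0.0, 0.0], [4.15, 2.16], [12.8, 0.72]]
#: rotameter-limited CO2 line flow in the closed-loop experiments (L/min)
PI_LINE_FLOW_L_MIN = 2.16

__all__ = [
    "MANUAL_CO2_SCHEDULE",
    "PI_LINE_FLOW_L_MIN",
    "manual_step_config",
    "pi_config",
    "plateau_before_stepdown",
    "plateau_after_stepdown",
    "settling_time_h",
    "settled_value",
]


def manual_step_config(seed: int = 0) -> SimulationConfig:
    """Default plant, one day, pH loop in manual mode with the CO2 step schedule."""
    cfg = SimulationConfig()
    cfg.simulation.random_seed = seed
    cfg.control.ph.mode = "manual"
    cfg.control.ph.schedule = [list(x) for x in MANUAL_CO2_SCHEDULE]
    return cfg


def pi_config(mode: str, setpoint: float, seed: int = 0) -> SimulationConfig:
    """Closed-loop variant: pH loop in ``pi_time`` or ``pi_event`` mode.

    The CO2 actuator saturates at the rotameter line flow of 2.16 L/min, as
    in the reference closed-loop experiments; the PI tuning is the shipped
    default (identical for both modes).
    """
    if mode not in ("pi_time", "pi_event"):
        raise ValueError("mode must be pi_time or pi_event")
    cfg = SimulationConfig()
    cfg.simulation.random_seed = seed
    cfg.control.ph.mode = mode
    cfg.control.ph.setpoint = setpoint
    cfg.operation.co2_max_flow_L_min = PI_LINE_FLOW_L_MIN
    return cfg


def _hours(frame: pd.DataFrame) -> np.ndarray:
    return frame["time_s"].to_numpy() / 3600.0


def plateau_before_stepdown(frame: pd.DataFrame, column: str = "ph_preinjection") -> float:
    """pH plateau under the high CO2 flow: mean over the last hour before 12.8 h."""
    h = _hours(frame)
    sel = (h > 11.8) & (h <= 12.8)
    return float(frame[column].to_numpy()[sel].mean())


def plateau_after_stepdown(frame: pd.DataFrame, column: str = "ph_preinjection") -> float:
    """pH plateau after the step-down: the flattest 1-h window of the afternoon.

    Scans window centres between 14.5 h and 19 h and returns the mean of the
    window with the smallest standard deviation (the plateau persists until
    photosynthesis decays with the evening light).
    """
    h = _hours(frame)
    ph = frame[column].to_numpy()
    best: tuple | None = None
    for centre in np.arange(14.5, 19.0, 0.25):
        sel = (h > centre - 0.5) & (h < centre + 0.5)
        if sel.sum() < 5:
            continue
        window = ph[sel]
        spread = window.std()
        if best is None or spread < best[0]:
            best = (spread, float(window.mean()))
    if best is None:
        raise ValueError("series too short for plateau detection")
    return best[1]


def settling_time_h(frame: pd.DataFrame, band: float = 0.05,
                    column: str = "ph_preinjection") -> float:
    """First time (h) the signal enters and remains within ±band of its final value.

    The final value is the mean over the last hour.  Returns ``inf`` if the
    signal never stays inside the band to the end of the run.
    """
    h = _hours(frame)
    y = frame[column].to_numpy()
    final = y[h > h[-1] - 1.0].mean()
    inside = np.abs(y - final) <= band
    idx = len(inside)
    for i in range(len(inside) - 1, -1, -1):
        if not inside[i]:
            break
        idx = i
    return float(h[idx]) if idx < len(inside) else float("inf")


def settled_value(frame: pd.DataFrame, last_hours: float = 2.0,
                  column: str = "ph_preinjection") -> float:
    """Mean of the signal over the final ``last_hours`` of the run."""
    h = _hours(frame)
    sel = h > h[-1] - last_hours
    return float(frame[column].to_numpy()[sel].mean())
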