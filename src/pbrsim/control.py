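"""Low-level control loops and actuator models.

Three loops act on the plant — CO2 injection valve ↔ culture pH, pump speed ↔
culture velocity, cooling-water valve ↔ column temperature — each in one of
four modes: manual, on/off relay with deadband, time-based discrete PI, or
event-based PI driven by a symmetric send-on-delta (SSOD) quantizer.

The PI law is positional with conditional-integration anti-windup: the
integral only accumulates while the command is inside the actuator bounds.
In event-based mode the quantizer transmits the measured signal only when it
crosses a level that is an integer multiple of ``delta`` away from the
setpoint; the PI then acts on the held, quantized error with an elapsed-time
weighted integral.  Inside the ±delta band the quantized error is zero, so
the integral and the command freeze — the send-on-delta economy.

Actuators are identified first-order lags with a static gain and hard
physical limits, advanced with the exact exponential discretization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "PIConfig",
    "PIState",
    "SSODConfig",
    "SSODState",
    "OnOffConfig",
    "ActuatorModel",
    "ActuatorState",
    "ControlLoop",
    "pi_time_step",
    "ssod_sample",
    "pi_event_update",
    "onoff_step",
    "actuator_step",
]


@dataclass(frozen=True)
class PIConfig:
    kp: float  # command units per unit of error (sign encodes plant gain)
    ti: float  # s, integral time
    ts: float  # s, sampling period in time-based mode
    u_min: float = 0.0
    u_max: float = 1.0

    def __post_init__(self) -> None:
        if self.ti <= 0 or self.ts <= 0:
            raise ValueError("ti and ts must be positive")
        if not self.u_min < self.u_max:
            raise ValueError("u_min must be < u_max")


@dataclass
class PIState:
    integral: float = 0.0  # time-weighted error accumulator (error·s)
    last_command: float = 0.0


def pi_time_step(error: float, state: PIState, cfg: PIConfig) -> float:
    """One sample of the positional PI: u = sat(kp e + kp/ti I).

    The integral accumulates ``error*ts`` only when the unsaturated command
    lies inside the bounds (conditional anti-windup); the state persists
    between calls.
    """
    u_raw = cfg.kp * error + (cfg.kp / cfg.ti) * state.integral
    u = min(max(u_raw, cfg.u_min), cfg.u_max)
    if cfg.u_min < u_raw < cfg.u_max:
        state.integral += error * cfg.ts
    state.last_command = u
    return u


@dataclass(frozen=True)
class SSODConfig:
    delta: float  # send-on-delta band in units of the controlled variable

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")


@dataclass
class SSODState:
    level: int = 0  # last transmitted quantization level


def ssod_sample(signal: float, state: SSODState, cfg: SSODConfig,
                setpoint: float = 0.0):
    """Symmetric send-on-delta quantizer around the setpoint.

    An event fires iff the signal crosses ``(level ± 1)·delta`` away from the
    setpoint; the transmitted value is the nearest crossed level times delta.
    Returns the new level (int) on an event, ``None`` otherwise.
    """
    rel = signal - setpoint
    lo = (state.level - 1) * cfg.delta
    hi = (state.level + 1) * cfg.delta
    if rel >= hi:
        new = math.floor(rel / cfg.delta + 1e-12)
    elif rel <= lo:
        new = math.ceil(rel / cfg.delta - 1e-12)
    else:
        return None
    state.level = int(new)
    return state.level


def pi_event_update(quantized_error: float, elapsed: float,
                    state: PIState, cfg: PIConfig) -> float:
    """PI update on the held quantized error with elapsed-time-weighted integral.

    ``elapsed`` is the time since the previous update; the held error drives
    the integral over that interval, with the same conditional anti-windup as
    the time-based form.  With zero quantized error and no prior integral the
    command is unchanged.
    """
    u_raw = cfg.kp * quantized_error + (cfg.kp / cfg.ti) * state.integral
    u = min(max(u_raw, cfg.u_min), cfg.u_max)
    if cfg.u_min < u_raw < cfg.u_max:
        state.integral += quantized_error * elapsed
    state.last_command = u
    return u


@dataclass(frozen=True)
class OnOffConfig:
    hysteresis: float = 0.0  # width of the relay deadband, units of the variable
    direction: int = 1  # +1 if command 1 should engage when measured > setpoint

    def __post_init__(self) -> None:
        if self.hysteresis < 0:
            raise ValueError("hysteresis must be >= 0")
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")


def onoff_step(measured: float, setpoint: float, previous: float,
               cfg: OnOffConfig) -> float:
    """Relay with deadband: 1 beyond +hysteresis/2, 0 beyond -hysteresis/2, hold inside."""
    x = cfg.direction * (measured - setpoint)
    if x > cfg.hysteresis / 2.0:
        return 1.0
    if x < -cfg.hysteresis / 2.0:
        return 0.0
    return previous


@dataclass(frozen=True)
class ActuatorModel:
    """Identified first-order actuator: physical output = gain·command, lagged."""

    gain: float  # physical units per unit command
    time_constant: float = 0.0  # s; 0 = instantaneous
    out_min: float = 0.0
    out_max: float = float("inf")

    def __post_init__(self) -> None:
        if self.time_constant < 0:
            raise ValueError("time_constant must be >= 0")
        if not self.out_min < self.out_max:
            raise ValueError("out_min must be < out_max")


@dataclass
class ActuatorState:
    output: float = 0.0


def actuator_step(command: float, state: ActuatorState,
                  model: ActuatorModel, dt: float) -> float:
    """Advance the first-order lag dx/dt = (gain·command − x)/τ by ``dt``.

    Uses the exact exponential update, so step responses match the analytic
    x(t) = gain·(1−e^{−t/τ}) to rounding; τ = 0 passes the command through.
    Output is clipped to the physical limits.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    target = model.gain * command
    if model.time_constant == 0.0:
        x = target
    else:
        a = math.exp(-dt / model.time_constant)
        x = target + (state.output - target) * a
    x = min(max(x, model.out_min), model.out_max)
    state.output = x
    return x


@dataclass
class ControlLoop:
    """One manipulated variable bound to one measured variable.

    ``mode`` is 'manual', 'onoff', 'pi_time' or 'pi_event'.  ``update`` is
    called every engine step with the current measurement and returns the
    dimensionless command for the actuator; sampling (time-based) and event
    detection (send-on-delta) are handled internally.
    """

    mode: str = "manual"
    setpoint: float = 0.0
    manual_value: float = 0.0
    pi: PIConfig = field(default_factory=lambda: PIConfig(kp=1.0, ti=100.0, ts=30.0))
    ssod: SSODConfig = field(default_factory=lambda: SSODConfig(delta=0.05))
    onoff: OnOffConfig = field(default_factory=OnOffConfig)
    schedule: list | None = None  # [(time_s, manual command)] overrides, manual mode

    pi_state: PIState = field(default_factory=PIState)
    ssod_state: SSODState = field(default_factory=SSODState)
    _command: float = 0.0
    _next_sample: float = 0.0
    _last_event_update: float = 0.0
    _held_error: float = 0.0
    event_count: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("manual", "onoff", "pi_time", "pi_event"):
            raise ValueError(f"unknown control mode {self.mode!r}")
        if self.mode == "manual":
            self._command = self.manual_value

    def update(self, t: float, measured: float) -> float:
        if self.mode == "manual":
            cmd = self.manual_value
            if self.schedule:
                for t_sched, value in self.schedule:
                    if t >= t_sched:
                        cmd = value
            self._command = min(max(cmd, self.pi.u_min), self.pi.u_max)
        elif self.mode == "onoff":
            self._command = onoff_step(measured, self.setpoint, self._command, self.onoff)
        elif self.mode == "pi_time":
            if t >= self._next_sample - 1e-9:
                error = self.setpoint - measured
                self._command = pi_time_step(error, self.pi_state, self.pi)
                self._next_sample = t + self.pi.ts
        else:  # pi_event: continuous PI driven by the held, quantized error
            event = ssod_sample(measured, self.ssod_state, self.ssod, self.setpoint)
            if event is not None:
                self.event_count += 1
            elapsed = t - self._last_event_update
            self._last_event_update = t
            if elapsed > 0.0:
                # integrate the error held over the elapsed interval
                pi_event_update(self._held_error, elapsed, self.pi_state, self.pi)
            self._held_error = -self.ssod_state.level * self.ssod.delta
            # inside the ±delta band the quantized error is zero: integral and
            # command freeze until the next level crossing (send-on-delta economy)
            self._command = pi_event_update(self._held_error, 0.0,
                                            self.pi_state, self.pi)
        return self._command

    @property
    def command(self) -> float:
        return self._command
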