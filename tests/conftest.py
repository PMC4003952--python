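"""Shared fixtures: the heavy one-day reference runs are computed once."""

from __future__ import annotations

import numpy as np
import pytest

from pbrsim.engine import run_simulation
from pbrsim.scenarios import manual_step_config, pi_config, plateau_before_stepdown
from pbrsim.solar import EnvironmentForcing


@pytest.fixture(scope="session")
def manual_run():
    """One-day default-plant run with the manual CO2 step schedule."""
    return run_simulation(manual_step_config())


@pytest.fixture(scope="session")
def ph_setpoint(manual_run):
    """Closed-loop setpoint: the plateau measured under the high manual flow."""
    return round(plateau_before_stepdown(manual_run.frame), 3)


@pytest.fixture(scope="session")
def pi_time_run(ph_setpoint):
    return run_simulation(pi_config("pi_time", ph_setpoint))


@pytest.fixture(scope="session")
def pi_event_run(ph_setpoint):
    return run_simulation(pi_config("pi_event", ph_setpoint))


@pytest.fixture
def constant_light_forcing():
    """Flat 500 W/m2, 22 degC forcing for short regrowth/kinetics runs."""
    t = np.array([0.0, 86400.0])
    g = np.array([500.0, 500.0])
    return EnvironmentForcing(
        time=t, global_irradiance=g, direct_irradiance=0.8 * g,
        diffuse_irradiance=0.2 * g, ambient_temperature=np.array([22.0, 22.0]),
    )
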