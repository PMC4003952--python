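"""Culture kinetics, carbonate chemistry, gas exchange and compartment balances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbrsim.culture import (
    AIR_Y_CO2,
    AIR_Y_O2,
    ChemistryParams,
    ColumnState,
    KineticParams,
    LoopState,
    PBRGeometry,
    average_irradiance,
    biomass_rate,
    carbonate_h_newton,
    co2_injection_flow,
    column_derivatives,
    ct_for_ph,
    gas_liquid_transfer,
    loop_derivatives,
    ph_from_carbonate,
    photosynthesis_o2_rate,
    photosynthesis_rates,
    solve_h,
)

GEOM = PBRGeometry()
KIN = KineticParams()
CHEM = ChemistryParams()


class TestGeometry:
    def test_plant_volumes(self):
        assert GEOM.loop_volume == pytest.approx(math.pi * 0.045**2 * 400.0)
        assert GEOM.column_liquid_volume == pytest.approx(0.9 * math.pi * 0.2**2 * 3.5)
        assert GEOM.element_length == pytest.approx(8.0)

    @pytest.mark.parametrize("field, value", [("tube_length", -1.0), ("n_elements", 0),
                                              ("liquid_fraction_column", 1.5)])
    def test_invalid_geometry_rejected(self, field, value):
        with pytest.raises(ValueError):
            PBRGeometry(**{field: value})


class TestAverageIrradiance:
    def test_transparent_culture_limit(self):
        assert average_irradiance(800.0, 0.0, 0.06, 0.09) == pytest.approx(800.0)

    def test_unit_optical_depth(self):
        # x = Ka Cb p = 1: Iav/I0 = (1 - e^-1) = 0.6321...
        cb = 1.0 / (0.06 * 0.09)
        assert average_irradiance(100.0, cb, 0.06, 0.09) == pytest.approx(
            100.0 * (1.0 - math.exp(-1.0)), rel=1e-10
        )

    def test_strictly_decreasing_in_biomass(self):
        cbs = np.linspace(0.0, 3000.0, 50)
        iav = average_irradiance(500.0, cbs, 0.06, 0.09)
        assert np.all(np.diff(iav) < 0.0)
        assert np.all((iav >= 0.0) & (iav <= 500.0))


class TestPhotosynthesisKinetics:
    def test_dark_without_respiration_is_zero(self):
        kin = KineticParams(respiration_rate=0.0)
        assert photosynthesis_o2_rate(0.0, 0.2, 500.0, kin) == 0.0

    def test_full_o2_inhibition_clips_production(self):
        gross, _ = photosynthesis_rates(500.0, KIN.o2_inhibition_conc * 1.1, 500.0, KIN)
        assert gross == 0.0

    def test_half_saturation_identity(self):
        kin = KineticParams(hill_n=1.0, o2_inhibition_conc=1e9, respiration_rate=0.0)
        rate = photosynthesis_o2_rate(kin.i_half, 0.0, 500.0, kin)
        assert rate == pytest.approx(500.0 * kin.r_o2_max / 2.0, rel=1e-9)

    def test_net_rate_negative_in_dark(self):
        assert photosynthesis_o2_rate(0.0, 0.25, 500.0, KIN) < 0.0

    def test_carbon_limitation_monotone(self):
        co2 = np.linspace(0.0, 2.0, 20)
        gross, _ = photosynthesis_rates(500.0, 0.2, 500.0, KIN, co2_aq=co2)
        assert np.all(np.diff(gross) > 0.0)

    def test_biomass_rate_from_gross_production(self):
        assert biomass_rate(1e-5, KIN) == pytest.approx(KIN.yield_x_per_o2 * 1e-5)
        assert biomass_rate(0.0, KIN) == 0.0
        # dark respiration does not erode biomass unless the decay flag is set
        assert biomass_rate(0.0, KIN, net_o2_rate=-1e-6) == 0.0
        kin = KineticParams(dark_biomass_decay=True)
        assert biomass_rate(0.0, kin, net_o2_rate=-1e-6) == pytest.approx(-26e-6)


class TestCarbonateSystem:
    def test_no_carbonate_closed_form(self):
        """CT = 0: the charge balance reduces to [OH] - [H] = Alk, a quadratic in h."""
        ph, co2, hco3, co3 = ph_from_carbonate(0.0, CHEM)
        alk = CHEM.alkalinity
        h_expected = (-alk + math.sqrt(alk**2 + 4.0 * CHEM.kw)) / 2.0
        assert 10.0 ** (3.0 - ph) == pytest.approx(h_expected, rel=1e-9)
        assert co2 == 0.0 and hco3 == 0.0 and co3 == 0.0

    def test_against_brute_force_grid_oracle(self):
        """Bisection pH agrees with a 1e6-point residual grid scan to 1e-4."""
        rng = np.random.default_rng(42)
        ph_grid = np.linspace(2.0, 12.0, 1_000_000)
        h_grid = 10.0 ** (3.0 - ph_grid)
        for _ in range(100):
            ct = rng.uniform(0.0, 5.0)
            alk = rng.uniform(0.5, 5.0)
            chem = ChemistryParams(alkalinity=alk)
            denom = h_grid**2 + chem.k1 * h_grid + chem.k1 * chem.k2
            resid = (ct * chem.k1 * (h_grid + 2.0 * chem.k2) / denom
                     + chem.kw / h_grid - h_grid - alk)
            ph_oracle = ph_grid[np.argmin(np.abs(resid))]
            ph_solver, *_ = ph_from_carbonate(ct, chem)
            assert abs(ph_solver - ph_oracle) < 1e-4

    def test_ph_strictly_decreasing_in_ct(self):
        cts = np.linspace(0.1, 6.0, 40)
        phs = [ph_from_carbonate(ct, CHEM)[0] for ct in cts]
        assert np.all(np.diff(phs) < 0.0)

    def test_species_sum_to_ct(self):
        ph, co2, hco3, co3 = ph_from_carbonate(2.6, CHEM)
        assert co2 + hco3 + co3 == pytest.approx(2.6, rel=1e-12)

    def test_ct_for_ph_inverts_solver(self):
        ct = ct_for_ph(7.5, CHEM)
        ph, *_ = ph_from_carbonate(ct, CHEM)
        assert ph == pytest.approx(7.5, abs=1e-9)

    def test_newton_update_tracks_brentq(self):
        """Warm-started Newton follows a per-step-sized CT drift to bracketed
        accuracy (the engine moves CT by well under 0.1% per step)."""
        cts = np.linspace(1.0, 4.0, 25)
        h = np.array([solve_h(ct, CHEM) for ct in cts])
        h_moved = carbonate_h_newton(h, cts * 1.001, CHEM, iterations=3)
        h_exact = np.array([solve_h(ct * 1.001, CHEM) for ct in cts])
        np.testing.assert_allclose(h_moved, h_exact, rtol=1e-9)

    def test_unreachable_bracket_raises(self):
        with pytest.raises(ValueError):
            solve_h(-1.0, CHEM)  # negative CT violates the precondition
        with pytest.raises(ValueError, match="root"):
            # an alkalinity far outside the bracketed pH range cannot balance
            solve_h(0.0, ChemistryParams(alkalinity=5e4))


class TestGasLiquidTransfer:
    def test_equilibrium_and_zero_kla(self):
        assert gas_liquid_transfer(0.02, 0.25, 0.25) == 0.0
        assert gas_liquid_transfer(0.0, 0.5, 0.1) == 0.0

    def test_exponential_relaxation_to_saturation(self):
        """Closed volume with constant C*: C relaxes as exp(-kla t) within 0.1%."""
        kla, c_star, c0, dt = 0.02, 0.26, 0.05, 0.01
        c = c0
        n = int(3 / kla / dt)
        for _ in range(n):
            c += dt * gas_liquid_transfer(kla, c_star, c)
        expected = c_star + (c0 - c_star) * math.exp(-kla * n * dt)
        assert c == pytest.approx(expected, rel=1e-3)


class TestCO2Injection:
    def test_closed_valve(self):
        assert co2_injection_flow(0.0, 5.0) == (0.0, 0.0)

    def test_full_valve_molar_rate(self):
        # 5 L/min at 25 degC, 1 atm = 5 / 24.465 / 60 mol/s
        dissolved, losses = co2_injection_flow(1.0, 5.0, 1.0)
        assert dissolved == pytest.approx(3.406e-3, rel=1e-3)
        assert losses == 0.0

    @given(cmd=st.floats(0.0, 1.0), eff=st.floats(0.01, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_supply_bookkeeping(self, cmd, eff):
        dissolved, losses = co2_injection_flow(cmd, 5.0, eff)
        supplied = cmd * 5.0 / 24.465 / 60.0
        assert dissolved + losses == pytest.approx(supplied, rel=1e-12, abs=1e-15)

    def test_command_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            co2_injection_flow(1.2, 5.0)


def _uniform_loop(n, cb=500.0, o2=0.25, ct=2.5):
    return LoopState(
        biomass=np.full(n, cb), dissolved_o2=np.full(n, o2),
        tic=np.full(n, ct), temperature=np.full(n, 22.0),
    )


def _column(cb=500.0, o2=0.25, ct=2.5, y_o2=AIR_Y_O2, y_co2=AIR_Y_CO2):
    return ColumnState(biomass=cb, dissolved_o2=o2, tic=ct, temperature=22.0,
                       gas_y_o2=y_o2, gas_y_co2=y_co2, gas_molar_holdup=1.8)


class TestColumnBalance:
    def test_equilibrium_column_is_stationary(self):
        """Loop return equals column state, gas at saturation, no air: all derivatives 0."""
        chem = ChemistryParams()
        col = _column(o2=chem.henry_o2 * AIR_Y_O2)
        kin = KineticParams(respiration_rate=0.0)
        co2_aq = chem.henry_co2 * col.gas_y_co2  # liquid at gas saturation
        d = column_derivatives(col, (col.biomass, col.dissolved_o2, col.tic),
                               0.0, 0.0, GEOM, chem, kin, co2_aq)
        for val in (d.d_biomass, d.d_dissolved_o2, d.d_tic, d.d_y_o2, d.d_y_co2):
            assert val == pytest.approx(0.0, abs=1e-15)

    def test_air_strips_supersaturated_oxygen(self):
        col = _column(o2=0.8)
        kin = KineticParams(respiration_rate=0.0)
        d = column_derivatives(col, (col.biomass, col.dissolved_o2, col.tic),
                               0.0, 80.0, GEOM, CHEM, kin, 0.05)
        assert d.d_dissolved_o2 < 0.0
        assert d.transfer_o2 > 0.0

    def test_closed_system_conserves_oxygen(self):
        """No air, no photosynthesis: outgassed O2 only moves between the
        liquid, the constant-pressure gas holdup and the vent stream — the
        three-way balance closes to 1e-8 relative over an hour of stepping."""
        chem = ChemistryParams()
        kin = KineticParams(respiration_rate=0.0)
        col = _column(o2=0.6, y_o2=0.10)
        vl = GEOM.column_liquid_volume
        total0 = col.dissolved_o2 * vl + col.gas_y_o2 * col.gas_molar_holdup
        vented = 0.0
        dt = 1.0
        for _ in range(3600):
            d = column_derivatives(col, (col.biomass, col.dissolved_o2, col.tic),
                                   0.0, 0.0, GEOM, chem, kin, chem.henry_co2 * col.gas_y_co2)
            col.dissolved_o2 += dt * d.d_dissolved_o2
            col.gas_y_o2 += dt * d.d_y_o2
            col.gas_y_co2 += dt * d.d_y_co2
            vented += dt * d.vent_o2
        total1 = col.dissolved_o2 * vl + col.gas_y_o2 * col.gas_molar_holdup + vented
        assert abs(total1 - total0) / total0 < 1e-8

    def test_negative_flow_rejected(self):
        col = _column()
        with pytest.raises(ValueError):
            column_derivatives(col, (0.0, 0.0, 0.0), -1.0, 80.0, GEOM, CHEM, KIN, 0.05)


class TestLoopBalance:
    def test_stagnant_inert_loop_is_stationary(self):
        kin = KineticParams(respiration_rate=0.0)
        loop = _uniform_loop(GEOM.n_elements)
        d = loop_derivatives(loop, 0.0, (500.0, 0.25, 2.5), 0.0, 0.0, GEOM, kin)
        np.testing.assert_allclose(d.d_biomass, 0.0, atol=1e-15)
        np.testing.assert_allclose(d.d_dissolved_o2, 0.0, atol=1e-15)
        np.testing.assert_allclose(d.d_tic, 0.0, atol=1e-15)

    def test_tracer_transit_time(self):
        """A passive tracer pulse entering element 1 exits after about
        tube_length / velocity = 400 / 0.9 = 444 s."""
        kin = KineticParams(respiration_rate=0.0)
        n = GEOM.n_elements
        loop = _uniform_loop(n, o2=0.0)
        velocity, dt = 0.9, 1.0
        exit_conc = []
        pulse_duration = GEOM.element_length / velocity  # fill element 1 once
        for i in range(1000):
            o2_in = 1.0 if i * dt < pulse_duration else 0.0
            d = loop_derivatives(loop, velocity, (500.0, o2_in, 2.5), 0.0, 0.0,
                                 GEOM, kin, dt=dt)
            loop.dissolved_o2 += dt * d.d_dissolved_o2
            exit_conc.append(loop.dissolved_o2[-1])
        exit_conc = np.array(exit_conc)
        centroid = float(np.sum(np.arange(len(exit_conc)) * dt * exit_conc)
                         / np.sum(exit_conc))
        transit = GEOM.tube_length / velocity
        assert abs(centroid - transit) <= GEOM.element_length / velocity + dt

    def test_oxygen_accumulates_along_loop(self, manual_run):
        """In daylight steady circulation the dissolved O2 at the loop end
        exceeds the column value: O2 builds up along the solar receiver."""
        frame = manual_run.frame
        h = frame["time_s"] / 3600.0
        daylight = (h > 9.0) & (h < 15.0)
        assert np.all(frame["do2_loop_end_mol_m3"][daylight]
                      > frame["do2_column_mol_m3"][daylight])

    def test_cfl_violation_raises(self):
        loop = _uniform_loop(GEOM.n_elements)
        with pytest.raises(ValueError, match="CFL"):
            loop_derivatives(loop, 0.9, (500.0, 0.25, 2.5), 0.0, 0.0, GEOM, KIN,
                             dt=20.0)

    def test_injection_feeds_first_element(self):
        kin = KineticParams(respiration_rate=0.0)
        loop = _uniform_loop(GEOM.n_elements)
        d = loop_derivatives(loop, 0.0, (500.0, 0.25, 2.5), 1e-3, 0.0, GEOM, kin)
        assert d.d_tic[0] == pytest.approx(1e-3 / GEOM.element_volume)
        np.testing.assert_allclose(d.d_tic[1:], 0.0, atol=1e-15)
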