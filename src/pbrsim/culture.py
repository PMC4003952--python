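"""Liquid- and gas-phase mass balances of the tubular photobioreactor.

The reactor is split, as in the real fence-type plant, into a perfectly mixed
bubble column (airlift + degasser, with a gas phase) and a 400 m tubular loop
(solar receiver) treated as a plug-flow reactor discretized into N perfectly
mixed elements.  Photosynthesis follows a light response on the Beer–Lambert
average irradiance over the tube cross-section, throttled multiplicatively by
dissolved-oxygen inhibition and by dissolved-CO2 availability; pH follows from
total inorganic carbon and a fixed alkalinity through the carbonate system.

Unit conventions: concentrations in mol/m3 (biomass in g/m3), volumes m3,
flows m3/s for liquid and L/min for gas at the interface (converted at
25 degC, 1 atm), temperatures degC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

#: molar volume of an ideal gas at 25 degC, 1 atm (L/mol)
MOLAR_VOLUME_L = 24.465
#: mole fractions of the sparged air
AIR_Y_O2 = 0.2095
AIR_Y_CO2 = 4.2e-4
#: dissolved-O2 half-saturation of dark respiration (mol/m3); lets the
#: respiratory sink vanish smoothly as the broth approaches anoxia instead
#: of driving the explicit integrator negative
RESP_O2_HALF = 0.01

__all__ = [
    "PBRGeometry",
    "KineticParams",
    "ChemistryParams",
    "LoopState",
    "ColumnState",
    "average_irradiance",
    "photosynthesis_o2_rate",
    "photosynthesis_rates",
    "biomass_rate",
    "ph_from_carbonate",
    "carbonate_speciation",
    "carbonate_h_newton",
    "solve_h",
    "ct_for_ph",
    "gas_liquid_transfer",
    "co2_injection_flow",
    "gas_flow_mol_s",
    "column_derivatives",
    "loop_derivatives",
]


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PBRGeometry:
    """Fence-type tubular PBR geometry (defaults: the Almería pilot plant)."""

    tube_length: float = 400.0  # m
    tube_diameter: float = 0.09  # m
    column_height: float = 3.5  # m
    column_diameter: float = 0.4  # m
    n_elements: int = 50
    liquid_fraction_column: float = 0.9

    def __post_init__(self) -> None:
        for name in ("tube_length", "tube_diameter", "column_height", "column_diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_elements < 1:
            raise ValueError("n_elements must be >= 1")
        if not 0.0 < self.liquid_fraction_column <= 1.0:
            raise ValueError("liquid_fraction_column must be in (0, 1]")

    @property
    def tube_cross_section(self) -> float:
        return math.pi * (self.tube_diameter / 2.0) ** 2

    @property
    def element_length(self) -> float:
        return self.tube_length / self.n_elements

    @property
    def element_volume(self) -> float:
        return self.tube_cross_section * self.element_length

    @property
    def loop_volume(self) -> float:
        return self.tube_cross_section * self.tube_length

    @property
    def column_total_volume(self) -> float:
        return math.pi * (self.column_diameter / 2.0) ** 2 * self.column_height

    @property
    def column_liquid_volume(self) -> float:
        return self.liquid_fraction_column * self.column_total_volume

    @property
    def column_gas_volume(self) -> float:
        return self.column_total_volume - self.column_liquid_volume

    @property
    def total_liquid_volume(self) -> float:
        return self.loop_volume + self.column_liquid_volume

    @property
    def light_path(self) -> float:
        """Optical path for the average-irradiance model: the tube diameter."""
        return self.tube_diameter


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticParams:
    """Photosynthesis and growth kinetics.

    The functional form is a Hill light response on the average irradiance,
    multiplied by a dissolved-O2 inhibition clip ``max(0, 1-(dO2/KO2)^m)``
    and a dissolved-CO2 Monod factor ``CO2aq/(c_half+CO2aq)`` (carbon
    availability is what stabilizes the culture pH when CO2 injection is the
    limiting carbon supply).  All defaults are calibration constants for the
    simulated plant, not literature values; every one is config-overridable.
    """

    r_o2_max: float = 4.2e-6  # mol O2 / g biomass / s, light- and C-saturated
    i_half: float = 150.0  # W/m2, half-saturation average irradiance
    hill_n: float = 1.8  # light-response shape exponent
    o2_inhibition_conc: float = 1.2  # mol/m3 dissolved O2 at full inhibition
    inhibition_exponent: float = 4.0
    c_half: float = 1.2  # mol/m3 dissolved CO2 half-saturation
    extinction_coeff: float = 0.06  # m2/g biomass (Beer-Lambert)
    yield_x_per_o2: float = 26.0  # g biomass per mol O2 evolved
    photosynthetic_quotient: float = 1.0  # mol O2 per mol C fixed
    respiration_rate: float = 2.0e-8  # mol O2 / g / s, dark maintenance
    dark_biomass_decay: bool = False  # biomass loss when net rate < 0

    def __post_init__(self) -> None:
        for name in (
            "r_o2_max", "i_half", "hill_n", "o2_inhibition_conc",
            "inhibition_exponent", "c_half", "extinction_coeff",
            "yield_x_per_o2", "photosynthetic_quotient",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.respiration_rate < 0:
            raise ValueError("respiration_rate must be >= 0")


@dataclass(frozen=True)
class ChemistryParams:
    """Carbonate system, Henry solubilities and column mass transfer.

    Dissociation constants are freshwater values at 25 degC expressed on the
    mol/m3 scale (K [mol/m3] = 1000 * K [mol/L]); ``kw`` is in (mol/m3)^2.
    Henry coefficients give the saturation concentration per unit gas mole
    fraction at 1 atm total pressure.
    """

    k1: float = 4.467e-4  # mol/m3  (10^-6.35 M)
    k2: float = 4.677e-8  # mol/m3  (10^-10.33 M)
    kw: float = 1.0e-8  # (mol/m3)^2
    alkalinity: float = 2.5  # mol/m3, fixed over a run
    henry_o2: float = 1.23  # mol/m3 per mole fraction
    henry_co2: float = 34.0  # mol/m3 per mole fraction
    kla_o2_column: float = 0.02  # 1/s
    kla_co2_column: float = 0.04  # 1/s

    def __post_init__(self) -> None:
        if not self.k1 > self.k2 > 0:
            raise ValueError("require k1 > k2 > 0")
        if self.kw <= 0 or self.alkalinity < 0:
            raise ValueError("invalid kw or alkalinity")
        if self.kla_o2_column < 0 or self.kla_co2_column < 0:
            raise ValueError("kla must be >= 0")


# --------------------------------------------------------------------------
# states
# --------------------------------------------------------------------------

@dataclass
class LoopState:
    """Per-element liquid composition along the tubular loop (arrays of N)."""

    biomass: np.ndarray  # g/m3
    dissolved_o2: np.ndarray  # mol/m3
    tic: np.ndarray  # total inorganic carbon, mol/m3
    temperature: np.ndarray  # degC

    def copy(self) -> "LoopState":
        return LoopState(
            self.biomass.copy(), self.dissolved_o2.copy(),
            self.tic.copy(), self.temperature.copy(),
        )


@dataclass
class ColumnState:
    """Bubble-column liquid composition plus gas-phase mole fractions."""

    biomass: float  # g/m3
    dissolved_o2: float  # mol/m3
    tic: float  # mol/m3
    temperature: float  # degC
    gas_y_o2: float = AIR_Y_O2
    gas_y_co2: float = AIR_Y_CO2
    gas_molar_holdup: float = 1.0  # mol

    def __post_init__(self) -> None:
        if self.gas_molar_holdup <= 0:
            raise ValueError("gas_molar_holdup must be positive")
        if not (0.0 <= self.gas_y_o2 <= 1.0 and 0.0 <= self.gas_y_co2 <= 1.0
                and self.gas_y_o2 + self.gas_y_co2 <= 1.0):
            raise ValueError("gas mole fractions outside [0, 1]")


# --------------------------------------------------------------------------
# light and kinetics
# --------------------------------------------------------------------------

def average_irradiance(surface_irradiance, biomass, extinction_coeff, light_path):
    """Beer–Lambert average irradiance over the light path.

    Iav = I0 (1 - exp(-Ka Cb p)) / (Ka Cb p), with the transparent-culture
    limit Iav -> I0 handled analytically for small optical depth.
    """
    i0 = np.asarray(surface_irradiance, float)
    x = np.asarray(extinction_coeff * np.asarray(biomass, float) * light_path, float)
    small = x < 1e-8
    xs = np.where(small, 1.0, x)
    frac = np.where(small, 1.0 - x / 2.0, (1.0 - np.exp(-xs)) / xs)
    out = i0 * frac
    return float(out) if out.ndim == 0 else out


def photosynthesis_rates(i_av, dissolved_o2, biomass, kin: KineticParams, co2_aq=None):
    """Gross and net volumetric O2 evolution rates (mol O2 / m3 / s).

    gross = Cb r_max I^n/(Ih^n+I^n) clip(1-(dO2/KO2)^m) fC(CO2aq)
    net   = gross - Cb r_resp
    With ``co2_aq=None`` the carbon factor is 1 (carbon-replete culture).
    """
    i_av = np.asarray(i_av, float)
    cb = np.asarray(biomass, float)
    do2 = np.asarray(dissolved_o2, float)
    light = i_av**kin.hill_n / (kin.i_half**kin.hill_n + i_av**kin.hill_n)
    inhib = np.clip(1.0 - (do2 / kin.o2_inhibition_conc) ** kin.inhibition_exponent, 0.0, 1.0)
    if co2_aq is None:
        fc = 1.0
    else:
        c = np.maximum(np.asarray(co2_aq, float), 0.0)
        fc = c / (kin.c_half + c)
    gross = cb * kin.r_o2_max * light * inhib * fc
    resp_avail = np.maximum(do2, 0.0) / (RESP_O2_HALF + np.maximum(do2, 0.0))
    net = gross - cb * kin.respiration_rate * resp_avail
    return gross, net


def photosynthesis_o2_rate(i_av, dissolved_o2, biomass, kin: KineticParams, co2_aq=None):
    """Net volumetric O2 evolution rate (mol O2 / m3 / s); negative in the dark."""
    _, net = photosynthesis_rates(i_av, dissolved_o2, biomass, kin, co2_aq)
    return net


def biomass_rate(gross_o2_rate, kin: KineticParams, net_o2_rate=None):
    """Biomass growth rate (g / m3 / s) from the gross O2 evolution rate.

    Growth is yield × gross production; dark respiration does not erode
    biomass unless ``kin.dark_biomass_decay`` is set, in which case a
    negative net rate is converted at the same yield.
    """
    gross = np.maximum(np.asarray(gross_o2_rate, float), 0.0)
    rate = kin.yield_x_per_o2 * gross
    if kin.dark_biomass_decay and net_o2_rate is not None:
        net = np.asarray(net_o2_rate, float)
        rate = np.where(net < 0, kin.yield_x_per_o2 * net, rate)
    out = np.asarray(rate, float)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# carbonate chemistry
# --------------------------------------------------------------------------

def _charge_balance(h, ct, chem: ChemistryParams):
    """Alkalinity residual f(h) = [HCO3] + 2[CO3] + [OH] - [H] - Alk (mol/m3).

    Strictly decreasing in h, so a sign change brackets the unique root.
    """
    denom = h * h + chem.k1 * h + chem.k1 * chem.k2
    carb = ct * chem.k1 * (h + 2.0 * chem.k2) / denom
    return carb + chem.kw / h - h - chem.alkalinity


def solve_h(ct: float, chem: ChemistryParams, ph_lo: float = 2.0, ph_hi: float = 12.0) -> float:
    """Bracketed solve for [H+] (mol/m3) at given CT and alkalinity."""
    if ct < 0:
        raise ValueError("total inorganic carbon must be >= 0")
    h_lo = 10.0 ** (3.0 - ph_hi)  # high pH -> small h
    h_hi = 10.0 ** (3.0 - ph_lo)
    f_lo = _charge_balance(h_lo, ct, chem)
    f_hi = _charge_balance(h_hi, ct, chem)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no charge-balance root in pH [{ph_lo}, {ph_hi}] "
            f"for CT={ct} alkalinity={chem.alkalinity}"
        )
    return brentq(_charge_balance, h_lo, h_hi, args=(ct, chem), xtol=1e-18, rtol=8.9e-16)


def carbonate_speciation(ct, h, chem: ChemistryParams):
    """(CO2_aq, HCO3, CO3) in mol/m3 from CT and [H+]."""
    denom = h * h + chem.k1 * h + chem.k1 * chem.k2
    co2 = ct * h * h / denom
    hco3 = ct * chem.k1 * h / denom
    co3 = ct * chem.k1 * chem.k2 / denom
    return co2, hco3, co3


def ph_from_carbonate(ct: float, chem: ChemistryParams):
    """Culture pH and carbonate species from total inorganic carbon.

    Solves the fixed-alkalinity charge balance
    ``Alk = [HCO3] + 2[CO3] + [OH] - [H]`` bracketed on pH in [2, 12].
    Returns ``(ph, co2_aq, hco3, co3)``.
    """
    h = solve_h(ct, chem)
    co2, hco3, co3 = carbonate_speciation(ct, h, chem)
    return 3.0 - math.log10(h), co2, hco3, co3


def carbonate_h_newton(h, ct, chem: ChemistryParams, iterations: int = 2):
    """Vectorized warm-started Newton update of [H+] for slowly drifting CT.

    The residual is strictly decreasing in h, so Newton from a nearby
    previous solution converges quadratically; callers should seed with
    :func:`solve_h` and may re-bracket if the returned residual is large.
    """
    h = np.asarray(h, float).copy()
    ct = np.asarray(ct, float)
    for _ in range(iterations):
        denom = h * h + chem.k1 * h + chem.k1 * chem.k2
        num = chem.k1 * (h + 2.0 * chem.k2)
        f = ct * num / denom + chem.kw / h - h - chem.alkalinity
        dfdh = (
            ct * (chem.k1 * denom - num * (2.0 * h + chem.k1)) / (denom * denom)
            - chem.kw / (h * h)
            - 1.0
        )
        step = f / dfdh
        h_new = h - step
        # keep iterates positive; halve towards previous value if overshoot
        h = np.where(h_new > 0, h_new, 0.5 * h)
    return h


def ct_for_ph(ph: float, chem: ChemistryParams) -> float:
    """Total inorganic carbon that puts the culture at a given pH."""
    h = 10.0 ** (3.0 - ph)
    denom = h * h + chem.k1 * h + chem.k1 * chem.k2
    num = chem.k1 * (h + 2.0 * chem.k2)
    ct = (chem.alkalinity - chem.kw / h + h) * denom / num
    if ct < 0:
        raise ValueError(f"pH {ph} unreachable at alkalinity {chem.alkalinity}")
    return ct


# --------------------------------------------------------------------------
# gas-liquid exchange and CO2 supply
# --------------------------------------------------------------------------

def gas_liquid_transfer(kla, saturation_conc, dissolved):
    """Volumetric absorption rate kla (C* - C) in mol/m3/s (positive into liquid)."""
    if np.any(np.asarray(kla) < 0):
        raise ValueError("kla must be >= 0")
    out = np.asarray(kla * (np.asarray(saturation_conc, float) - np.asarray(dissolved, float)))
    return float(out) if out.ndim == 0 else out


def gas_flow_mol_s(flow_L_min: float) -> float:
    """Convert a gas flow in L/min (25 degC, 1 atm) to mol/s."""
    return flow_L_min / MOLAR_VOLUME_L / 60.0


def co2_injection_flow(valve_command: float, max_flow_L_min: float,
                       absorption_efficiency: float = 1.0):
    """Dissolved CO2 molar rate from the injection valve.

    Returns ``(dissolved_mol_s, losses_mol_s)`` where the losses are the
    un-absorbed fraction of the supplied gas; supplied = dissolved + losses.
    """
    if not 0.0 <= valve_command <= 1.0:
        raise ValueError("valve command outside [0, 1]")
    if not 0.0 <= absorption_efficiency <= 1.0:
        raise ValueError("absorption_efficiency outside [0, 1]")
    supplied = gas_flow_mol_s(valve_command * max_flow_L_min)
    dissolved = absorption_efficiency * supplied
    return dissolved, supplied - dissolved


# --------------------------------------------------------------------------
# compartment balances
# --------------------------------------------------------------------------

@dataclass
class ColumnDerivatives:
    d_biomass: float
    d_dissolved_o2: float
    d_tic: float
    d_y_o2: float
    d_y_co2: float
    transfer_o2: float  # mol/s, liquid -> gas positive
    transfer_co2: float  # mol/s, liquid -> gas positive
    vent_o2: float  # mol/s leaving with the vent gas
    vent_co2: float
    air_in_o2: float
    air_in_co2: float
    gross_o2_mol_s: float  # column photosynthesis, mol O2/s
    net_o2_mol_s: float


def column_derivatives(
    col: ColumnState,
    loop_return: tuple,
    liquid_flow: float,
    air_flow_L_min: float,
    geom: PBRGeometry,
    chem: ChemistryParams,
    kin: KineticParams,
    co2_aq: float,
    surface_irradiance: float = 0.0,
    column_light_factor: float = 0.0,
) -> ColumnDerivatives:
    """Time derivatives of the perfectly mixed bubble column.

    ``loop_return`` is the (biomass, dissolved_o2, tic) of the last loop
    element feeding the column; outflow composition equals the column
    composition (perfect mixing).  The gas phase has constant molar holdup
    with a quasi-steady vent flow = air inlet + net transfer from the liquid,
    which keeps mole fractions bounded.  By default the column is dark
    (``column_light_factor=0``): the solar receiver is where photosynthesis
    happens.
    """
    if liquid_flow < 0 or air_flow_L_min < 0:
        raise ValueError("flows must be >= 0")
    vl = geom.column_liquid_volume
    cb_in, o2_in, ct_in = loop_return
    f_air = gas_flow_mol_s(air_flow_L_min)

    # gas-liquid transfer, liquid -> gas positive (mol/s)
    sat_o2 = chem.henry_o2 * col.gas_y_o2
    sat_co2 = chem.henry_co2 * col.gas_y_co2
    t_o2 = chem.kla_o2_column * vl * (col.dissolved_o2 - sat_o2)
    t_co2 = chem.kla_co2_column * vl * (co2_aq - sat_co2)

    # optional residual photosynthesis in the column (dark by default)
    if column_light_factor > 0.0 and surface_irradiance > 0.0:
        i_col = average_irradiance(
            column_light_factor * surface_irradiance, col.biomass,
            kin.extinction_coeff, geom.column_diameter,
        )
    else:
        i_col = 0.0
    gross, net = photosynthesis_rates(i_col, col.dissolved_o2, col.biomass, kin, co2_aq)
    gross, net = float(gross), float(net)

    dilution = liquid_flow / vl
    d_cb = dilution * (cb_in - col.biomass) + biomass_rate(gross, kin, net)
    d_o2 = dilution * (o2_in - col.dissolved_o2) - t_o2 / vl + net
    # net carbon uptake: gross fixation minus respiratory CO2 return
    d_ct = dilution * (ct_in - col.tic) - t_co2 / vl - net / kin.photosynthetic_quotient

    # gas phase: quasi-steady total molar flow keeps holdup constant
    f_out = max(f_air + t_o2 + t_co2, 0.0)
    air_in_o2 = f_air * AIR_Y_O2
    air_in_co2 = f_air * AIR_Y_CO2
    vent_o2 = f_out * col.gas_y_o2
    vent_co2 = f_out * col.gas_y_co2
    d_y_o2 = (air_in_o2 + t_o2 - vent_o2) / col.gas_molar_holdup
    d_y_co2 = (air_in_co2 + t_co2 - vent_co2) / col.gas_molar_holdup

    return ColumnDerivatives(
        d_biomass=d_cb, d_dissolved_o2=d_o2, d_tic=d_ct,
        d_y_o2=d_y_o2, d_y_co2=d_y_co2,
        transfer_o2=t_o2, transfer_co2=t_co2,
        vent_o2=vent_o2, vent_co2=vent_co2,
        air_in_o2=air_in_o2, air_in_co2=air_in_co2,
        gross_o2_mol_s=gross * vl, net_o2_mol_s=net * vl,
    )


@dataclass
class LoopDerivatives:
    d_biomass: np.ndarray
    d_dissolved_o2: np.ndarray
    d_tic: np.ndarray
    gross_o2: np.ndarray  # mol/m3/s per element
    net_o2: np.ndarray


def loop_derivatives(
    loop: LoopState,
    velocity: float,
    column_exit: tuple,
    injection_rate: float,
    surface_irradiance: float,
    geom: PBRGeometry,
    kin: KineticParams,
    co2_aq: np.ndarray | None = None,
    dt: float | None = None,
) -> LoopDerivatives:
    """Per-element derivatives of the plug-flow loop (upwind advection).

    Element 1 is fed by the column exit plus the dissolved CO2 injection;
    the last element feeds the column.  The loop is a closed tube with no
    headspace, so there is no gas exchange: photosynthetic O2 accumulates
    along the loop until the culture returns to the airlift.
    """
    if velocity < 0:
        raise ValueError("velocity must be >= 0")
    if injection_rate < 0:
        raise ValueError("injection rate must be >= 0")
    dx = geom.element_length
    if dt is not None and velocity * dt / dx > 1.0 + 1e-12:
        raise ValueError(
            f"advection CFL violated: v*dt/dx = {velocity * dt / dx:.3f} > 1; "
            f"use dt <= {dx / velocity:.3f} s"
        )
    cb_in, o2_in, ct_in = column_exit
    a = velocity / dx  # 1/s

    up_cb = np.empty_like(loop.biomass)
    up_o2 = np.empty_like(loop.dissolved_o2)
    up_ct = np.empty_like(loop.tic)
    up_cb[0], up_o2[0], up_ct[0] = cb_in, o2_in, ct_in
    up_cb[1:] = loop.biomass[:-1]
    up_o2[1:] = loop.dissolved_o2[:-1]
    up_ct[1:] = loop.tic[:-1]

    i_av = average_irradiance(
        surface_irradiance, loop.biomass, kin.extinction_coeff, geom.light_path
    )
    gross, net = photosynthesis_rates(i_av, loop.dissolved_o2, loop.biomass, kin, co2_aq)

    d_cb = a * (up_cb - loop.biomass) + biomass_rate(gross, kin, net)
    d_o2 = a * (up_o2 - loop.dissolved_o2) + net
    d_ct = a * (up_ct - loop.tic) - net / kin.photosynthetic_quotient
    d_ct[0] += injection_rate / geom.element_volume

    return LoopDerivatives(d_biomass=d_cb, d_dissolved_o2=d_o2, d_tic=d_ct,
                           gross_o2=gross, net_o2=net)
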