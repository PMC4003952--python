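# Methods

`pbrsim` simulates an outdoor fence-type tubular photobioreactor (PBR) for
microalgae culture: a 400 m transparent tube loop (the solar receiver, inner
diameter 0.09 m) closed by a 3.5 m × 0.4 m bubble column that degasses the
broth, supplies air, hosts the cooling coil and returns the culture to the
loop at 0.9 m/s. This note describes the models, their assumptions, the
parameters that matter, and what the shipped defaults do and do not claim.

## Plant structure and state

The column is treated as one perfectly mixed compartment with a liquid phase
(biomass `Cb` in g/m³, dissolved O₂ and total inorganic carbon `C_T` in
mol/m³, temperature) and a gas phase (O₂ and CO₂ mole fractions over a
constant molar holdup). The loop is a plug-flow reactor discretized into
`n_elements` perfectly mixed elements (default 50, i.e. 8 m per element)
advected with first-order upwind differencing; `n_elements = 1` degenerates
gracefully to a two-tank system. Liquid flow is incompressible, so the pump
velocity sets the same volumetric flow everywhere
(`Q = v·π d²/4 ≈ 5.7 L/s`).

Time stepping is explicit operator splitting at `dt = 1 s` (default):
controllers → actuators → reaction/transfer → advection → thermal →
carbonate chemistry → harvest → logging. Controllers act before the plant
update, as in sampled-data control of a continuous process. Advection is
sub-stepped whenever `v·dt/Δx > 1`; at the defaults the CFL number is 0.11.
All per-step fluxes are accumulated alongside the state updates, so the
carbon and oxygen closure audits hold to rounding (≈1e-12 relative over a
day) and exercise the whole splitting, not a separate bookkeeping path.

## Solar forcing

Ground-level global horizontal irradiance is the extraterrestrial horizontal
irradiance times a clearness index `kt` that is fixed for a run:
`G = kt · G_sc (1 + 0.033 cos(2πn/365)) cosθz`, with `G_sc = 1367 W/m²`,
Cooper's declination formula, and the zenith angle from latitude,
declination and hour angle (night clips `cosθz` to 0). The direct/diffuse
split uses the Erbs piecewise-polynomial diffuse fraction in `kt`. Solar
time is used directly — no equation-of-time or longitude correction — which
shifts the true clock time of solar noon by up to ~15 min at the default
site (Almería, 36.8° N); for daily-pattern studies this is immaterial, and
`longitude` stays in the configuration for a future correction. Tilted
surfaces and within-run `kt` variation are out of scope. Recorded
irradiance profiles can be loaded from CSV instead; the diffuse split is
then reconstructed from the back-computed per-sample clearness index capped
at 1. Ambient temperature defaults to a sinusoid (mean 22 °C, amplitude
6 °C, peak at 15:00) because the plant's measured ambient series is not
available; a profile CSV may carry a recorded ambient column.

## Growth and gas exchange

Light available to the culture is the Beer–Lambert average over the tube
diameter `p`: `I_av = I₀ (1 − e^(−K_a C_b p)) / (K_a C_b p)`, with
extinction coefficient `K_a = 0.06 m²/g`. The volumetric gross O₂ evolution
rate is

```
R_gross = Cb · r_max · I_av^n/(I_h^n + I_av^n)
            · clip(1 − (dO₂/K_O2)^m, 0, 1)
            · CO2_aq/(c_half + CO2_aq)
```

a Hill-type light response (`r_max = 4.2e-6 mol O₂ g⁻¹ s⁻¹`,
`I_h = 150 W/m²`, `n = 1.8`), a dissolved-oxygen inhibition clip
(`K_O2 = 1.2 mol/m³`, `m = 4`) — the physiological reason the column must
strip O₂ — and a dissolved-CO₂ Monod factor (`c_half = 1.2 mol/m³`).

The carbon factor deserves a word, because the plant's pH behaviour depends
on it structurally. The injected CO₂ is the culture's only substantial
carbon source: at 80 L/min the air sparge can carry at most
`F_air · CO2_aq/H_CO2` mol/s of CO₂ out of (or into) the broth, about
9e-5 mol/s near pH 7.9 — five times less than the 0.72 L/min injection it
would have to balance. Without a carbon term in the kinetics nothing ties
the photosynthesis rate to `C_T`, so after a step change in the injected
flow the pH drifts monotonically instead of seeking a plateau. With the
Monod factor, the culture draws dissolved CO₂ down (or lets it accumulate)
until uptake matches supply, and the pH plateaus characteristic of the
operated plant emerge as genuine quasi-steady states. Over the operating
range (CO₂(aq) ≈ 0.03–0.3 mol/m³) the factor is nearly linear in CO₂(aq).

Net rate is `R_net = R_gross − Cb·r_resp·dO₂/(dO₂ + 0.01)`; the small
Monod factor on the maintenance respiration (`r_resp = 2e-8 mol g⁻¹ s⁻¹`)
lets the sink die out smoothly near anoxia instead of driving the explicit
integrator negative. Biomass grows as `yield × R_gross`
(26 g biomass per mol O₂); dark respiration does not erode biomass unless
the `dark_biomass_decay` flag is set (default off, so biomass is
non-decreasing). Carbon uptake is `R_net/PQ` with photosynthetic quotient
`PQ = 1`.

The loop is a closed tube with no headspace: no gas exchange, O₂
accumulates along the receiver until the airlift. The column exchanges O₂
and CO₂ with its gas holdup via `kLa(C* − C)` (`kLa_O2 = 0.02 s⁻¹`,
`kLa_CO2 = 0.04 s⁻¹`), with saturation `C* = H·y` at 1 atm
(`H_O2 = 1.23`, `H_CO2 = 34 mol m⁻³` per unit mole fraction). The gas phase
keeps a constant molar holdup with a quasi-steady vent
(`out = air in + net transfer`), which bounds the mole fractions and makes
the vent stream the carrier of CO₂ losses. The column is dark by default
(the receiver is where photosynthesis happens); a `column_light_factor`
is exposed for sensitivity studies. CO₂ injection (a valve command times
the line flow, converted at 24.465 L/mol) dissolves into the first loop
element with efficiency 1.0 by default; any un-absorbed fraction plus the
net vented CO₂ is reported as losses.

## Carbonate chemistry and pH

pH closes the carbon balance through a fixed alkalinity
(`Alk = 2.5 mol/m³`) and the freshwater carbonate system at 25 °C
(`pK1 = 6.35`, `pK2 = 10.33`, `pKw = 14`, all on the mol/m³ scale):
`Alk = [HCO₃⁻] + 2[CO₃²⁻] + [OH⁻] − [H⁺]` with the carbonate fractions as
functions of `[H⁺]` and `C_T`. The residual is strictly decreasing in
`[H⁺]`, so the root is unique; reference solves bracket pH ∈ [2, 12] with
Brent's method to machine tolerance, and the per-step updates use a
warm-started vectorized Newton iteration (2 iterations track the ≤0.1 %
per-step drift of `C_T` to ~1e-10 relative; the test suite checks the
Newton path against the bracketed solver and against a 10⁶-point residual
grid scan). Temperature dependence of the equilibrium constants is not
modelled, consistent with temperature-free kinetics.

## Thermal model

Temperature uses the same lumped-volume idea as the mass balances: one
first-law ODE per volume (default: one per loop element plus the column),

```
ρVc_p dT/dt = ṁc_p(T_up − T) + U A_out (T_amb − T) + α A_proj G − Q_hx
```

with advection chained in flow order, a single combined wall conductance
`U = 15 W m⁻² K⁻¹` standing in for the internal-convection and wall
correlations of the physical plant, solar absorption `α = 0.35` on the
projected area `d × L` of each tube volume (the column is treated as
shaded), and an effectiveness-NTU heat-exchanger sink in the column
(`UA = 2000 W/K`, cooling water at 15 °C). Long-wave radiative loss is
omitted. The update is explicit Euler, sub-stepped to half the fastest
volume time constant; the adiabatic closed loop conserves enthalpy exactly
(telescoping advection), which the suite asserts to 1e-8/hour. Temperature
does not modulate the growth kinetics by default (an open question of the
source model); the culture temperature peaks 1–2 h after solar noon with
these constants, as expected from the ~2 h loop thermal time constant.

## Control

Three loops: CO₂ valve ↔ pre-injection pH sensor (the sensor the injection
directly acts on; the tube-centre and column-entry sensors are logged),
pump ↔ culture velocity, cooling valve ↔ column temperature. Each supports
manual, on/off relay with deadband, time-based PI, and event-based
(send-on-delta, SSOD) PI. Actuators are identified first-order lags with
hard limits, advanced with the exact exponential update.

The PI is positional, `u = sat(k_p e + (k_p/t_i)∫e)`, with
conditional-integration anti-windup. The event-based variant quantizes the
measured signal at levels `±kδ` around the setpoint and runs the same PI on
the held, quantized error: between events the integral ramps on the held
error; inside the ±δ band the quantized error is zero so integral and
command freeze — the send-on-delta economy. (A variant that freezes the
command entirely between events was tried and discarded: under the loop's
~444 s transport delay from injection point to pH sensor it deadlocks
outside the band and produces 0.3-pH excursions.)

Shipped pH-loop tuning: `k_p = −1 /pH`, `t_i = 600 s`, `t_s = 900 s`,
`δ = 0.03 pH` (velocity: 1.0, 20 s, 1 s, 0.02 m/s; temperature: 0.2 /K,
900 s, 60 s, 0.25 K). These are design choices, not identified values. Two
consequences are worth making explicit. First, with the 900 s sampling
period — a realistic SCADA period for a loop whose plant responds over
hours — the time-based pH loop sustains a small limit cycle (~±0.07 pH)
around the setpoint, driven by the transport dead time; its time-averaged
value still sits on the setpoint. Second, the SSOD loop monitors the sensor
continuously and freezes inside its deadband, so it quenches that cycle and
reaches a settled state hours before the time-based loop — the event-based
advantage the tool demonstrates. With a much tighter sampling period
(~30 s) both modes settle within about an hour of each other; the
comparison, like every tuning here, is configuration, not physics.

In the closed-loop reference experiments the CO₂ actuator saturates at
2.16 L/min, matching the plant practice of a solenoid valve behind a
manually set rotameter; the default standalone line limit is 5 L/min.

Harvesting is ideal and manual: at a scheduled time a fraction `f` of the
biomass is removed from every liquid compartment and replaced by fresh
medium at constant volume (other species mix as `(1−f)·old + f·medium`;
medium is alkalinity-equilibrated at pH 8, air-saturated O₂, culture
temperature).

## Reference experiments and calibration

The kinetic, chemical and transfer defaults above are **calibration
constants**: the source plant's identified values are not public, so the
defaults were fitted once against the plant's documented operating
behaviour — the manual CO₂-step experiment (flow 0 → 2.16 L/min at 4.15 h,
2.16 → 0.72 L/min at 12.8 h, producing culture pH plateaus of 7.5 and 7.9)
— and then frozen. With them the simulator reproduces the full daily
pattern: dissolved O₂ peaking at midday, biomass accumulating through
daylight (~+0.4 g/L/day, a realistic areal productivity for this reactor
class), pH rising with irradiance when injection is off, and the two
plateaus within 0.01 pH. They are plausible for a dense *Scenedesmus*-type
outdoor culture but are not measurements; every one is config-overridable.

The plateau detector reports the mean pH over the last hour before the
step-down (high-flow plateau) and the flattest one-hour window between
14.5 h and 19 h (low-flow plateau; after sunset the continuing injection
pulls the pH down again, so the plateau is an afternoon feature). Settling
time is the first time a signal enters and remains within ±0.05 of its
final value (mean over the last hour).

## Numerical choices and degenerate inputs

- Explicit Euler throughout; default `dt = 1 s` against fastest time
  constants of ~25 s (column CO₂ transfer) and ~33 s (gas holdup). Halving
  `dt` moves end-of-day pH, biomass and temperature by <0.5 %; doubling
  `n_elements` moves them by <1 % (both asserted in the suite).
- Concentrations are floored at zero with the clipped mass charged to the
  closure audits (at the defaults no clipping occurs; the audits would
  expose it).
- `velocity = 0` stalls advection but reactions continue; `kt = 0` with
  injection, respiration and gas exchange off is an exactly dead system.
- The charge-balance bracket [2, 12] raises a configuration error rather
  than extrapolating when an extreme alkalinity/`C_T` pair has no root
  there.
- One simulated day at the defaults runs in ~25 s on one core; runs are
  bit-for-bit deterministic for a fixed configuration (the seed is reserved
  for the optional sensor-noise hook, off by default).

## What the synthetic conditions do not show

The radiation model is a clear-sky scaling: no clouds passing within a day,
no spectral effects. Ambient temperature is a sinusoid. Nutrient (N/P)
dynamics, photoacclimation, shear damage, contamination and temperature-
dependent kinetics are not modelled; the carbonate constants are fixed at
25 °C. The calibration reproduces the documented operating points of one
plant — passing tests therefore show the model is internally consistent
and matches that plant's reported behaviour, not that it predicts an
arbitrary reactor; transferring it to another system means re-identifying
the kinetic and transfer constants.
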