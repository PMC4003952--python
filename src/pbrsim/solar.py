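"""Synthetic horizontal solar radiation and ambient-temperature forcing.

The irradiance model is the classical clearness-index construction: the sun's
declination and the solar zenith angle give the extraterrestrial irradiance on
a horizontal plane, and a fixed clearness index ``kt`` scales it down to the
ground-level global irradiance.  The direct/diffuse split uses the Erbs
piecewise-polynomial diffuse-fraction correlation.  Only horizontal radiation
is modelled; solar time is used directly (no equation-of-time or longitude
correction), which is adequate for daily-pattern studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SOLAR_CONSTANT = 1367.0  # W/m2

__all__ = [
    "SolarLocation",
    "AmbientModel",
    "EnvironmentForcing",
    "declination",
    "cos_zenith",
    "extraterrestrial_horizontal",
    "global_horizontal",
    "split_direct_diffuse",
    "generate_forcing",
    "load_profile",
]


@dataclass(frozen=True)
class SolarLocation:
    """Geographic location plus atmospheric clearness.

    ``clearness_index`` is the ratio of ground-level global irradiance to the
    extraterrestrial irradiance (≈0.8 on the clearest days, →0 overcast) and
    is held fixed for the duration of a simulation run.
    """

    latitude: float = 36.8  # degrees north; default: Almería, Spain
    longitude: float = -2.4  # degrees east (retained for future use)
    clearness_index: float = 0.8

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")
        if not 0.0 <= self.clearness_index <= 1.0:
            raise ValueError(
                f"clearness_index {self.clearness_index} outside [0, 1]"
            )


@dataclass(frozen=True)
class AmbientModel:
    """Sinusoidal daily ambient temperature: mean + amplitude·cos(2π(t−t_peak)/day)."""

    mean_C: float = 22.0
    amplitude_C: float = 6.0
    peak_hour: float = 15.0

    def at(self, t_seconds: np.ndarray | float) -> np.ndarray | float:
        phase = 2.0 * math.pi * (np.asarray(t_seconds, float) / 86400.0 - self.peak_hour / 24.0)
        return self.mean_C + self.amplitude_C * np.cos(phase)


@dataclass
class EnvironmentForcing:
    """Time series of horizontal irradiance components and ambient temperature.

    Invariants: ``global = direct + diffuse``; all components zero while the
    sun is below the horizon; ``time`` strictly increasing (seconds from the
    start of the simulated period, which begins at local solar midnight).
    """

    time: np.ndarray  # s
    global_irradiance: np.ndarray  # W/m2
    direct_irradiance: np.ndarray  # W/m2
    diffuse_irradiance: np.ndarray  # W/m2
    ambient_temperature: np.ndarray  # degC
    _interp: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        if self.time.ndim != 1 or len(self.time) < 2:
            raise ValueError("forcing needs at least two samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("forcing time must be strictly increasing")
        for name in ("global_irradiance", "direct_irradiance", "diffuse_irradiance"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != self.time.shape:
                raise ValueError(f"{name} length mismatch")
            if np.any(arr < 0):
                raise ValueError(f"{name} has negative values")
            setattr(self, name, arr)
        self.ambient_temperature = np.asarray(self.ambient_temperature, float)

    def irradiance_at(self, t: float) -> float:
        """Global irradiance (W/m2) at time ``t`` by linear interpolation."""
        return float(np.interp(t, self.time, self.global_irradiance))

    def ambient_at(self, t: float) -> float:
        return float(np.interp(t, self.time, self.ambient_temperature))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "global_Wm2": self.global_irradiance,
                "direct_Wm2": self.direct_irradiance,
                "diffuse_Wm2": self.diffuse_irradiance,
                "ambient_C": self.ambient_temperature,
            }
        )


def declination(day_of_year: int | np.ndarray) -> float | np.ndarray:
    """Solar declination (degrees) by Cooper's formula.

    δ = 23.45 · sin(2π (284 + n) / 365) for day-of-year n ∈ [1, 365].
    """
    day = np.asarray(day_of_year)
    if np.any((day < 1) | (day > 365)):
        raise ValueError("day_of_year must be in [1, 365]")
    out = 23.45 * np.sin(2.0 * math.pi * (284.0 + day) / 365.0)
    return float(out) if np.isscalar(day_of_year) else out


def cos_zenith(
    latitude: float, decl: float | np.ndarray, solar_hour: float | np.ndarray
) -> float | np.ndarray:
    """Cosine of the solar zenith angle, clipped to [0, 1] (night → 0).

    cosθz = sinφ sinδ + cosφ cosδ cosω with hour angle ω = 15°·(h − 12).
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError("latitude outside [-90, 90]")
    phi = math.radians(latitude)
    d = np.radians(np.asarray(decl, float))
    omega = np.radians(15.0 * (np.asarray(solar_hour, float) - 12.0))
    c = np.sin(phi) * np.sin(d) + np.cos(phi) * np.cos(d) * np.cos(omega)
    c = np.clip(c, 0.0, 1.0)
    return float(c) if c.ndim == 0 else c


def extraterrestrial_horizontal(
    day: int | np.ndarray, cos_z: float | np.ndarray
) -> float | np.ndarray:
    """Extraterrestrial irradiance on a horizontal plane (W/m2).

    G0 = Gsc · (1 + 0.033 cos(2π n / 365)) · cosθz.
    """
    cz = np.asarray(cos_z, float)
    if np.any((cz < 0) | (cz > 1)):
        raise ValueError("cos_zenith outside [0, 1]")
    g0 = SOLAR_CONSTANT * (1.0 + 0.033 * np.cos(2.0 * math.pi * np.asarray(day, float) / 365.0)) * cz
    return float(g0) if g0.ndim == 0 else g0


def global_horizontal(
    location: SolarLocation, day: int | np.ndarray, solar_hour: float | np.ndarray
) -> float | np.ndarray:
    """Ground-level global horizontal irradiance: kt × extraterrestrial."""
    cz = cos_zenith(location.latitude, declination(day), solar_hour)
    return location.clearness_index * extraterrestrial_horizontal(day, cz)


def _erbs_diffuse_fraction(kt: np.ndarray) -> np.ndarray:
    """Erbs correlation for the diffuse fraction of global irradiance."""
    kt = np.asarray(kt, float)
    fd = np.where(kt <= 0.22, 1.0 - 0.09 * kt, 0.165)
    mid = (kt > 0.22) & (kt <= 0.80)
    ktm = np.where(mid, kt, 0.0)
    poly = (
        0.9511
        - 0.1604 * ktm
        + 4.388 * ktm**2
        - 16.638 * ktm**3
        + 12.336 * ktm**4
    )
    fd = np.where(mid, poly, fd)
    return np.clip(fd, 0.0, 1.0)


def split_direct_diffuse(
    global_irr: float | np.ndarray,
    clearness_index: float | np.ndarray,
    cos_z: float | np.ndarray,  # noqa: ARG001 - kept for interface symmetry
) -> tuple:
    """Split global horizontal irradiance into (direct, diffuse) components.

    Uses the Erbs diffuse-fraction correlation in the clearness index; the
    two components always sum exactly to the input global value.
    """
    g = np.asarray(global_irr, float)
    if np.any(g < 0):
        raise ValueError("global irradiance must be >= 0")
    fd = _erbs_diffuse_fraction(clearness_index)
    diffuse = fd * g
    direct = g - diffuse
    if np.ndim(global_irr) == 0:
        return float(direct), float(diffuse)
    return direct, diffuse


def generate_forcing(
    location: SolarLocation,
    start_day: int = 172,
    n_days: float = 1.0,
    step: float = 60.0,
    ambient: AmbientModel | None = None,
) -> EnvironmentForcing:
    """Synthesize a forcing series covering ``[0, n_days·86400]`` seconds.

    Time 0 corresponds to local solar midnight of ``start_day`` (day of year).
    """
    if n_days <= 0:
        raise ValueError("n_days must be positive")
    if step <= 0:
        raise ValueError("step must be positive")
    ambient = ambient or AmbientModel()
    t = np.arange(0.0, n_days * 86400.0 + 0.5 * step, step)
    day = start_day + np.floor(t / 86400.0)
    day = ((day - 1) % 365) + 1
    hour = (t / 3600.0) % 24.0
    cz = cos_zenith(location.latitude, declination(day), hour)
    g = location.clearness_index * extraterrestrial_horizontal(day, cz)
    direct, diffuse = split_direct_diffuse(g, location.clearness_index, cz)
    # direct beam cannot exist without sun above horizon
    direct = np.where(cz > 0, direct, 0.0)
    diffuse = g - direct
    return EnvironmentForcing(
        time=t,
        global_irradiance=g,
        direct_irradiance=direct,
        diffuse_irradiance=diffuse,
        ambient_temperature=np.asarray(ambient.at(t), float),
    )


class ProfileFormatError(ValueError):
    """A forcing-profile CSV violated the expected dialect."""


def load_profile(
    path,
    location: SolarLocation | None = None,
    start_day: int = 172,
    ambient: AmbientModel | None = None,
) -> EnvironmentForcing:
    """Load a recorded forcing profile CSV.

    Expected header ``time_s,global_Wm2`` with optional third column
    ``ambient_C``; '#'-prefixed lines are comments.  The direct/diffuse split
    is reconstructed per sample from the back-computed clearness index
    (capped at 1); if the ambient column is absent the sinusoidal default
    model fills it in.
    """
    location = location or SolarLocation()
    rows = []
    have_ambient = False
    with open(path, "r", encoding="utf-8") as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
                if header[:2] != ["time_s", "global_Wm2"]:
                    raise ProfileFormatError(
                        f"line {lineno}: expected header 'time_s,global_Wm2[,ambient_C]'"
                    )
                have_ambient = len(header) >= 3 and header[2] == "ambient_C"
                continue
            parts = line.split(",")
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ProfileFormatError(f"line {lineno}: unparsable row {line!r}") from exc
            if len(vals) < 2:
                raise ProfileFormatError(f"line {lineno}: expected at least 2 columns")
            if vals[1] < 0:
                raise ProfileFormatError(f"line {lineno}: negative irradiance")
            rows.append((lineno, vals))
    if header is None or len(rows) < 2:
        raise ProfileFormatError("profile needs a header and at least two data rows")
    t = np.array([v[0] for _, v in rows])
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ProfileFormatError(
            f"line {rows[bad[0] + 1][0]}: time not strictly increasing"
        )
    g = np.array([v[1] for _, v in rows])
    if have_ambient:
        amb = np.array([v[2] if len(v) > 2 else np.nan for _, v in rows])
        if np.any(np.isnan(amb)):
            raise ProfileFormatError("ambient_C column has missing values")
    else:
        amb = np.asarray((ambient or AmbientModel()).at(t), float)
    day = ((start_day + np.floor(t / 86400.0) - 1) % 365) + 1
    hour = (t / 3600.0) % 24.0
    cz = cos_zenith(location.latitude, declination(day), hour)
    g0 = extraterrestrial_horizontal(day, cz)
    with np.errstate(divide="ignore", invalid="ignore"):
        kt = np.where(g0 > 0, np.minimum(g / np.maximum(g0, 1e-12), 1.0), 0.0)
    direct, diffuse = split_direct_diffuse(g, kt, cz)
    direct = np.where(cz > 0, direct, 0.0)
    diffuse = g - direct
    return EnvironmentForcing(
        time=t,
        global_irradiance=g,
        direct_irradiance=direct,
        diffuse_irradiance=diffuse,
        ambient_temperature=amb,
    )
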