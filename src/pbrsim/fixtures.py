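"""Reproducible fixture generation: synthetic stand-ins for recorded profiles.

The real plant's operators can load recorded irradiance profiles; for tests
and demos this module writes equivalent CSV files from the radiation model,
optionally with seeded multiplicative noise, plus a canned step-test input
for controller experiments.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .solar import AmbientModel, SolarLocation, generate_forcing

__all__ = ["generate_fixtures"]


def generate_fixtures(kind: str, out_dir, seed: int = 0, *,
                      location: SolarLocation | None = None,
                      start_day: int = 172, n_days: float = 1.0,
                      step: float = 300.0, noise_fraction: float = 0.1) -> Path:
    """Write one fixture CSV of the given ``kind`` and return its path.

    kinds: ``radiation`` (clean model output), ``noisy_radiation`` (seeded
    multiplicative noise, clipped at zero), ``step_test`` (a unit step at
    mid-file, for actuator/controller identification exercises).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    location = location or SolarLocation()
    rng = np.random.default_rng(seed)

    if kind in ("radiation", "noisy_radiation"):
        forcing = generate_forcing(location, start_day=start_day, n_days=n_days,
                                   step=step, ambient=AmbientModel())
        g = forcing.global_irradiance.copy()
        if kind == "noisy_radiation" and noise_fraction > 0:
            g = np.maximum(g * (1.0 + noise_fraction * rng.standard_normal(g.shape)), 0.0)
        path = out_dir / f"{kind}.csv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# synthetic {kind} fixture, seed={seed}\n")
            fh.write("time_s,global_Wm2,ambient_C\n")
            for t, gi, a in zip(forcing.time, g, forcing.ambient_temperature):
                fh.write(f"{t:.1f},{gi:.6g},{a:.6g}\n")
        return path

    if kind == "step_test":
        t = np.arange(0.0, 3600.0 + 1, step)
        u = np.where(t >= t[-1] / 2.0, 1.0, 0.0)
        path = out_dir / "step_test.csv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# synthetic step-test input, seed={seed}\n")
            fh.write("time_s,command\n")
            for ti, ui in zip(t, u):
                fh.write(f"{ti:.1f},{ui:.1f}\n")
        return path

    raise ValueError(f"unknown fixture kind {kind!r}")
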