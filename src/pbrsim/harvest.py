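"""Ideal, user-triggered harvesting.

A harvest event removes a fraction ``f`` of the biomass instantaneously from
every liquid compartment and replaces the removed broth with fresh medium at
constant volume: biomass becomes ``(1-f)·Cb`` while the other liquid species
mix as ``(1-f)·old + f·medium``.  This is the idealized filtration +
medium make-up of the real plant's harvesting line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .culture import ColumnState, LoopState

__all__ = ["HarvestEvent", "apply_harvest"]


@dataclass(frozen=True)
class HarvestEvent:
    time: float  # s from simulation start
    fraction: float  # of biomass removed, in [0, 1]
    medium_tic: float = 2.5  # mol/m3 (fresh medium, near alkalinity equilibrium)
    medium_o2: float = 0.258  # mol/m3 (air saturation)
    medium_temperature: float | None = None  # None = no thermal shock

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("harvest fraction outside [0, 1]")
        if self.time < 0:
            raise ValueError("harvest time must be >= 0")


def apply_harvest(
    loop: LoopState,
    column: ColumnState,
    element_volume: float,
    column_volume: float,
    event: HarvestEvent,
) -> float:
    """Apply a harvest in place; returns the harvested biomass in grams.

    The audit identity ``biomass before = biomass after + harvested`` holds
    to rounding because the removal is a pure scaling.
    """
    f = event.fraction
    before = float(np.sum(loop.biomass) * element_volume + column.biomass * column_volume)

    loop.biomass *= 1.0 - f
    loop.dissolved_o2 = (1.0 - f) * loop.dissolved_o2 + f * event.medium_o2
    loop.tic = (1.0 - f) * loop.tic + f * event.medium_tic
    column.biomass *= 1.0 - f
    column.dissolved_o2 = (1.0 - f) * column.dissolved_o2 + f * event.medium_o2
    column.tic = (1.0 - f) * column.tic + f * event.medium_tic
    if event.medium_temperature is not None:
        loop.temperature = (1.0 - f) * loop.temperature + f * event.medium_temperature
        column.temperature = (1.0 - f) * column.temperature + f * event.medium_temperature

    after = float(np.sum(loop.biomass) * element_volume + column.biomass * column_volume)
    return before - after
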