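"""Stochastic necrosis model.

A hepatocyte becomes committed to necrosis when two conditions hold
simultaneously: its intracellular H2O2 exceeds a critical concentration and
its glutathione pool is depleted (below a configurable fraction of the basal
level). Once the criterion is met, death occurs within a time step with a
per-minute exponential hazard weighted by position along the sinusoid —
pericentral cells (low oxygen supply) are the most sensitive, with the
weight anchored to 1 at the central vein and decaying as the inverse of the
distance to it. A committed cell executes necrosis after a stochastic delay
drawn uniformly from [delay_min, delay_max] (default 0-1 min); at execution
all metabolic and transport fluxes stop and the intracellular state is
frozen (dc/dt = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cell_kinetics import IDX, SPECIES

__all__ = [
    "InjuryParameters",
    "CellState",
    "DeathEvent",
    "positional_weight",
    "death_check",
    "apply_death",
]

#: softening length in the inverse-distance weight, in fractions of the
#: sinusoid length (about one hepatocyte of the 16-section tube)
POSITION_EPS = 1.0 / 16.0


@dataclass
class InjuryParameters:
    """Necrosis-criterion parameters.

    h2o2_crit is the critical intracellular H2O2 concentration (uM); the
    default equals the value obtained by calibrating the cell model at the
    in-vitro LC50 exposure of APAP (4000 uM). gsh_depletion_fraction
    quantifies "GSH is consumed" as GSH below that fraction of basal.
    hazard_scale is the per-minute death hazard at the central vein once the
    criterion is met; sensitivity_floor is the approximate hazard weight at
    the portal inlet.
    """

    h2o2_crit: float = 4000.0
    gsh_depletion_fraction: float = 0.1
    delay_min: float = 0.0
    delay_max: float = 1.0
    sensitivity_floor: float = 0.1
    hazard_scale: float = 2.0

    def __post_init__(self) -> None:
        if self.h2o2_crit <= 0:
            raise ValueError("h2o2_crit must be > 0")
        if not 0 <= self.gsh_depletion_fraction < 1:
            raise ValueError("gsh_depletion_fraction must be in [0, 1)")
        if not 0 <= self.delay_min <= self.delay_max:
            raise ValueError("need 0 <= delay_min <= delay_max")
        if self.sensitivity_floor <= 0 or self.hazard_scale < 0:
            raise ValueError("sensitivity_floor must be > 0 and hazard_scale >= 0")


@dataclass
class CellState:
    """One hepatocyte: concentration vector plus alive/dead status."""

    concentrations: np.ndarray
    alive: bool = True
    basal_gsh: float = 2500.0

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.concentrations.shape != (len(SPECIES),):
            raise ValueError("CellState needs one concentration per species")

    @property
    def h2o2(self) -> float:
        return float(self.concentrations[IDX["H2O2"]])

    @property
    def gsh(self) -> float:
        return float(self.concentrations[IDX["GSH"]])


@dataclass(frozen=True)
class DeathEvent:
    """A committed necrosis event for one cell.

    ``cell_id`` is (sinusoid, section, slot); execution happens at
    ``time_exec = time_trigger + delay`` with delay in [delay_min, delay_max].
    """

    cell_id: tuple[int, int, int]
    time_trigger: float
    time_exec: float
    x_frac: float = float("nan")

    def __post_init__(self) -> None:
        if self.time_exec < self.time_trigger:
            raise ValueError("execution time must be >= trigger time")


def positional_weight(x_frac: float, params: InjuryParameters) -> float:
    """Hazard weight in (0, 1] for a cell at fractional position ``x_frac``
    (0 = portal inlet, 1 = central vein).

    weight = min(1, floor / max(1 - x, eps)), which is 1 at the central
    vein, floor at the portal inlet, and non-decreasing in between (inverse
    proportionality to the distance from the central vein, softened by one
    hepatocyte length).
    """
    if not 0.0 <= x_frac <= 1.0:
        raise ValueError(f"x_frac must be in [0, 1], got {x_frac}")
    return min(1.0, params.sensitivity_floor / max(1.0 - x_frac, POSITION_EPS))


def death_check(
    cell: CellState,
    x_frac: float,
    params: InjuryParameters,
    dt: float,
    rng: np.random.Generator,
    t_now: float = 0.0,
    cell_id: tuple[int, int, int] = (0, 0, 0),
) -> DeathEvent | None:
    """Test the necrosis criterion over one step and maybe commit a death.

    If H2O2 > h2o2_crit and GSH < gsh_depletion_fraction * basal GSH, the
    cell dies within this step with probability
    ``1 - exp(-hazard_scale * positional_weight * dt)``; a committed death
    executes after a uniform [delay_min, delay_max] delay.
    """
    if not cell.alive:
        raise ValueError("death_check called on a dead cell")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    criterion = (
        cell.h2o2 > params.h2o2_crit
        and cell.gsh < params.gsh_depletion_fraction * cell.basal_gsh
    )
    if not criterion:
        return None
    w = positional_weight(x_frac, params)
    p_death = 1.0 - np.exp(-params.hazard_scale * w * dt)
    if rng.random() >= p_death:
        return None
    delay = rng.uniform(params.delay_min, params.delay_max)
    return DeathEvent(cell_id=cell_id, time_trigger=t_now,
                      time_exec=t_now + delay, x_frac=x_frac)


def apply_death(cell: CellState, t_exec: float) -> CellState:
    """Execute a committed necrosis: freeze the cell at its current state.

    All metabolic and transport fluxes are zero thereafter (the dead-cell
    branch of ``cell_rhs`` returns a zero derivative).
    """
    if not cell.alive:
        raise ValueError("apply_death called twice on the same cell")
    cell.alive = False
    return cell
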