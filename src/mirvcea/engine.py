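"""Discrete-time cohort simulation over {stable, progressive, dead}.

The whole cohort starts in the stable state.  Each 28-day cycle it is
redistributed by the transition schedule (no return from progressive to
stable; death is absorbing), and costs, life-years and QALYs are accrued on
start-of-cycle occupancy, discounted at an annual rate.  A half-cycle
correction (accrual on the average of start- and end-of-cycle occupancy) is
available behind a flag for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .transitions import DAYS_PER_YEAR, TransitionSchedule

__all__ = ["STATES", "ModelSettings", "CohortTrace", "step", "discount_factor", "run"]

STATES = ("stable", "progressive", "dead")


@dataclass(frozen=True)
class ModelSettings:
    """Global simulation settings.

    horizon_cycles defaults to 65 = ceil(5 * 365.25 / 28), i.e. five years of
    28-day cycles; the annual discount rate applies to both costs and
    effects.
    """

    cycle_days: float = 28.0
    horizon_cycles: int = 65
    annual_discount_rate: float = 0.03
    half_cycle_correction: bool = False

    def __post_init__(self):
        if self.horizon_cycles < 1:
            raise ValueError("horizon_cycles must be >= 1")
        if self.annual_discount_rate < 0:
            raise ValueError("discount rate must be >= 0")

    @property
    def years_per_cycle(self) -> float:
        return self.cycle_days / DAYS_PER_YEAR


def step(occupancy, p_sp: float, p_sd: float, p_pd: float) -> np.ndarray:
    """One cycle of the cohort: returns the next (stable, progressive, dead).

    stable' = stable (1 - p_sp - p_sd); progressive' = stable p_sp +
    progressive (1 - p_pd); dead' = dead + stable p_sd + progressive p_pd.
    """
    occ = np.asarray(occupancy, dtype=float)
    for name, p in (("p_sp", p_sp), ("p_sd", p_sd), ("p_pd", p_pd)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} outside [0, 1]")
    if p_sp + p_sd > 1.0 + 1e-12:
        raise ValueError("p_sp + p_sd exceeds 1")
    stable, prog, dead = occ
    return np.array(
        [
            stable * (1.0 - p_sp - p_sd),
            stable * p_sp + prog * (1.0 - p_pd),
            dead + stable * p_sd + prog * p_pd,
        ]
    )


def discount_factor(cycle: int, settings: ModelSettings):
    """(1 + r)^(-elapsed years) at the start of ``cycle``."""
    c = np.asarray(cycle)
    if np.any(c < 0):
        raise ValueError("cycle must be >= 0")
    f = (1.0 + settings.annual_discount_rate) ** (-(c * settings.years_per_cycle))
    return float(f) if np.ndim(cycle) == 0 else f


@dataclass
class CohortTrace:
    """State occupancy and accumulated outcomes of one strategy.

    ``occupancy`` has shape (horizon+1, 3): start-of-cycle fractions for
    cycles 0..horizon (the last row is the end-of-horizon state).  Cumulative
    arrays have length horizon and are discounted unless suffixed otherwise.
    """

    occupancy: np.ndarray
    cum_cost: np.ndarray
    cum_ly: np.ndarray
    cum_qaly: np.ndarray
    cum_cost_undisc: np.ndarray
    cum_ly_undisc: np.ndarray
    cum_qaly_undisc: np.ndarray

    @property
    def total_cost(self) -> float:
        return float(self.cum_cost[-1])

    @property
    def total_ly(self) -> float:
        return float(self.cum_ly[-1])

    @property
    def total_qaly(self) -> float:
        return float(self.cum_qaly[-1])

    def to_frame(self) -> pd.DataFrame:
        h = self.cum_cost.size
        return pd.DataFrame(
            {
                "cycle": np.arange(h),
                "stable": self.occupancy[:h, 0],
                "progressive": self.occupancy[:h, 1],
                "dead": self.occupancy[:h, 2],
                "disc_cost": self.cum_cost,
                "disc_ly": self.cum_ly,
                "disc_qaly": self.cum_qaly,
            }
        )


def run(
    schedule: TransitionSchedule,
    costs: np.ndarray,
    utilities: np.ndarray,
    settings: ModelSettings,
) -> CohortTrace:
    """Run the cohort model for one strategy.

    ``costs`` and ``utilities`` are (horizon, 3) arrays giving the per-cycle
    euro cost and the utility weight of each state (columns in STATES order);
    the dead column is conventionally zero.  Life-years count any alive
    state.  Accrual uses start-of-cycle occupancy, or the start/end average
    when ``settings.half_cycle_correction`` is on.
    """
    h = settings.horizon_cycles
    if schedule.horizon_cycles != h:
        raise ValueError(
            f"schedule horizon {schedule.horizon_cycles} != settings horizon {h}"
        )
    costs = np.asarray(costs, dtype=float)
    utilities = np.asarray(utilities, dtype=float)
    if costs.shape != (h, 3) or utilities.shape != (h, 3):
        raise ValueError(f"costs and utilities must have shape ({h}, 3)")

    occ = np.empty((h + 1, 3))
    occ[0] = (1.0, 0.0, 0.0)
    p_sp, p_sd, p_pd = schedule.p_sp, schedule.p_sd, schedule.p_pd
    for c in range(h):
        stable, prog, dead = occ[c]
        occ[c + 1, 0] = stable * (1.0 - p_sp[c] - p_sd[c])
        occ[c + 1, 1] = stable * p_sp[c] + prog * (1.0 - p_pd[c])
        occ[c + 1, 2] = dead + stable * p_sd[c] + prog * p_pd[c]

    basis = 0.5 * (occ[:-1] + occ[1:]) if settings.half_cycle_correction else occ[:-1]
    df = discount_factor(np.arange(h), settings)
    ypc = settings.years_per_cycle

    cost_per_cycle = np.einsum("cs,cs->c", basis, costs)
    alive = basis[:, 0] + basis[:, 1]
    qaly_per_cycle = np.einsum("cs,cs->c", basis, utilities) * ypc

    return CohortTrace(
        occupancy=occ,
        cum_cost=np.cumsum(cost_per_cycle * df),
        cum_ly=np.cumsum(alive * ypc * df),
        cum_qaly=np.cumsum(qaly_per_cycle * df),
        cum_cost_undisc=np.cumsum(cost_per_cycle),
        cum_ly_undisc=np.cumsum(alive * ypc),
        cum_qaly_undisc=np.cumsum(qaly_per_cycle),
    )
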