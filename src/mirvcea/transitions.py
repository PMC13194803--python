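"""Per-cycle transition probabilities from survival curves and a life table.

The three-state cohort model needs, for every 28-day cycle, the probabilities
stable -> progressive, stable -> dead and progressive -> dead.  These are
derived so that the cohort trace reproduces the fitted curves exactly: stable
occupancy tracks S_PFS on the cycle grid and the alive fraction tracks S_OS
(the progressive-to-dead probability is obtained "by subtracting the two
cohorts").  Background (natural) mortality from a period life table is applied
in the stable state; the OS-matching death probability in the progressive
state already embeds all-cause mortality, so it is not added there.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import ParametricSurvivalModel

__all__ = [
    "DAYS_PER_YEAR",
    "DAYS_PER_MONTH",
    "MONTHS_PER_CYCLE",
    "TransitionSchedule",
    "interval_prob_from_survivor_fraction",
    "annual_to_cycle_mortality",
    "background_mortality_per_cycle",
    "build_schedule",
]

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = 30.4375  # 365.25 / 12
MONTHS_PER_CYCLE = 28.0 / DAYS_PER_MONTH


@dataclass
class TransitionSchedule:
    """Per-cycle transition probabilities for one arm.

    Arrays are indexed by cycle c in 0..horizon-1; cycle c covers the model
    time interval [t_c, t_{c+1}) with t_c = c * 28/30.4375 months.
    """

    p_sp: np.ndarray  # stable -> progressive
    p_sd: np.ndarray  # stable -> dead
    p_pd: np.ndarray  # progressive -> dead
    cycle_days: float = 28.0
    n_clipped: int = 0

    def __post_init__(self):
        for name in ("p_sp", "p_sd", "p_pd"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} outside [0, 1]")
        if len({self.p_sp.size, self.p_sd.size, self.p_pd.size}) != 1:
            raise ValueError("probability arrays must share a length")
        if np.any(self.p_sp + self.p_sd > 1 + 1e-12):
            raise ValueError("p_sp + p_sd exceeds 1")

    @property
    def horizon_cycles(self) -> int:
        return int(self.p_sp.size)

    def to_frame(self, arm: str = "") -> pd.DataFrame:
        """Audit table with columns arm, cycle, p_sp, p_sd, p_pd."""
        return pd.DataFrame(
            {
                "arm": arm,
                "cycle": np.arange(self.horizon_cycles),
                "p_sp": self.p_sp,
                "p_sd": self.p_sd,
                "p_pd": self.p_pd,
            }
        )


def interval_prob_from_survivor_fraction(y: float, t: float) -> float:
    """Constant per-cycle event probability consistent with a fraction ``y``
    of the cohort surviving ``t`` cycles: P = 1 - y**(1/t).

    The printed form of this conversion carries a sign error (it would be
    negative for y < 1); the standard survivor-fraction identity is used.
    ``y = 0`` maps to certainty (P = 1).
    """
    if t <= 0:
        raise ValueError("t must be > 0")
    if y > 1:
        raise ValueError("survivor proportion cannot exceed 1")
    if y < 0:
        raise ValueError("survivor proportion cannot be negative")
    if y == 0:
        return 1.0
    return 1.0 - math.exp(math.log(y) / t)


def annual_to_cycle_mortality(annual_prob: float, cycle_days: float = 28.0):
    """Convert an annual death probability to a 28-day-cycle probability via
    constant-hazard rescaling: 1 - (1 - q)**(cycle_days/365.25)."""
    q = np.asarray(annual_prob, dtype=float)
    if np.any((q < 0) | (q >= 1)):
        raise ValueError("annual probability must lie in [0, 1)")
    out = 1.0 - np.power(1.0 - q, cycle_days / DAYS_PER_YEAR)
    return float(out) if np.ndim(annual_prob) == 0 else out


def background_mortality_per_cycle(
    life_table: pd.DataFrame,
    start_age: float,
    horizon_cycles: int,
    cycle_days: float = 28.0,
) -> np.ndarray:
    """Per-cycle natural-death probability at the attained age of each cycle.

    The life table has columns ``age`` (strictly increasing) and
    ``annual_death_prob``; ages beyond the last row reuse the last row.
    """
    ages = np.asarray(life_table["age"], dtype=float)
    probs = np.asarray(life_table["annual_death_prob"], dtype=float)
    if np.any(np.diff(ages) <= 0):
        raise ValueError("life table ages must be strictly increasing")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("life table probabilities must lie in [0, 1]")
    attained = start_age + np.arange(horizon_cycles) * cycle_days / DAYS_PER_YEAR
    idx = np.clip(np.searchsorted(ages, attained, side="right") - 1, 0, ages.size - 1)
    annual = np.minimum(probs[idx], 1.0 - 1e-12)
    return annual_to_cycle_mortality(annual, cycle_days)


def build_schedule(
    pfs_model: ParametricSurvivalModel,
    os_model: ParametricSurvivalModel,
    bg: np.ndarray | float,
    horizon_cycles: int,
    cycle_days: float = 28.0,
) -> TransitionSchedule:
    """Derive the per-cycle transition probabilities for one arm.

    On the cycle grid t_c = c * cycle_days/30.4375 months the targets are
    stable occupancy S_PFS(t_c) and alive fraction S_OS(t_c), with S_OS
    clipped up to S_PFS where the fitted curves cross.  Per cycle the stable
    exit total is fixed by the PFS decline, E = 1 - S_PFS(t_{c+1})/S_PFS(t_c),
    and the required deaths by the OS decline, D = S_OS(t_c) - S_OS(t_{c+1}).
    Deaths are drawn from the progressive compartment first ("subtracting the
    two cohorts"); any deaths the progressive mass cannot supply — always the
    case while that compartment is still empty, because the published OS
    curves mix deaths from both pre- and post-progression states — fall on
    the stable state, displacing progression (p_sp = E - p_sd stays exact).
    Background mortality is a floor on the stable death probability.  With
    this allocation the engine trace reproduces S_PFS and S_OS exactly
    whenever the targets are feasible (always, for bg = 0 and OS >= PFS).

    ``bg`` may be a scalar or a length-``horizon_cycles`` array of per-cycle
    background death probabilities.
    """
    if horizon_cycles < 1:
        raise ValueError("horizon_cycles must be >= 1")
    bg_arr = np.broadcast_to(np.asarray(bg, dtype=float), (horizon_cycles,)).copy()
    if np.any((bg_arr < 0) | (bg_arr > 1)):
        raise ValueError("background probabilities must lie in [0, 1]")

    months_per_cycle = cycle_days / DAYS_PER_MONTH
    t = np.arange(horizon_cycles + 1) * months_per_cycle
    s_pfs = pfs_model.survival(t)
    s_os = os_model.survival(t)

    n_clipped = int(np.sum(s_os < s_pfs - 1e-15))
    if n_clipped:
        logger.info("OS < PFS at %d grid points; clipping OS up to PFS", n_clipped)
    s_os = np.maximum(s_os, s_pfs)

    p_sp = np.zeros(horizon_cycles)
    p_sd = np.zeros(horizon_cycles)
    p_pd = np.zeros(horizon_cycles)
    n_prob_clipped = 0
    tiny = 1e-15

    for c in range(horizon_cycles):
        stable = s_pfs[c]
        prog = s_os[c] - s_pfs[c]
        deaths = s_os[c] - s_os[c + 1]

        if stable <= tiny:
            # stable compartment exhausted: all remaining deaths from progressive
            p_sd[c] = bg_arr[c]
            if prog > tiny:
                raw_pd = deaths / prog
                if raw_pd > 1:
                    n_prob_clipped += 1
                    logger.warning("cycle %d: alive target exceeds progressive mass", c)
                p_pd[c] = min(max(raw_pd, 0.0), 1.0)
            continue

        exit_total = 1.0 - s_pfs[c + 1] / stable
        if deaths - stable * bg_arr[c] <= prog + 1e-12:
            # progressive (plus background) can supply every required death
            sd = bg_arr[c]
            raw_pd = (deaths - stable * sd) / prog if prog > tiny else 0.0
            if raw_pd < 0:
                # background alone over-kills relative to the OS decline
                n_prob_clipped += 1
            p_pd[c] = min(max(raw_pd, 0.0), 1.0)
        else:
            # overflow: exhaust the progressive compartment, remainder dies
            # directly from stable (pre-progression mortality in the OS data)
            p_pd[c] = 1.0
            sd = (deaths - prog) / stable
        if sd > exit_total + 1e-12:
            n_prob_clipped += 1  # stable must shrink faster than S_PFS allows
        sd = min(sd, 1.0)
        p_sd[c] = sd
        p_sp[c] = min(max(exit_total - sd, 0.0), 1.0 - sd)

    if n_prob_clipped:
        logger.info("clipped %d transition probabilities into [0, 1]", n_prob_clipped)

    return TransitionSchedule(
        p_sp=p_sp, p_sd=p_sd, p_pd=p_pd, cycle_days=cycle_days,
        n_clipped=n_clipped + n_prob_clipped,
    )
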