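"""Per-cycle cost and utility assembly from the base-case inputs.

Costs accrue in the stable state only (drug, monitoring, imaging,
premedication, and amortized adverse-event treatment — all treatment-
emergent); the dead state accrues nothing.  Grade >= 3 adverse events enter
the cost stack only if their between-arm incidence difference passes a
Pearson chi-square test at p < 0.05, and their per-episode inpatient (DRG)
cost is amortized uniformly over the 60-month horizon.  Utilities are 0.61
(stable) and 0.50 (progressive) with optional per-cycle linear decline
scenarios, floored at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .engine import STATES

__all__ = [
    "AEEntry",
    "GateResult",
    "EconomicInputs",
    "ae_cost_per_cycle",
    "ae_inclusion_gate",
    "standard_arm_drug_cost",
    "cycle_cost",
    "utility_at",
    "mirv_cycle_cost_from_dose",
]

logger = logging.getLogger(__name__)

ARMS = ("mirv", "standard")


@dataclass(frozen=True)
class AEEntry:
    """One grade >= 3 adverse event with trial incidences and episode cost."""

    name: str
    incidence: dict          # arm -> cumulative fraction over the trial
    drg_cost: float          # euro per treated episode
    amortization_months: float = 60.0
    arm_sizes: tuple = (227, 226)
    counts: tuple | None = None  # observed events per arm; derived if None

    def event_counts(self) -> tuple[int, int]:
        if self.counts is not None:
            return tuple(int(c) for c in self.counts)
        return tuple(
            int(round(self.incidence[arm] * n)) for arm, n in zip(ARMS, self.arm_sizes)
        )


@dataclass(frozen=True)
class GateResult:
    include: bool
    chi2: float
    p_value: float
    reason: str = ""


def ae_cost_per_cycle(entry: AEEntry, arm: str) -> float:
    """Amortized euro cost per model cycle: incidence x episode cost spread
    over the amortization window (months treated as 4-week cycles)."""
    if entry.amortization_months <= 0:
        raise ValueError("amortization_months must be > 0")
    return entry.incidence[arm] * entry.drg_cost / entry.amortization_months


def ae_inclusion_gate(entry: AEEntry, alpha: float = 0.05) -> GateResult:
    """Pearson chi-square on the 2x2 event/no-event x arm table, no
    continuity correction; include iff p < alpha.  Tables with a zero margin
    (no events, or events in everyone) are excluded with a warning."""
    a, b = entry.event_counts()
    n1, n2 = entry.arm_sizes
    if a > n1 or b > n2:
        raise ValueError("event counts cannot exceed arm sizes")
    table = np.array([[a, n1 - a], [b, n2 - b]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        logger.warning("adverse event %s: degenerate 2x2 table, excluded", entry.name)
        return GateResult(False, float("nan"), float("nan"), "zero margin")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return GateResult(bool(p < alpha), float(chi2), float(p))


@dataclass(frozen=True)
class EconomicInputs:
    """All euro amounts per 28-day cycle, plus utilities, for both arms."""

    mirv_drug_cost: float = 18231.66
    standard_mode: str = "blended"          # blended | weighted
    standard_blended_cost: float = 1276.83
    standard_components: tuple = (
        ("paclitaxel", 519.77, 0.41),
        ("topotecan", 299.43, 0.23),
        ("pegylated_liposomal_doxorubicin", 457.63, 0.36),
    )
    monitoring_per_cycle: float = 96.96
    imaging_early: float = 141.12
    imaging_late: float = 70.56
    imaging_switch_after_cycle: int = 9      # 1-based: cycles 1..9 early
    premedication: dict = field(
        default_factory=lambda: {"mirv": 82.06, "standard": 27.93}
    )
    adverse_events: tuple = ()
    ae_significance_level: float = 0.05
    utility_stable: float = 0.61
    utility_progressive: float = 0.50
    utility_decline: dict = field(
        default_factory=lambda: {"mirv": 0.0, "standard": 0.0}
    )
    # per-arm utility overrides for bivariate scenarios: arm -> (u_stable, u_prog)
    utility_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.standard_mode not in ("blended", "weighted"):
            raise ValueError("standard_mode must be 'blended' or 'weighted'")
        for value, name in (
            (self.mirv_drug_cost, "mirv_drug_cost"),
            (self.standard_blended_cost, "standard_blended_cost"),
            (self.monitoring_per_cycle, "monitoring_per_cycle"),
            (self.imaging_early, "imaging_early"),
            (self.imaging_late, "imaging_late"),
        ):
            if value < 0:
                raise ValueError(f"{name} must be >= 0")
        for u, name in (
            (self.utility_stable, "utility_stable"),
            (self.utility_progressive, "utility_progressive"),
        ):
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def from_config(cls, config: dict) -> "EconomicInputs":
        drugs = config["drugs"]
        mon = config["monitoring"]
        ae_cfg = config["adverse_events"]
        util = config["utilities"]
        entries = tuple(
            AEEntry(
                name=e["name"],
                incidence={"mirv": e["incidence_mirv"], "standard": e["incidence_standard"]},
                drg_cost=e["drg_cost"],
                amortization_months=ae_cfg.get("amortization_months", 60),
                arm_sizes=tuple(ae_cfg.get("arm_sizes", (227, 226))),
                counts=tuple(e["counts"]) if "counts" in e else None,
            )
            for e in ae_cfg.get("entries", [])
        )
        return cls(
            mirv_drug_cost=drugs["mirv_cost_per_cycle"],
            standard_mode=drugs.get("standard_mode", "blended"),
            standard_blended_cost=drugs.get("standard_blended_cost", 1276.83),
            standard_components=tuple(
                (c["name"], c["cost"], c["proportion"])
                for c in drugs.get("standard_components", [])
            ),
            monitoring_per_cycle=mon["monitoring_per_cycle"],
            imaging_early=mon["imaging_early"],
            imaging_late=mon["imaging_late"],
            imaging_switch_after_cycle=mon.get("imaging_switch_after_cycle", 9),
            premedication=dict(config["premedication"]),
            adverse_events=entries,
            ae_significance_level=ae_cfg.get("significance_level", 0.05),
            utility_stable=util["stable"],
            utility_progressive=util["progressive"],
            utility_decline={
                "mirv": util.get("decline_per_cycle_mirv", 0.0),
                "standard": util.get("decline_per_cycle_standard", 0.0),
            },
        )

    # -- derived quantities -------------------------------------------------
    def drug_cost(self, arm: str) -> float:
        if arm == "mirv":
            return self.mirv_drug_cost
        return standard_arm_drug_cost(self, self.standard_mode)

    def included_aes(self) -> list[tuple[AEEntry, GateResult]]:
        out = []
        for entry in self.adverse_events:
            gate = ae_inclusion_gate(entry, self.ae_significance_level)
            if gate.include:
                out.append((entry, gate))
        return out

    def ae_total_per_cycle(self, arm: str) -> float:
        return sum(ae_cost_per_cycle(e, arm) for e, _ in self.included_aes())

    def base_utility(self, arm: str, state: str) -> float:
        if arm in self.utility_overrides:
            u_stable, u_prog = self.utility_overrides[arm]
        else:
            u_stable, u_prog = self.utility_stable, self.utility_progressive
        return {"stable": u_stable, "progressive": u_prog, "dead": 0.0}[state]

    def with_utility_overrides(self, arm: str, u_stable: float, u_prog: float):
        overrides = dict(self.utility_overrides)
        overrides[arm] = (u_stable, u_prog)
        return replace(self, utility_overrides=overrides)

    # -- matrices for the engine --------------------------------------------
    def cost_matrix(self, arm: str, horizon_cycles: int) -> np.ndarray:
        """(horizon, 3) per-cycle euro costs by state; stable-only accrual."""
        out = np.zeros((horizon_cycles, len(STATES)))
        fixed = (
            self.drug_cost(arm)
            + self.monitoring_per_cycle
            + self.premedication[arm]
            + self.ae_total_per_cycle(arm)
        )
        cycles = np.arange(horizon_cycles)
        imaging = np.where(
            cycles + 1 <= self.imaging_switch_after_cycle,
            self.imaging_early,
            self.imaging_late,
        )
        out[:, 0] = fixed + imaging
        return out

    def utility_matrix(self, arm: str, horizon_cycles: int) -> np.ndarray:
        """(horizon, 3) utility weights by state, with decline and floor."""
        out = np.zeros((horizon_cycles, len(STATES)))
        for c in range(horizon_cycles):
            out[c, 0] = utility_at(self, arm, "stable", c)
            out[c, 1] = utility_at(self, arm, "progressive", c)
        return out


def standard_arm_drug_cost(inputs: EconomicInputs, mode: str | None = None) -> float:
    """Comparator-arm drug cost per cycle.

    ``blended`` returns the configured single average therapy expense per
    treatment interval (base case, 1,276.83); ``weighted`` returns the
    treatment-proportion-weighted sum of the per-drug monthly costs.  The two
    disagree in the published inputs and are deliberately both available.
    """
    mode = mode or inputs.standard_mode
    if mode == "blended":
        return inputs.standard_blended_cost
    if mode == "weighted":
        props = [p for _, _, p in inputs.standard_components]
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("treatment proportions must sum to 1 in weighted mode")
        return sum(cost * p for _, cost, p in inputs.standard_components)
    raise ValueError(f"unknown mode {mode!r}")


def cycle_cost(inputs: EconomicInputs, arm: str, cycle: int) -> float:
    """Stable-state euro cost for 0-based ``cycle``: drug + monitoring +
    premedication + gated adverse events + imaging (early tariff through
    1-based cycle 9, late tariff afterwards)."""
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    imaging = (
        inputs.imaging_early
        if cycle + 1 <= inputs.imaging_switch_after_cycle
        else inputs.imaging_late
    )
    return (
        inputs.drug_cost(arm)
        + inputs.monitoring_per_cycle
        + inputs.premedication[arm]
        + inputs.ae_total_per_cycle(arm)
        + imaging
    )


def utility_at(inputs: EconomicInputs, arm: str, state: str, cycle: int) -> float:
    """Utility weight of a state at 0-based ``cycle``: base utility minus the
    arm's per-cycle decline times the cycle index, floored at 0."""
    if state == "dead":
        return 0.0
    if state not in ("stable", "progressive"):
        raise ValueError(f"unknown state {state!r}")
    base = inputs.base_utility(arm, state)
    return max(base - inputs.utility_decline.get(arm, 0.0) * cycle, 0.0)


def mirv_cycle_cost_from_dose(
    actual_weight_kg: float,
    height_cm: float,
    price_per_mg: float = 30.39,
    dose_mg_per_kg: float = 6.0,
    dosing_interval_days: float = 21.0,
    cycle_days: float = 28.0,
    aibw_fraction: float = 0.4,
) -> float:
    """Optional dose-derived intervention drug cost per 28-day interval.

    Dosing is per kilogram of adjusted ideal body weight (AIBW) every three
    weeks, re-expressed per four-week interval for comparability.  AIBW =
    IBW + aibw_fraction * (actual - IBW) with the female Devine ideal body
    weight IBW = 45.5 + 0.9 * (height_cm - 152); the protocol's exact
    adjustment formula is not published, so the fraction is configurable.
    """
    ibw = 45.5 + 0.9 * (height_cm - 152.0)
    aibw = ibw + aibw_fraction * max(actual_weight_kg - ibw, 0.0)
    per_administration = dose_mg_per_kg * aibw * price_per_mg
    return per_administration * cycle_days / dosing_interval_days
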