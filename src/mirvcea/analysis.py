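"""Incremental cost-effectiveness results and deterministic sensitivity
analyses: one-way (tornado) variation, bivariate utility grids, scenario
settings, and the drug-price threshold search.

Conventions: increments are intervention minus comparator; ICER = dcost/dLY
and ICUR = dcost/dQALY are only reported as ratios when the denominator is
nonzero and the increments are not a dominance configuration (one strategy
cheaper *and* more effective), which is flagged instead; net monetary
benefit NMB(WTP) = WTP * dQALY - dcost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .economics import AEEntry, EconomicInputs

__all__ = [
    "CEResult",
    "DSASpec",
    "incremental",
    "apply_param",
    "default_dsa_specs",
    "one_way_dsa",
    "bivariate_utility",
    "price_threshold",
    "scenario_settings",
]


@dataclass(frozen=True)
class CEResult:
    """Totals per strategy plus incremental summaries at given WTP values."""

    cost: dict            # arm -> discounted euro total
    ly: dict              # arm -> discounted life-years
    qaly: dict            # arm -> discounted QALYs
    dcost: float
    dly: float
    dqaly: float
    icer: float | None    # euro per life-year; None when undefined/dominance
    icur: float | None    # euro per QALY
    nmb: dict             # WTP -> net monetary benefit (euro)
    dominance: str        # "", "intervention dominant", "intervention dominated"


def _ratio(dcost: float, deffect: float) -> float | None:
    if deffect == 0:
        return None
    return dcost / deffect


def incremental(
    base: dict, comparator: dict, wtp_grid=(155499.0,)
) -> CEResult:
    """Incremental result for intervention ``base`` vs ``comparator``.

    Each argument is a mapping with keys ``cost``, ``ly``, ``qaly`` holding
    the strategy's discounted totals.
    """
    dcost = base["cost"] - comparator["cost"]
    dly = base["ly"] - comparator["ly"]
    dqaly = base["qaly"] - comparator["qaly"]

    dominance = ""
    if dcost <= 0 and dqaly > 0:
        dominance = "intervention dominant"
    elif dcost > 0 and dqaly < 0:
        dominance = "intervention dominated"

    icer = None if dominance else _ratio(dcost, dly)
    icur = None if dominance else _ratio(dcost, dqaly)
    nmb = {float(w): float(w) * dqaly - dcost for w in wtp_grid}
    return CEResult(
        cost={"mirv": base["cost"], "standard": comparator["cost"]},
        ly={"mirv": base["ly"], "standard": comparator["ly"]},
        qaly={"mirv": base["qaly"], "standard": comparator["qaly"]},
        dcost=dcost, dly=dly, dqaly=dqaly,
        icer=icer, icur=icur, nmb=nmb, dominance=dominance,
    )


# ---------------------------------------------------------------------------
# Deterministic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DSASpec:
    """One tornado row: a named parameter varied to mean*(1 -/+ multiplier)."""

    name: str
    multiplier: float

    def __post_init__(self):
        if not 0 < self.multiplier < 1:
            raise ValueError("multiplier must lie in (0, 1)")

    @property
    def low(self) -> float:
        return 1.0 - self.multiplier

    @property
    def high(self) -> float:
        return 1.0 + self.multiplier


#: Parameter names understood by :func:`apply_param`.
DSA_PARAMETERS = (
    "mirv_drug_cost",
    "standard_drug_cost",
    "monitoring_cost",
    "ae_cost",
    "premedication_cost",
    "utility_stable",
    "utility_progressive",
)


def apply_param(econ: EconomicInputs, name: str, factor: float) -> EconomicInputs:
    """Return a copy of the inputs with one parameter group scaled.

    Monitoring includes the imaging tariffs (imaging is part of the
    monitoring schedule); utilities are shared across arms and clipped to
    [0, 1] after scaling.
    """
    if name == "mirv_drug_cost":
        return replace(econ, mirv_drug_cost=econ.mirv_drug_cost * factor)
    if name == "standard_drug_cost":
        return replace(
            econ,
            standard_blended_cost=econ.standard_blended_cost * factor,
            standard_components=tuple(
                (n, c * factor, p) for n, c, p in econ.standard_components
            ),
        )
    if name == "monitoring_cost":
        return replace(
            econ,
            monitoring_per_cycle=econ.monitoring_per_cycle * factor,
            imaging_early=econ.imaging_early * factor,
            imaging_late=econ.imaging_late * factor,
        )
    if name == "ae_cost":
        return replace(
            econ,
            adverse_events=tuple(
                replace(e, drg_cost=e.drg_cost * factor) for e in econ.adverse_events
            ),
        )
    if name == "premedication_cost":
        return replace(
            econ, premedication={a: v * factor for a, v in econ.premedication.items()}
        )
    if name == "utility_stable":
        return replace(econ, utility_stable=min(max(econ.utility_stable * factor, 0.0), 1.0))
    if name == "utility_progressive":
        return replace(
            econ, utility_progressive=min(max(econ.utility_progressive * factor, 0.0), 1.0)
        )
    raise KeyError(f"unknown DSA parameter {name!r}; expected one of {DSA_PARAMETERS}")


def default_dsa_specs(config: dict) -> list[DSASpec]:
    """Tornado rows from the config's dsa section: drug prices +/-50%,
    adverse-event, monitoring and premedication costs +/-25%, each state
    utility +/-20% one at a time."""
    dsa = config["dsa"]
    return [
        DSASpec("mirv_drug_cost", dsa["drug_multiplier"]),
        DSASpec("standard_drug_cost", dsa["drug_multiplier"]),
        DSASpec("monitoring_cost", dsa["monitoring_multiplier"]),
        DSASpec("ae_cost", dsa["ae_multiplier"]),
        DSASpec("premedication_cost", dsa["ae_multiplier"]),
        DSASpec("utility_stable", dsa["utility_multiplier"]),
        DSASpec("utility_progressive", dsa["utility_multiplier"]),
    ]


def one_way_dsa(runner, specs: list[DSASpec]) -> pd.DataFrame:
    """Recompute the ICUR at each parameter's low and high value.

    Returns the tornado table (parameter, icur_low, icur_high, width) sorted
    by descending bar width.
    """
    rows = []
    for spec in specs:
        out = {}
        for label, factor in (("icur_low", spec.low), ("icur_high", spec.high)):
            result = runner.run(econ=apply_param(runner.econ, spec.name, factor))
            out[label] = math.nan if result.icur is None else result.icur
        width = abs(out["icur_high"] - out["icur_low"])
        rows.append({"parameter": spec.name, **out, "width": width})
    return (
        pd.DataFrame(rows)
        .sort_values("width", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def bivariate_utility(runner, stable_utils, prog_utils, arm: str = "mirv") -> pd.DataFrame:
    """ICUR over a grid of (stable, progressive) utility pairs applied to one
    arm only (the comparator keeps the base utilities)."""
    rows = []
    for u_s in stable_utils:
        for u_p in prog_utils:
            econ = runner.econ.with_utility_overrides(arm, u_s, u_p)
            result = runner.run(econ=econ)
            rows.append(
                {
                    "utility_stable": u_s,
                    "utility_progressive": u_p,
                    "dqaly": result.dqaly,
                    "icur": math.nan if result.icur is None else result.icur,
                }
            )
    return pd.DataFrame(rows)


def price_threshold(runner, wtp: float, bounds=(0.0, 50000.0), xtol: float = 0.001) -> float:
    """Intervention drug price per cycle at which the ICUR equals ``wtp``.

    The incremental cost is affine in the per-cycle price while dQALY is
    unaffected, so ICUR is monotone in price and the root is unique; solved
    by scalar root bracketing to well below one cent.
    """
    def gap(price: float) -> float:
        result = runner.run(econ=replace(runner.econ, mirv_drug_cost=price))
        if result.icur is None:
            # dominance at this price: negative incremental cost
            return result.dcost / result.dqaly - wtp
        return result.icur - wtp

    lo, hi = bounds
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo * g_hi > 0:
        raise ValueError(f"WTP {wtp} not bracketed by price bounds {bounds}")
    return float(optimize.brentq(gap, lo, hi, xtol=xtol))


def scenario_settings(runner, horizon_years=(5.0, 10.0), discounts=(0.0, 0.03, 0.05)) -> pd.DataFrame:
    """Rerun the full pipeline over alternative horizons and discount rates."""
    from .engine import ModelSettings
    from .transitions import DAYS_PER_YEAR

    rows = []
    for years in horizon_years:
        for rate in discounts:
            cycles = math.ceil(years * DAYS_PER_YEAR / runner.settings.cycle_days)
            settings = ModelSettings(
                cycle_days=runner.settings.cycle_days,
                horizon_cycles=cycles,
                annual_discount_rate=rate,
                half_cycle_correction=runner.settings.half_cycle_correction,
            )
            result = runner.run(settings=settings)
            rows.append(
                {
                    "horizon_years": years,
                    "discount_rate": rate,
                    "dcost": result.dcost,
                    "dly": result.dly,
                    "dqaly": result.dqaly,
                    "icer": math.nan if result.icer is None else result.icer,
                    "icur": math.nan if result.icur is None else result.icur,
                }
            )
    return pd.DataFrame(rows)
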