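"""End-to-end model runner: fitted survival curves + life table + economic
inputs -> cohort traces and incremental cost-effectiveness results.

This is the single object every analysis layer (base case, tornado,
bivariate utilities, threshold search, probabilistic sensitivity analysis)
drives, each with its own parameter overrides, so that all of them share one
code path through the Markov engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import engine, transitions
from .analysis import CEResult, incremental
from .economics import EconomicInputs
from .engine import ModelSettings
from .survival import ParametricSurvivalFitter, ParametricSurvivalModel
from .synthetic import ARMS, ENDPOINTS

__all__ = ["ModelRunner", "fit_survival_models"]


def fit_survival_models(km_tables: dict) -> tuple[dict, dict]:
    """Fit and select a parametric model per (arm, endpoint) KM table.

    Returns ``(models, rankings)``: the selected ParametricSurvivalModel and
    the per-curve family ranking table, both keyed by (arm, endpoint).
    """
    models, rankings = {}, {}
    for key, table in km_tables.items():
        fitter = ParametricSurvivalFitter().fit(table)
        models[key] = fitter.model_
        rankings[key] = fitter.ranking_
    return models, rankings


@dataclass
class ModelRunner:
    """Deterministic pipeline for one two-arm comparison.

    ``models`` maps (arm, endpoint) -> ParametricSurvivalModel for arms
    ("mirv", "standard") and endpoints ("pfs", "os").  ``life_table`` is a
    DataFrame(age, annual_death_prob); set ``use_background=False`` to drop
    natural mortality (used by oracle tests).
    """

    models: dict
    life_table: pd.DataFrame | None
    econ: EconomicInputs
    settings: ModelSettings = field(default_factory=ModelSettings)
    start_age: float = 64.0
    wtp_grid: tuple = (151833.0, 155499.0, 310998.0, 466497.0)
    use_background: bool = True

    @classmethod
    def from_config(
        cls, config: dict, models: dict, life_table: pd.DataFrame
    ) -> "ModelRunner":
        model_cfg = config["model"]
        cycle_days = float(model_cfg["cycle_days"])
        horizon_cycles = int(
            np.ceil(model_cfg["horizon_years"] * transitions.DAYS_PER_YEAR / cycle_days)
        )
        settings = ModelSettings(
            cycle_days=cycle_days,
            horizon_cycles=horizon_cycles,
            annual_discount_rate=model_cfg["annual_discount_rate"],
            half_cycle_correction=model_cfg.get("half_cycle_correction", False),
        )
        return cls(
            models=models,
            life_table=life_table,
            econ=EconomicInputs.from_config(config),
            settings=settings,
            start_age=model_cfg.get("start_age", 64),
            wtp_grid=tuple(config["thresholds"]["wtp_grid"]),
        )

    # ------------------------------------------------------------------
    def background(self, settings: ModelSettings) -> np.ndarray:
        if not self.use_background or self.life_table is None:
            return np.zeros(settings.horizon_cycles)
        return transitions.background_mortality_per_cycle(
            self.life_table, self.start_age, settings.horizon_cycles, settings.cycle_days
        )

    def schedule(
        self,
        arm: str,
        settings: ModelSettings | None = None,
        multipliers: dict | None = None,
    ) -> transitions.TransitionSchedule:
        """Transition schedule for one arm, optionally perturbed by lognormal
        PSA multipliers {'mortality': m, 'progression': m} (applied to the
        death and progression probabilities respectively, then re-clipped)."""
        settings = settings or self.settings
        sched = transitions.build_schedule(
            self.models[(arm, "pfs")],
            self.models[(arm, "os")],
            self.background(settings),
            settings.horizon_cycles,
            settings.cycle_days,
        )
        if multipliers:
            m_mort = multipliers.get("mortality", 1.0)
            m_prog = multipliers.get("progression", 1.0)
            p_sd = np.clip(sched.p_sd * m_mort, 0.0, 1.0)
            p_pd = np.clip(sched.p_pd * m_mort, 0.0, 1.0)
            p_sp = np.clip(sched.p_sp * m_prog, 0.0, 1.0 - p_sd)
            sched = transitions.TransitionSchedule(
                p_sp=p_sp, p_sd=p_sd, p_pd=p_pd, cycle_days=sched.cycle_days
            )
        return sched

    def trace(
        self,
        arm: str,
        econ: EconomicInputs | None = None,
        settings: ModelSettings | None = None,
        multipliers: dict | None = None,
    ) -> engine.CohortTrace:
        econ = econ or self.econ
        settings = settings or self.settings
        sched = self.schedule(arm, settings, multipliers)
        costs = econ.cost_matrix(arm, settings.horizon_cycles)
        utilities = econ.utility_matrix(arm, settings.horizon_cycles)
        return engine.run(sched, costs, utilities, settings)

    def run(
        self,
        econ: EconomicInputs | None = None,
        settings: ModelSettings | None = None,
        multipliers: dict | None = None,
    ) -> CEResult:
        """Run both arms and return the incremental result (mirv vs standard)."""
        totals = {}
        for arm in ARMS:
            tr = self.trace(arm, econ, settings, multipliers)
            totals[arm] = {"cost": tr.total_cost, "ly": tr.total_ly, "qaly": tr.total_qaly}
        return incremental(totals["mirv"], totals["standard"], self.wtp_grid)

    def traces(self, **kwargs) -> dict:
        """Both arms' full cohort traces (for reports and audit CSVs)."""
        return {arm: self.trace(arm, **kwargs) for arm in ARMS}
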