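"""Synthetic trial inputs: digitized-style KM curves, a toy life table, and
the default configuration.

No individual-patient data are distributed with this package.  Instead, the
generator emulates what a digitizer extracts from published two-arm PFS/OS
Kaplan–Meier plots with roughly 24 months of follow-up: survival proportions
sampled on a monthly grid from known parametric ground truth, perturbed by
additive Gaussian "digitization" noise and projected back onto valid
(non-increasing, [0,1]) survival curves.  Default medians match the trial
the default configuration describes: PFS 5.62 vs 3.98 months and OS 16.46 vs
12.75 months, intervention arm log-logistic, comparator arm Weibull.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .survival import ParametricSurvivalModel

__all__ = [
    "SyntheticTrialSpec",
    "default_trial_spec",
    "generate_km_curves",
    "generate_life_table",
    "default_config",
    "ARMS",
    "ENDPOINTS",
]

ARMS = ("mirv", "standard")
ENDPOINTS = ("pfs", "os")

_LOG2 = np.log(2.0)


def _weibull_from_median(shape: float, median: float) -> ParametricSurvivalModel:
    return ParametricSurvivalModel("weibull", (shape, median / _LOG2 ** (1.0 / shape)))


@dataclass
class SyntheticTrialSpec:
    """Ground truth and sampling plan for a synthetic two-arm trial.

    ``pfs_truth`` / ``os_truth`` map arm name -> ParametricSurvivalModel.
    ``noise_sd`` is the additive Gaussian sd on the survival proportion
    (dimensionless); ``grid_step`` and ``followup_months`` are in months.
    """

    arm_names: tuple = ARMS
    pfs_truth: dict = field(default_factory=dict)
    os_truth: dict = field(default_factory=dict)
    followup_months: float = 24.0
    grid_step: float = 1.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.followup_months <= 0:
            raise ValueError("followup_months must be > 0")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def time_grid(self) -> np.ndarray:
        n = int(np.floor(self.followup_months / self.grid_step + 1e-9))
        return np.arange(n + 1) * self.grid_step


def default_trial_spec(noise_sd: float = 0.02, seed: int = 0) -> SyntheticTrialSpec:
    """The stated synthetic world: log-logistic intervention arm, Weibull
    comparator arm, medians at the trial values, 24 monthly grid points.

    Log-logistic shape 1.8 and Weibull shape 1.3 give gently decelerating
    hazards typical of digitized oncology KM curves; with a common shape per
    arm the OS curve dominates PFS by construction.
    """
    pfs = {
        "mirv": ParametricSurvivalModel("loglogistic", (1.8, 5.62)),
        "standard": _weibull_from_median(1.3, 3.98),
    }
    os_ = {
        "mirv": ParametricSurvivalModel("loglogistic", (1.8, 16.46)),
        "standard": _weibull_from_median(1.3, 12.75),
    }
    return SyntheticTrialSpec(
        arm_names=ARMS, pfs_truth=pfs, os_truth=os_,
        followup_months=24.0, grid_step=1.0, noise_sd=noise_sd, seed=seed,
    )


def generate_km_curves(spec: SyntheticTrialSpec) -> dict:
    """Sample digitized-style KM tables from the spec's ground truth.

    Returns ``{(arm, endpoint): DataFrame(time_months, survival)}``.  The
    first point is always (0, 1).  Noise is additive Gaussian followed by an
    L2 isotonic (non-increasing) projection and clipping to [0, 1], so the
    output is always a valid survival curve; with ``noise_sd=0`` the truth is
    returned exactly.  Specs whose OS truth falls below the PFS truth anywhere
    on the grid are rejected.
    """
    t = spec.time_grid()
    rng = np.random.default_rng(spec.seed)
    iso = IsotonicRegression(increasing=False, y_min=0.0, y_max=1.0)

    # validate OS >= PFS on the grid before drawing anything
    for arm in spec.arm_names:
        s_pfs = spec.pfs_truth[arm].survival(t)
        s_os = spec.os_truth[arm].survival(t)
        if np.any(s_os < s_pfs - 1e-12):
            raise ValueError(f"OS truth below PFS truth for arm {arm!r}")

    out = {}
    for arm in spec.arm_names:
        for endpoint, truth in (("pfs", spec.pfs_truth[arm]), ("os", spec.os_truth[arm])):
            s = truth.survival(t)
            if spec.noise_sd > 0:
                s = s + rng.normal(0.0, spec.noise_sd, size=t.size)
                s = iso.fit_transform(t, s)
            s = np.clip(s, 0.0, 1.0)
            s[0] = 1.0
            out[(arm, endpoint)] = pd.DataFrame({"time_months": t, "survival": s})
    return out


def generate_life_table(
    start_age: float = 64,
    n_ages: int = 40,
    base_prob: float = 0.012,
    growth: float = 1.095,
) -> pd.DataFrame:
    """Toy period life table: geometric (Gompertz-like) annual death risk.

    annual_death_prob(age) = min(base_prob * growth**(age - start_age), 1).
    Defaults approximate a German female table around age 64, where the
    annual death probability is roughly 1.2% and grows ~9-10% per year of
    age.  Returns a DataFrame with columns ``age`` and ``annual_death_prob``.
    """
    if not 0 < base_prob < 1:
        raise ValueError("base_prob must be in (0, 1)")
    if growth < 1:
        raise ValueError("growth must be >= 1")
    if n_ages < 1:
        raise ValueError("n_ages must be >= 1")
    ages = start_age + np.arange(n_ages)
    probs = np.minimum(base_prob * growth ** np.arange(n_ages), 1.0)
    return pd.DataFrame({"age": ages, "annual_death_prob": probs})


# ---------------------------------------------------------------------------
# Default configuration (base-case inputs)
# ---------------------------------------------------------------------------

#: Per-episode inpatient (DRG) costs are not printed directly; they are
#: implied by the per-cycle cell and the incidence via
#: per_cycle = incidence * drg_cost / amortization_months.
_DEFAULT_CONFIG = {
    "model": {
        "cycle_days": 28,
        "horizon_years": 5.0,
        "annual_discount_rate": 0.03,
        "half_cycle_correction": False,
        "start_age": 64,
    },
    "drugs": {
        # per 28-day treatment interval; the alternative 18281.66 appears in
        # some sources for the same interval and can be set here instead
        "mirv_cost_per_cycle": 18231.66,
        "standard_mode": "blended",  # blended | weighted
        "standard_blended_cost": 1276.83,
        "standard_components": [
            {"name": "paclitaxel", "cost": 519.77, "proportion": 0.41},
            {"name": "topotecan", "cost": 299.43, "proportion": 0.23},
            {"name": "pegylated_liposomal_doxorubicin", "cost": 457.63, "proportion": 0.36},
        ],
    },
    "monitoring": {
        "monitoring_per_cycle": 96.96,
        "imaging_early": 141.12,   # cycles 1-9 (1-based)
        "imaging_late": 70.56,     # cycle >= 10
        "imaging_switch_after_cycle": 9,
    },
    "premedication": {
        "mirv": 82.06,
        "standard": 27.93,
    },
    "adverse_events": {
        "amortization_months": 60,
        "arm_sizes": [227, 226],
        "significance_level": 0.05,
        "entries": [
            # grade >= 3 events; incidences are cumulative trial fractions
            {"name": "anemia", "incidence_mirv": 0.0088, "incidence_standard": 0.0929,
             "drg_cost": 0.50 * 60 / 0.0088},
            {"name": "neutropenia", "incidence_mirv": 0.0088, "incidence_standard": 0.1593,
             "drg_cost": 0.41 * 60 / 0.0088},
        ],
    },
    "utilities": {
        "stable": 0.61,
        "progressive": 0.50,
        "decline_per_cycle_mirv": 0.0,
        "decline_per_cycle_standard": 0.0,
    },
    "dsa": {
        "drug_multiplier": 0.50,
        "ae_multiplier": 0.25,
        "monitoring_multiplier": 0.25,
        "utility_multiplier": 0.20,
    },
    "psa": {
        "n_iterations": 10000,
        "transition_multiplier_sdlog": 0.10,
    },
    "thresholds": {
        "gdp_per_capita": 51833.0,
        "wtp_grid": [151833.0, 155499.0, 310998.0, 466497.0],
        "primary": 155499.0,
    },
}


def default_config() -> dict:
    """Deep copy of the base-case configuration (all euro amounts per 28-day
    cycle, utilities dimensionless, discounting annual)."""
    return copy.deepcopy(_DEFAULT_CONFIG)
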