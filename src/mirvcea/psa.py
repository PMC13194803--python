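"""First-order Monte Carlo probabilistic sensitivity analysis.

Parameter uncertainty is propagated by redrawing, in every iteration, the
cost inputs from gamma distributions (moment-matched to a mean and sd), the
state utilities from beta distributions (sd derived from a 95% CI
half-width), and two lognormal multiplicative factors (meanlog 0, sdlog 0.10
by default, roughly a +/-20% band) applied to the mortality- and
progression-type transition probabilities — each factor drawn once per
iteration and shared across cycles and arms.  The deterministic pipeline is
rerun per draw; summaries are the mean of per-iteration ICURs with a normal
95% CI, the ratio-of-means ICUR, and the cost-effectiveness acceptability
curve CEAC(WTP) = fraction of iterations with positive net monetary benefit.

The published spreads of the cost and utility distributions are not stated;
by default the deterministic sensitivity ranges are re-expressed as sds by
treating +/-range as a 95% interval (sd = multiplier * mean / 1.96).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .analysis import apply_param
from .economics import EconomicInputs

__all__ = [
    "PSAConfig",
    "PSAResult",
    "sample_cost",
    "sample_utility",
    "sample_transition_multiplier",
    "run_psa",
    "default_psa_config",
]


def sample_cost(mean: float, sd: float, rng: np.random.Generator, size=None):
    """Gamma draw(s) with the given mean and sd (shape = mean^2/sd^2,
    scale = sd^2/mean)."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be > 0")
    shape = mean**2 / sd**2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, size=size)


def sample_utility(mean: float, ci_halfwidth: float, rng: np.random.Generator, size=None):
    """Beta draw(s) with the given mean; sd = ci_halfwidth / 1.96.

    Moment matching: alpha = mean * (mean(1-mean)/sd^2 - 1) and beta the
    complementary weight.  Infeasible moments (sd^2 >= mean(1-mean)) are
    rejected.
    """
    if not 0 < mean < 1:
        raise ValueError("utility mean must lie in (0, 1)")
    if ci_halfwidth <= 0:
        raise ValueError("ci_halfwidth must be > 0")
    sd = ci_halfwidth / 1.96
    var = sd**2
    if var >= mean * (1.0 - mean):
        raise ValueError("infeasible beta moments: sd^2 >= mean(1-mean)")
    nu = mean * (1.0 - mean) / var - 1.0
    return rng.beta(mean * nu, (1.0 - mean) * nu, size=size)


def sample_transition_multiplier(sdlog: float, rng: np.random.Generator, size=None):
    """Lognormal multiplier(s) with meanlog 0 (median 1)."""
    if sdlog <= 0:
        raise ValueError("sdlog must be > 0")
    return rng.lognormal(0.0, sdlog, size=size)


@dataclass(frozen=True)
class PSAConfig:
    """Sampling plan: (name, mean, sd) cost triples -> gamma; (name, mean,
    95% CI half-width) utility triples -> beta; one transition-multiplier
    sdlog shared by the mortality and progression factors."""

    n_iterations: int = 10000
    seed: int = 0
    cost_params: tuple = ()       # (name, mean, sd); name understood by apply_param
    utility_params: tuple = ()    # (name, mean, ci_halfwidth)
    transition_multiplier_sdlog: float = 0.10
    wtp_grid: tuple = (151833.0, 155499.0, 310998.0, 466497.0)

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.transition_multiplier_sdlog <= 0:
            raise ValueError("transition_multiplier_sdlog must be > 0")


def default_psa_config(econ: EconomicInputs, config: dict, seed: int = 0) -> PSAConfig:
    """Sampling plan from the configuration: cost sds from the DSA ranges
    (sd = multiplier * mean / 1.96), utility half-widths at +/-20% of the
    mean, transition sdlog and iteration count from the psa section."""
    dsa = config["dsa"]
    psa_cfg = config["psa"]

    def sd(mean, mult):
        return mult * mean / 1.96

    monitoring_mean = econ.monitoring_per_cycle + econ.imaging_early
    ae_mean = sum(e.drg_cost for e in econ.adverse_events)
    premed_mean = sum(econ.premedication.values())
    cost_params = [
        ("mirv_drug_cost", econ.mirv_drug_cost, sd(econ.mirv_drug_cost, dsa["drug_multiplier"])),
        ("standard_drug_cost", econ.standard_blended_cost,
         sd(econ.standard_blended_cost, dsa["drug_multiplier"])),
        ("monitoring_cost", monitoring_mean, sd(monitoring_mean, dsa["monitoring_multiplier"])),
        ("premedication_cost", premed_mean, sd(premed_mean, dsa["ae_multiplier"])),
    ]
    if ae_mean > 0:
        cost_params.append(("ae_cost", ae_mean, sd(ae_mean, dsa["ae_multiplier"])))
    utility_params = [
        ("utility_stable", econ.utility_stable, dsa["utility_multiplier"] * econ.utility_stable),
        ("utility_progressive", econ.utility_progressive,
         dsa["utility_multiplier"] * econ.utility_progressive),
    ]
    return PSAConfig(
        n_iterations=psa_cfg.get("n_iterations", 10000),
        seed=seed,
        cost_params=tuple(cost_params),
        utility_params=tuple(utility_params),
        transition_multiplier_sdlog=psa_cfg.get("transition_multiplier_sdlog", 0.10),
        wtp_grid=tuple(config["thresholds"]["wtp_grid"]),
    )


@dataclass
class PSAResult:
    """Per-iteration increments and their summaries."""

    draws: pd.DataFrame           # iter, dcost, dqaly, icur (NaN if dqaly <= 0)
    mean_icur: float              # mean of per-iteration ICURs (dqaly > 0 only)
    ci_low: float
    ci_high: float
    ratio_of_means: float         # mean dcost / mean dqaly
    n_nonpositive_dqaly: int
    ceac: pd.DataFrame            # wtp, prob_ce

    def prob_cost_effective(self, wtp: float) -> float:
        row = self.ceac[self.ceac["wtp"] == wtp]
        if row.empty:
            raise KeyError(f"WTP {wtp} not in the configured grid")
        return float(row["prob_ce"].iloc[0])


def _substream(seed: int, name: str) -> np.random.Generator:
    # per-parameter substream keyed by a stable hash of the name, so adding a
    # parameter never reshuffles the draws of the others
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


def run_psa(runner, config: PSAConfig) -> PSAResult:
    """Monte Carlo over the full deterministic pipeline.

    Every iteration scales each named cost group to its gamma draw, replaces
    the state utilities with beta draws (shared across arms), applies the two
    lognormal transition multipliers, reruns both arms, and records the
    increments.  Iterations with dQALY <= 0 are excluded from the mean-ICUR
    summary but counted and retained in the CEAC.
    """
    n = config.n_iterations
    draws = {}
    for name, mean, sd in config.cost_params:
        draws[name] = sample_cost(mean, sd, _substream(config.seed, "cost:" + name), size=n)
    util_draws = {}
    for name, mean, hw in config.utility_params:
        util_draws[name] = sample_utility(mean, hw, _substream(config.seed, "util:" + name), size=n)
    mult_mort = sample_transition_multiplier(
        config.transition_multiplier_sdlog, _substream(config.seed, "mult:mortality"), size=n
    )
    mult_prog = sample_transition_multiplier(
        config.transition_multiplier_sdlog, _substream(config.seed, "mult:progression"), size=n
    )

    cost_means = {name: mean for name, mean, _ in config.cost_params}
    dcost = np.empty(n)
    dqaly = np.empty(n)
    for i in range(n):
        econ = runner.econ
        for name, values in draws.items():
            econ = apply_param(econ, name, values[i] / cost_means[name])
        for name, values in util_draws.items():
            econ = apply_param(econ, name, values[i] / getattr(runner.econ, name))
        result = runner.run(
            econ=econ,
            multipliers={"mortality": mult_mort[i], "progression": mult_prog[i]},
        )
        dcost[i] = result.dcost
        dqaly[i] = result.dqaly

    valid = dqaly > 0
    icur = np.where(valid, dcost / np.where(valid, dqaly, 1.0), np.nan)
    n_bad = int(np.sum(~valid))
    icur_valid = icur[valid]
    mean_icur = float(np.mean(icur_valid))
    se = float(np.std(icur_valid, ddof=1) / np.sqrt(icur_valid.size)) if icur_valid.size > 1 else 0.0

    ceac = pd.DataFrame(
        {
            "wtp": list(config.wtp_grid),
            "prob_ce": [float(np.mean(w * dqaly - dcost > 0)) for w in config.wtp_grid],
        }
    )
    return PSAResult(
        draws=pd.DataFrame({"iter": np.arange(n), "dcost": dcost, "dqaly": dqaly, "icur": icur}),
        mean_icur=mean_icur,
        ci_low=mean_icur - 1.96 * se,
        ci_high=mean_icur + 1.96 * se,
        ratio_of_means=float(np.mean(dcost) / np.mean(dqaly)),
        n_nonpositive_dqaly=n_bad,
        ceac=ceac,
    )
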