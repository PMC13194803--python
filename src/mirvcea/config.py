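"""Configuration loading, defaulting and validation.

The configuration is one YAML file with flat sections (model, drugs,
monitoring, premedication, adverse_events, utilities, dsa, psa, thresholds).
Absent keys fall back to the base-case defaults from
:func:`mirvcea.synthetic.default_config`; unknown keys and out-of-range
values are rejected with messages naming the offending key.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .synthetic import default_config

__all__ = ["ConfigError", "load_config", "validate_config", "merge_config"]


class ConfigError(ValueError):
    """A configuration key is unknown or violates its constraint."""


def merge_config(user: dict | None) -> dict:
    """Overlay a (possibly partial) user config on the defaults.

    Scalars override; dict sections merge one level deep; lists (drug
    components, adverse-event entries, the WTP grid) replace wholesale.
    Unknown sections or keys raise :class:`ConfigError`.
    """
    base = default_config()
    if not user:
        return base
    if not isinstance(user, dict):
        raise ConfigError("config root must be a mapping of sections")
    for section, values in user.items():
        if section not in base:
            raise ConfigError(f"unknown config section {section!r}")
        if not isinstance(values, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        for key, value in values.items():
            if key not in base[section]:
                raise ConfigError(f"unknown key {section}.{key}")
            base[section][key] = copy.deepcopy(value)
    return base


def _require(cond: bool, key: str, constraint: str):
    if not cond:
        raise ConfigError(f"{key}: {constraint}")


def validate_config(config: dict) -> dict:
    """Check every constraint the model relies on; returns the config."""
    m = config["model"]
    _require(m["cycle_days"] > 0, "model.cycle_days", "must be > 0")
    _require(m["horizon_years"] > 0, "model.horizon_years", "must be > 0")
    _require(m["annual_discount_rate"] >= 0, "model.annual_discount_rate", "must be >= 0")

    d = config["drugs"]
    _require(d["mirv_cost_per_cycle"] >= 0, "drugs.mirv_cost_per_cycle", "must be >= 0")
    _require(
        d["standard_mode"] in ("blended", "weighted"),
        "drugs.standard_mode", "must be 'blended' or 'weighted'",
    )
    _require(d["standard_blended_cost"] >= 0, "drugs.standard_blended_cost", "must be >= 0")
    props = [c["proportion"] for c in d["standard_components"]]
    if d["standard_mode"] == "weighted":
        _require(
            abs(sum(props) - 1.0) <= 1e-9,
            "drugs.standard_components", "proportions must sum to 1",
        )
    for c in d["standard_components"]:
        _require(c["cost"] >= 0, f"drugs.standard_components[{c['name']}].cost", "must be >= 0")

    mon = config["monitoring"]
    for key in ("monitoring_per_cycle", "imaging_early", "imaging_late"):
        _require(mon[key] >= 0, f"monitoring.{key}", "must be >= 0")
    _require(
        mon["imaging_switch_after_cycle"] >= 1,
        "monitoring.imaging_switch_after_cycle", "must be >= 1",
    )

    for arm, value in config["premedication"].items():
        _require(value >= 0, f"premedication.{arm}", "must be >= 0")

    ae = config["adverse_events"]
    _require(ae["amortization_months"] > 0, "adverse_events.amortization_months", "must be > 0")
    _require(
        0 < ae["significance_level"] < 1,
        "adverse_events.significance_level", "must lie in (0, 1)",
    )
    for entry in ae["entries"]:
        for field in ("incidence_mirv", "incidence_standard"):
            _require(
                0 <= entry[field] <= 1,
                f"adverse_events.entries[{entry['name']}].{field}", "must lie in [0, 1]",
            )
        _require(
            entry["drg_cost"] >= 0,
            f"adverse_events.entries[{entry['name']}].drg_cost", "must be >= 0",
        )

    u = config["utilities"]
    for key in ("stable", "progressive"):
        _require(0 <= u[key] <= 1, f"utilities.{key}", "must lie in [0, 1]")
    for key in ("decline_per_cycle_mirv", "decline_per_cycle_standard"):
        _require(u[key] >= 0, f"utilities.{key}", "must be >= 0")

    for key, value in config["dsa"].items():
        _require(0 < value < 1, f"dsa.{key}", "must lie in (0, 1)")

    p = config["psa"]
    _require(p["n_iterations"] >= 1, "psa.n_iterations", "must be >= 1")
    _require(p["transition_multiplier_sdlog"] > 0, "psa.transition_multiplier_sdlog", "must be > 0")

    t = config["thresholds"]
    grid = list(t["wtp_grid"])
    _require(all(w > 0 for w in grid), "thresholds.wtp_grid", "values must be > 0")
    _require(grid == sorted(grid), "thresholds.wtp_grid", "values must be increasing")
    _require(t["gdp_per_capita"] > 0, "thresholds.gdp_per_capita", "must be > 0")
    _require(t["primary"] in grid, "thresholds.primary", "must be one of wtp_grid")
    return config


def load_config(path: str | Path | None = None) -> dict:
    """Read a YAML config (or none for pure defaults), merge and validate."""
    user = None
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        user = yaml.safe_load(text)
    return validate_config(merge_config(user))
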