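"""CSV readers/writers for every pipeline artifact, plus the run manifest.

All CSVs are UTF-8 with dot decimals and no currency symbols (locale-proof).
Euro amounts are written at full precision; presentation rounding to cents
happens only in the human-readable report.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_km_csv",
    "write_km_csv",
    "read_life_table_csv",
    "write_life_table_csv",
    "write_fit_report",
    "write_schedule_csv",
    "write_trace_csv",
    "write_manifest",
    "km_filename",
]

KM_COLUMNS = ["time_months", "survival"]
LIFE_COLUMNS = ["age", "annual_death_prob"]


def km_filename(arm: str, endpoint: str) -> str:
    return f"km_{arm}_{endpoint}.csv"


def read_km_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in KM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if np.any((df["survival"] < 0) | (df["survival"] > 1)):
        raise ValueError(f"{path}: survival outside [0, 1]")
    if np.any(df["time_months"] < 0):
        raise ValueError(f"{path}: negative times")
    return df[KM_COLUMNS]


def write_km_csv(df: pd.DataFrame, path: str | Path) -> None:
    df[KM_COLUMNS].to_csv(path, index=False)


def read_life_table_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in LIFE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df[LIFE_COLUMNS]


def write_life_table_csv(df: pd.DataFrame, path: str | Path) -> None:
    df[LIFE_COLUMNS].to_csv(path, index=False)


def write_fit_report(rankings: dict, path: str | Path) -> None:
    """Concatenate the per-(arm, endpoint) family rankings into one CSV."""
    frames = []
    for (arm, endpoint), table in rankings.items():
        t = table.copy()
        t.insert(0, "arm", arm)
        t.insert(1, "endpoint", endpoint)
        frames.append(t)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_schedule_csv(schedules: dict, path: str | Path) -> None:
    """`arm,cycle,p_sp,p_sd,p_pd` audit table for all arms."""
    frames = [sched.to_frame(arm) for arm, sched in schedules.items()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_trace_csv(trace, path: str | Path) -> None:
    trace.to_frame().to_csv(path, index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(
    out_dir: str | Path,
    config: dict,
    seed: int | None = None,
    input_paths: list | None = None,
) -> Path:
    """Record everything needed to reproduce a run: the config hash, input
    checksums, the seed and the software version."""
    from . import __version__

    out_dir = Path(out_dir)
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "config_sha256": config_hash,
        "seed": seed,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": {
            str(p): _sha256(Path(p)) for p in (input_paths or []) if Path(p).exists()
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return path
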