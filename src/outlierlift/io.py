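"""Trial-table text format, run configuration, and pipeline plumbing."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .cohort import TRIAL_COLUMNS
from .conditions import CONDITION_NAMES

logger = logging.getLogger(__name__)

#: Versioned header comment written to trial-table files.
SCHEMA_VERSION = "outlierlift-trials-v1"

_NUMERIC_COLUMNS = {
    "trial": int,
    "block": int,
    "object_height_cm": float,
    "object_mass_g": float,
    "spring_length_cm": float,
    "response_time_s": float,
    "points": int,
}


def write_trials(tables: list[pd.DataFrame] | pd.DataFrame, path: str | Path) -> None:
    """Write one or several participant tables as UTF-8 delimited text."""
    df = pd.concat(tables, ignore_index=True) if isinstance(tables, list) else tables
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {SCHEMA_VERSION}\n")
        df[list(TRIAL_COLUMNS)].to_csv(fh, index=False)


def read_trials(path: str | Path) -> list[pd.DataFrame]:
    """Read a trial-table file back into per-participant tables.

    Malformed numeric cells are rejected with the 1-based file line number;
    a missing required column is rejected by name.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        has_header_comment = first.startswith("#")
    skip = 1 if has_header_comment else 0
    df = pd.read_csv(path, skiprows=skip, dtype=str)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s): {sorted(missing)}")
    offset = skip + 2  # comment line + header line, to 1-based data lines
    for col, typ in _NUMERIC_COLUMNS.items():
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + offset
            raise ValueError(
                f"{path}: malformed value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} at line {line}"
            )
        df[col] = converted.astype(typ)
    df["is_outlier"] = df["is_outlier"].map(
        {"True": True, "False": False, "true": True, "false": False, "1": True, "0": False}
    )
    if df["is_outlier"].isna().any():
        raise ValueError(f"{path}: malformed boolean in column 'is_outlier'")
    return [g.reset_index(drop=True) for _, g in df.groupby("participant", sort=True)]


class ComparisonConfig(BaseModel):
    """One condition-versus-reference directional test."""

    condition: str
    reference: str
    direction: str = Field(pattern="^(increase|decrease)$")


class CohortConfig(BaseModel):
    """Participant-level distribution for one simulated condition."""

    latent_ce_mean: float = 80.0
    latent_ce_sd: float = 20.0
    motor_noise_sd: float = 0.5
    learning_rate: float = 0.15
    category_update_gain: float = 0.01


class RunConfig(BaseModel):
    """End-to-end pipeline configuration (simulate -> exclude -> metric -> tests)."""

    conditions: list[str]
    seed: int = 0
    n_participants: int = 20
    cohorts: dict[str, CohortConfig] = {}
    comparisons: list[ComparisonConfig] = []
    bootstrap_reps: int = 1000
    output_dir: str | None = None

    @field_validator("conditions")
    @classmethod
    def _known(cls, v: list[str]) -> list[str]:
        unknown = [c for c in v if c not in CONDITION_NAMES]
        if unknown:
            raise ValueError(f"unknown condition(s): {unknown}")
        return v

    def cohort_config(self, condition: str) -> CohortConfig:
        return self.cohorts.get(condition, CohortConfig())
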