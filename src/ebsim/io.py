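"""CSV and YAML plumbing.

Conventions: weights in kg, energies in kcal, time in days internally and
weeks at the user surface; CSV with header (RFC-4180); deterministic float
formatting (6 significant digits) so outputs diff cleanly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import ModelConfig
from .errors import ConfigError, CsvParseError, SchemaError
from .evaluation import COHORT_COLUMNS
from .intake import IntakeSchedule
from .simulate import TRAJECTORY_COLUMNS, SolverOptions, Trajectory

logger = logging.getLogger("ebsim")

_REQUIRED_COHORT_COLUMNS = [c for c in COHORT_COLUMNS if c != "predicted_weight"]
_NUMERIC_COHORT_COLUMNS = ["week", "observed_weight", "predicted_weight", "w0",
                           "intervention_length"]
FLOAT_FORMAT = "%.6g"


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort table, validating schema and numeric cells.

    Raises :class:`SchemaError` for missing required columns and
    :class:`CsvParseError` naming the 1-based file line of the first
    malformed cell. A header-only file yields an empty table with a logged
    warning.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skip_blank_lines=False)
    missing = [c for c in _REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if df.empty:
        logger.warning("%s: cohort file contains a header but no rows", path)
        out = pd.DataFrame(columns=COHORT_COLUMNS)
        return out.astype({c: float for c in _NUMERIC_COHORT_COLUMNS})

    out = pd.DataFrame({"subject_id": df["subject_id"].astype(str)})
    for col in _NUMERIC_COHORT_COLUMNS:
        if col not in df.columns:
            out[col] = np.nan
            continue
        raw = df[col]
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() & raw.notna() & (raw.str.strip() != "")
        if bad.any():
            row = int(bad.idxmax())
            # +2: header line plus 1-based numbering
            raise CsvParseError(
                f"{path}: non-numeric value {raw[row]!r} in column "
                f"{col!r} on line {row + 2}"
            )
        out[col] = parsed
    out["week"] = out["week"].astype(int)
    out["intervention_length"] = out["intervention_length"].astype(int)
    if (out["observed_weight"] <= 0).any():
        row = int((out["observed_weight"] <= 0).idxmax())
        raise CsvParseError(
            f"{path}: non-positive observed_weight on line {row + 2}"
        )
    return out[COHORT_COLUMNS]


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    table[COHORT_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory with fixed column order; refuses NaN values."""
    frame = traj.to_frame()
    if frame.isna().any().any():
        raise CsvParseError("trajectory contains NaN values; refusing to write")
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_trajectory_csv(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing trajectory columns {missing}")
    return Trajectory(**{c: df[c].to_numpy(float) for c in TRAJECTORY_COLUMNS})


@dataclass(frozen=True)
class LoggingConfig:
    level: str = "INFO"
    destination: str = "stderr"  # or a file path


@dataclass(frozen=True)
class RunConfig:
    """Everything a simulation/evaluation run needs, loadable from YAML."""

    model: ModelConfig = field(default_factory=ModelConfig)
    schedule: IntakeSchedule = field(default_factory=IntakeSchedule.vled_default)
    solver: SolverOptions = field(default_factory=SolverOptions)
    logging: LoggingConfig = field(default_factory=LoggingConfig)

    def to_dict(self) -> dict:
        solver = dataclasses.asdict(self.solver)
        if np.isinf(solver["max_step"]):
            solver["max_step"] = ".inf"
        return {
            "model": self.model.to_dict(),
            "schedule": self.schedule.to_dict(),
            "solver": solver,
            "logging": dataclasses.asdict(self.logging),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigError("run config must be a mapping")
        known = {"model", "schedule", "solver", "logging"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown run config sections: {sorted(unknown)}")
        model = ModelConfig.from_dict(data.get("model", {}))
        schedule = IntakeSchedule.from_dict(
            data.get("schedule", IntakeSchedule.vled_default().to_dict())
        )
        solver_data = dict(data.get("solver", {}))
        unknown = set(solver_data) - {"rtol", "atol", "max_step"}
        if unknown:
            raise ConfigError(f"unknown solver keys: {sorted(unknown)}")
        if solver_data.get("max_step") in (".inf", "inf"):
            solver_data["max_step"] = np.inf
        solver = SolverOptions(**solver_data)
        log_data = dict(data.get("logging", {}))
        unknown = set(log_data) - {"level", "destination"}
        if unknown:
            raise ConfigError(f"unknown logging keys: {sorted(unknown)}")
        return cls(
            model=model,
            schedule=schedule,
            solver=solver,
            logging=LoggingConfig(**log_data),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data or {})
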