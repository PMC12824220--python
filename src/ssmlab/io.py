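"""Trial-table CSV I/O and run configuration.

Trial tables are written as UTF-8 CSV with a fixed, documented column
order; omitted trials have ``response == "omitted"`` and an empty RT
field.  Configurations are YAML with strict key checking and documented
defaults matching the study constants (22 subjects, 160 trials,
EUR 0.10-0.80 value grid, 750 ms deadline, dt 0.005 for fitting and
0.001 for sampling).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .task import DESIGN_COLUMNS, REGRESSOR_COLUMNS, OUTCOME_COLUMNS, DEFAULT_GRID

TRIAL_COLUMNS = DESIGN_COLUMNS + REGRESSOR_COLUMNS + OUTCOME_COLUMNS
VALID_RESPONSES = {"left", "right", "omitted"}


def write_trials(table: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table to CSV in the documented column order."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    table[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path: str | Path, deadline: float | None = 0.75) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Malformed rows are reported with (1-based, header-exclusive) line
    numbers; RTs above the deadline are flagged.  Omitted trials must
    carry an empty RT field and round-trip as NaN.
    """
    frame = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns: {missing}")
    problems = []
    bad_resp = ~frame["response"].isin(VALID_RESPONSES)
    for idx in frame.index[bad_resp][:10]:
        problems.append(f"line {idx + 1}: invalid response {frame.at[idx, 'response']!r}")
    numeric_cols = [c for c in TRIAL_COLUMNS if c not in ("response",)]
    for col in numeric_cols:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        for idx in frame.index[bad][:10]:
            problems.append(f"line {idx + 1}: non-numeric {col}={frame.at[idx, col]!r}")
        frame[col] = coerced
    omitted = frame["response"] == "omitted"
    for idx in frame.index[omitted & frame["rt"].notna()][:10]:
        problems.append(f"line {idx + 1}: omitted trial carries an RT")
    for idx in frame.index[~omitted & frame["rt"].isna()][:10]:
        problems.append(f"line {idx + 1}: responded trial has no RT")
    if deadline is not None:
        over = frame["rt"] > deadline
        for idx in frame.index[over][:10]:
            problems.append(
                f"line {idx + 1}: rt={frame.at[idx, 'rt']} exceeds deadline {deadline}"
            )
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    return frame


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class TaskConfig:
    n_subjects: int = 22
    n_trials: int = 160
    value_grid: list[float] = field(default_factory=lambda: list(DEFAULT_GRID))
    deadline_s: float = 0.75
    weighting_ratio: float = 1.0


@dataclass
class GeneratorConfig:
    model: str = "lca"
    params: dict[str, Any] = field(default_factory=dict)


@dataclass
class FittingConfig:
    model: str = "Original*"
    ibs_repeats: int = 1
    k_max: int = 128
    popsize: int = 4
    maxiter: int = 16
    n_restarts: int = 2
    polish_maxfev: int = 40
    bounds: dict[str, list[float]] = field(default_factory=dict)
    fit_dt: float = 0.005
    sample_dt: float = 0.001


@dataclass
class ComparisonConfig:
    n_sim: int = 100
    floor: float | None = None
    bootstrap_resamples: int = 10_000


@dataclass
class RunConfig:
    task: TaskConfig = field(default_factory=TaskConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    fitting: FittingConfig = field(default_factory=FittingConfig)
    comparison: ComparisonConfig = field(default_factory=ComparisonConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build_section(cls, data: dict, path: str, errors: list[str]):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    for key in sorted(unknown):
        errors.append(f"unknown key {path}.{key}")
    kwargs = {k: v for k, v in data.items() if k in fields}
    return cls(**kwargs)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run configuration, applying documented defaults.

    Unknown keys are rejected; all validation errors are aggregated into
    one message.  An empty (or absent) file yields the full default
    configuration.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: top level must be a mapping")
    if overrides:
        data = {**data, **overrides}
    errors: list[str] = []
    sections = {
        "task": TaskConfig,
        "generator": GeneratorConfig,
        "fitting": FittingConfig,
        "comparison": ComparisonConfig,
    }
    kwargs: dict[str, Any] = {}
    for name, cls in sections.items():
        sub = data.pop(name, {}) or {}
        if not isinstance(sub, dict):
            errors.append(f"section {name!r} must be a mapping")
            sub = {}
        kwargs[name] = _build_section(cls, sub, name, errors)
    seed = data.pop("seed", 0)
    for key in sorted(data):
        errors.append(f"unknown key {key}")
    cfg = RunConfig(seed=int(seed), **kwargs)
    if cfg.task.deadline_s <= 0:
        errors.append("task.deadline_s must be positive")
    if cfg.task.n_trials < 0 or cfg.task.n_subjects < 0:
        errors.append("task.n_trials and task.n_subjects must be nonnegative")
    if cfg.generator.model != "lca":
        from . import ddm as _ddm

        try:
            _ddm.model_registry(cfg.generator.model)
        except KeyError as err:
            errors.append(str(err))
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    return cfg


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, pd.DataFrame):
            return obj.to_dict(orient="records")
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        if isinstance(obj, tuple):
            return list(obj)
        return super().default(obj)


def write_json(obj: Any, path: str | Path) -> None:
    """Stable-key-ordered JSON for reports (diff-friendly)."""

    def _keyfix(o):
        if isinstance(o, dict):
            return {str(k): _keyfix(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [_keyfix(v) for v in o]
        return o

    Path(path).write_text(
        json.dumps(_keyfix(obj), indent=2, sort_keys=True, cls=_NumpyEncoder, default=str)
        + "\n"
    )
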