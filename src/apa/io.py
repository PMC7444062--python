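"""CSV table I/O, schemas, and configuration.

All files are UTF-8 CSV with required headers (order-insensitive).
Reaction times are stored as integer milliseconds in files and converted
to seconds in memory.  Row-level violations are collected with line
numbers rather than aborting the load; a missing required column is a
schema error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from apa.scoring import TrialResponse, VASResponse
from apa.task_schedule import TrialSchedule


class SchemaError(ValueError):
    """Header-level violation: missing or unreadable required columns."""


@dataclass(frozen=True)
class RowError:
    line: int  # 1-based physical line in the file (header = line 1)
    column: str
    message: str


def _to_int(s: str) -> int:
    return int(s)


def _to_float(s: str) -> float:
    return float(s)


def _to_bool(s: str) -> bool:
    v = s.strip().lower()
    if v in ("1", "true", "t", "yes"):
        return True
    if v in ("0", "false", "f", "no"):
        return False
    raise ValueError(f"not a boolean: {s!r}")


def _nonneg(x):
    if x < 0:
        raise ValueError(f"must be non-negative, got {x}")
    return x


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    converter: Callable[[str], Any] = str
    required: bool = True
    nullable: bool = False
    validator: Callable[[Any], Any] | None = None


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[ColumnSpec, ...]


CATALOG_SCHEMA = TableSchema(
    "catalog",
    (ColumnSpec("id"), ColumnSpec("label"), ColumnSpec("category")),
)

SCHEDULE_SCHEMA = TableSchema(
    "schedule",
    (
        ColumnSpec("block", _to_int),
        ColumnSpec("trial_index", _to_int),
        ColumnSpec("pair_id", _to_int),
        ColumnSpec("left_id"),
        ColumnSpec("right_id"),
        ColumnSpec("pair_type"),
    ),
)

TRIAL_SCHEMA = TableSchema(
    "trials",
    (
        ColumnSpec("participant_id"),
        ColumnSpec("session", _to_int),
        ColumnSpec("block", _to_int),
        ColumnSpec("trial_index", _to_int),
        ColumnSpec("pair_id", _to_int),
        ColumnSpec("left_id"),
        ColumnSpec("right_id"),
        ColumnSpec("chosen_id", nullable=True),
        ColumnSpec("rt_ms", _to_int, nullable=True, validator=_nonneg),
        ColumnSpec("responded", _to_bool),
    ),
)

VAS_SCHEMA = TableSchema(
    "vas",
    (
        ColumnSpec("participant_id"),
        ColumnSpec("session", _to_int),
        ColumnSpec("activity_id"),
        ColumnSpec("liking", _to_float),
        ColumnSpec("wanting", _to_float),
    ),
)

EPOCH_SCHEMA = TableSchema(
    "epochs",
    (
        ColumnSpec("timestamp"),
        ColumnSpec("counts", _to_int, validator=_nonneg),
        ColumnSpec("wear_state"),
    ),
)

OBSERVATION_SCHEMA = TableSchema(
    "observation",
    (
        ColumnSpec("interval_index", _to_int),
        ColumnSpec("code"),
        ColumnSpec("code_b", required=False, nullable=True),
    ),
)

FITNESS_SCHEMA = TableSchema(
    "fitness",
    (
        ColumnSpec("stage", _to_int),
        ColumnSpec("watts", _to_float),
        ColumnSpec("vo2_ml_kg_min", _to_float, nullable=True),
        ColumnSpec("rer", _to_float, nullable=True),
        ColumnSpec("hr", _to_float, nullable=True),
        ColumnSpec("rpe", _to_float, nullable=True),
    ),
)


def read_table(
    path: str | Path, schema: TableSchema
) -> tuple[pd.DataFrame, list[RowError]]:
    """Load and validate a CSV against a schema.

    Returns the typed records (rows with cell errors are dropped) and
    the list of row-level errors with 1-based line numbers.  Raises
    :class:`SchemaError` when a required column is absent.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [
        c.name for c in schema.columns if c.required and c.name not in raw.columns
    ]
    if missing:
        raise SchemaError(
            f"{schema.name} file {path}: missing required column(s) {missing}"
        )
    errors: list[RowError] = []
    records: list[dict[str, Any]] = []
    present = [c for c in schema.columns if c.name in raw.columns]
    for i, row in enumerate(raw.itertuples(index=False)):
        line = i + 2  # header occupies line 1
        rec: dict[str, Any] = {}
        ok = True
        for col in present:
            cell = getattr(row, col.name)
            if cell == "" or cell is None:
                if col.nullable:
                    rec[col.name] = None
                    continue
                errors.append(RowError(line, col.name, "missing value"))
                ok = False
                continue
            try:
                value = col.converter(cell)
                if col.validator is not None:
                    value = col.validator(value)
            except (ValueError, TypeError) as exc:
                errors.append(RowError(line, col.name, str(exc)))
                ok = False
                continue
            rec[col.name] = value
        if ok:
            records.append(rec)
    frame = pd.DataFrame(records, columns=[c.name for c in present])
    return frame, errors


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Load a cohort table; numeric columns parsed, ids kept as strings."""
    table = pd.read_csv(path)
    for col in ("participant_id", "sex", "race_group"):
        if col not in table.columns:
            raise SchemaError(f"cohort file {path}: missing column {col!r}")
    if table["participant_id"].duplicated().any():
        dupes = table.loc[table["participant_id"].duplicated(), "participant_id"]
        raise SchemaError(f"duplicate participant ids: {sorted(set(dupes))}")
    return table


# ---------------------------------------------------------------------------
# conversions between file rows and in-memory objects

def trials_to_frame(
    trials: Sequence[TrialResponse],
    schedule: TrialSchedule,
    participant_id: str = "SIM",
    session: int = 1,
) -> pd.DataFrame:
    """Trial log rows in file layout (RT as integer milliseconds)."""
    sched = schedule.to_frame().set_index("pair_id")
    rows = []
    for t in trials:
        s = sched.loc[t.pair_id]
        rows.append(
            {
                "participant_id": participant_id,
                "session": session,
                "block": int(s["block"]),
                "trial_index": int(s["trial_index"]),
                "pair_id": t.pair_id,
                "left_id": s["left_id"],
                "right_id": s["right_id"],
                "chosen_id": t.chosen if t.responded else "",
                "rt_ms": int(round(t.rt * 1000)) if t.responded else "",
                "responded": t.responded,
            }
        )
    return pd.DataFrame(rows)


def trials_from_frame(frame: pd.DataFrame) -> list[TrialResponse]:
    out = []
    for row in frame.itertuples(index=False):
        if row.responded:
            out.append(
                TrialResponse(int(row.pair_id), row.chosen_id, row.rt_ms / 1000.0)
            )
        else:
            out.append(TrialResponse(int(row.pair_id), None, None, responded=False))
    return out


def vas_to_frame(
    responses: Sequence[VASResponse],
    participant_id: str = "SIM",
    session: int = 1,
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "session": session,
            "activity_id": [r.activity_id for r in responses],
            "liking": [r.liking for r in responses],
            "wanting": [r.wanting for r in responses],
        }
    )


def vas_from_frame(frame: pd.DataFrame) -> list[VASResponse]:
    return [
        VASResponse(r.activity_id, float(r.liking), float(r.wanting))
        for r in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class RunConfig:
    """Run-wide options; unknown keys in a config file are rejected."""

    seed: int = 0
    min_rt: float = 0.2
    max_rt: float = 10.0
    no_clean: bool = False
    wear_min_days: int = 4
    wear_min_hours: float = 10.0
    wear_min_weekend_days: int = 1
    verbosity: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_rt < self.max_rt:
            raise ValueError("need 0 < min_rt < max_rt")
        if self.wear_min_days < 1 or self.wear_min_hours <= 0:
            raise ValueError("wear thresholds out of domain")


def load_run_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    allowed = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def load_cohort_spec(path: str | Path):
    """Build a CohortSpec from a nested YAML config.

    Recognized top-level keys: ``n``, ``seed``, ``female_fraction``,
    ``white_fraction``, ``age_range`` and ``variables`` (a mapping of
    variable name to mean/sd/loading/loading_girls/observed_fraction
    overrides of the defaults).
    """
    from apa.respondent_sim import CohortSpec, VariableSpec, default_variables

    data = yaml.safe_load(Path(path).read_text()) or {}
    allowed = {"n", "seed", "female_fraction", "white_fraction", "age_range", "variables"}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    variables = default_variables()
    for name, over in (data.pop("variables", None) or {}).items():
        base = variables.get(name)
        fields = {
            "mean": base.mean if base else 0.0,
            "sd": base.sd if base else 1.0,
            "loading": base.loading if base else 0.0,
            "loading_girls": base.loading_girls if base else None,
            "observed_fraction": base.observed_fraction if base else 1.0,
        }
        bad = set(over) - set(fields)
        if bad:
            raise ValueError(f"unknown keys for variable {name!r}: {sorted(bad)}")
        fields.update(over)
        variables[name] = VariableSpec(**fields)
    if "age_range" in data:
        data["age_range"] = tuple(data["age_range"])
    return CohortSpec(variables=variables, **data)
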