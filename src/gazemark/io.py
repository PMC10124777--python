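"""Reading, writing, and validating the pipeline's delimited-text tables."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GAZE_COLUMNS = [
    "participant_id",
    "group",
    "timepoint",
    "day",
    "task",
    "trial",
    "t_ms",
    "x_px",
    "y_px",
    "pupil_au",
    "tracked_flag",
]
PUPIL_COLUMNS = [
    "participant_id",
    "group",
    "timepoint",
    "day",
    "task",
    "trial",
    "t_ms",
    "pupil_au",
]
_GAZE_SORT = ["participant_id", "timepoint", "day", "task", "trial", "t_ms"]
# fields that must parse for a row to be usable; x/y/pupil may be missing
_REQUIRED_NUMERIC = ["timepoint", "day", "trial", "t_ms", "tracked_flag"]


class DataError(ValueError):
    """Raised for malformed or missing input data."""


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_gaze_table(path, pupil_only: bool = False) -> Tuple[pd.DataFrame, int]:
    """Load and validate a gaze (or pupil) sample table.

    Returns ``(table, n_malformed)``; malformed rows (unparseable required
    fields) are dropped and counted.  Missing columns and empty files are
    hard errors.
    """
    columns = PUPIL_COLUMNS if pupil_only else GAZE_COLUMNS
    try:
        df = pd.read_csv(path, dtype=str)
    except (pd.errors.EmptyDataError, FileNotFoundError) as err:
        raise DataError(f"cannot read sample table {path}: {err}") from err
    for col in columns:
        if col not in df.columns:
            raise DataError(f"sample table {path} missing column {col!r}")
    if df.empty:
        raise DataError(f"sample table {path} has no rows")

    numeric = [c for c in columns if c not in ("participant_id", "group", "task")]
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    required = [c for c in _REQUIRED_NUMERIC if c in df.columns]
    bad = df[required].isna().any(axis=1) | df["participant_id"].isna()
    n_malformed = int(bad.sum())
    if n_malformed:
        logger.warning("dropping %d malformed rows from %s", n_malformed, path)
        df = df[~bad]
    if df.empty:
        raise DataError(f"sample table {path} has no valid rows")

    for col in ("timepoint", "day", "trial", "tracked_flag"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    sort_cols = [c for c in _GAZE_SORT if c in df.columns]
    df = df.sort_values(sort_cols, kind="stable").reset_index(drop=True)
    return df[columns], n_malformed


def read_clinical_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as err:
        raise DataError(f"cannot read clinical table {path}: {err}") from err
    for col in ("participant_id", "group", "age_years", "iq", "site"):
        if col not in df.columns:
            raise DataError(f"clinical table missing column {col!r}")
    return df


def read_trials_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as err:
        raise DataError(f"cannot read trial table {path}: {err}") from err


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
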