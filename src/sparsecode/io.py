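"""Delimited-text readers and writers for every table the pipeline uses.

All files are plain CSV (comma default; tab accepted via ``sep``) with named
header rows.  Floats are written with ``repr`` round-trip precision so that
write-then-read is lossless.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    ArousalTrace,
    RESPONSE_LABELS,
    SpikeEventTable,
    TRIAL_COLUMNS,
    UNIT_COLUMNS,
    logger,
)


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class ValidationError(ValueError):
    """A row holds a value outside its documented bounds."""


_FLOAT_FORMAT = "%.17g"


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _check_bounds(df: pd.DataFrame, path) -> None:
    """Raise ValidationError naming the first offending row (1-based data row)."""
    checks = [
        ("contrast", lambda v: (v >= 0) & (v <= 1), "contrast outside [0, 1]"),
        ("duration_ms", lambda v: v > 0, "duration_ms must be > 0"),
        ("reaction_time_s", lambda v: np.isfinite(v) & (v >= 0),
         "reaction_time_s must be finite and >= 0"),
    ]
    for col, ok, msg in checks:
        if col not in df.columns:
            continue
        bad = ~ok(df[col].to_numpy())
        if np.any(bad):
            row = int(np.flatnonzero(bad)[0]) + 1
            raise ValidationError(f"{path}: row {row}: {msg} (value {df[col].iloc[row - 1]!r})")


def read_trials(path, sep: str = ",") -> pd.DataFrame:
    """Read a behavioral trial table (one row per 2AFC trial).

    Returns a DataFrame with TRIAL_COLUMNS.  Categorical fields are
    validated; out-of-bounds values raise :class:`ValidationError` naming
    the row; a header-only file returns an empty table with a warning.
    """
    df = pd.read_csv(path, sep=sep)
    _require_columns(df, TRIAL_COLUMNS, path)
    if len(df) == 0:
        logger.warning("%s: header only, no trials", path)
        return df[TRIAL_COLUMNS]
    _check_bounds(df, path)
    bad_resp = ~df["response"].isin(RESPONSE_LABELS)
    if bad_resp.any():
        row = int(np.flatnonzero(bad_resp)[0]) + 1
        raise ValidationError(f"{path}: row {row}: bad response {df['response'].iloc[row - 1]!r}")
    bad_ori = ~df["orientation_label"].isin(RESPONSE_LABELS + ("none",))
    if bad_ori.any():
        row = int(np.flatnonzero(bad_ori)[0]) + 1
        raise ValidationError(
            f"{path}: row {row}: bad orientation_label {df['orientation_label'].iloc[row - 1]!r}"
        )
    df = df[TRIAL_COLUMNS].copy()
    df["correct"] = df["correct"].astype(bool)
    return df


def write_trials(trials: pd.DataFrame, path, sep: str = ",") -> None:
    trials[TRIAL_COLUMNS].to_csv(path, sep=sep, index=False, float_format=_FLOAT_FORMAT)


def read_spikes(
    events_path, presentations_path, units_path, sep: str = ","
) -> tuple[SpikeEventTable, pd.DataFrame]:
    """Read the three cross-referenced physiology tables.

    Spikes whose ``unit_id`` is absent from the unit table are orphans:
    they are counted, logged, and dropped.  Duplicated presentation
    ``trial_index`` values and non-monotone per-unit spike times raise.
    """
    events = pd.read_csv(events_path, sep=sep)
    _require_columns(events, ["unit_id", "spike_time_s"], events_path)
    presentations = pd.read_csv(presentations_path, sep=sep)
    _require_columns(
        presentations,
        ["trial_index", "onset_time_s", "orientation_label", "contrast", "duration_ms"],
        presentations_path,
    )
    units = pd.read_csv(units_path, sep=sep)
    _require_columns(units, UNIT_COLUMNS, units_path)

    known = set(units["unit_id"])
    orphan = ~events["unit_id"].isin(known)
    if orphan.any():
        logger.warning("%s: dropped %d orphan spike(s) from unknown units",
                       events_path, int(orphan.sum()))
        events = events[~orphan].reset_index(drop=True)
    bundle = SpikeEventTable(events=events, presentations=presentations)
    return bundle, units


def write_spikes(bundle: SpikeEventTable, units: pd.DataFrame,
                 events_path, presentations_path, units_path, sep: str = ",") -> None:
    bundle.events.to_csv(events_path, sep=sep, index=False, float_format=_FLOAT_FORMAT)
    bundle.presentations.to_csv(presentations_path, sep=sep, index=False,
                                float_format=_FLOAT_FORMAT)
    units.to_csv(units_path, sep=sep, index=False, float_format=_FLOAT_FORMAT)


def read_arousal(path, sep: str = ",") -> ArousalTrace:
    df = pd.read_csv(path, sep=sep)
    _require_columns(df, ["time_s", "pupil_size"], path)
    speed = df["running_speed"].to_numpy() if "running_speed" in df.columns else None
    return ArousalTrace(time_s=df["time_s"].to_numpy(),
                        pupil_size=df["pupil_size"].to_numpy(),
                        running_speed=speed)


def write_arousal(trace: ArousalTrace, path, sep: str = ",") -> None:
    data = {"time_s": trace.time_s, "pupil_size": trace.pupil_size}
    if trace.running_speed is not None:
        data["running_speed"] = trace.running_speed
    pd.DataFrame(data).to_csv(path, sep=sep, index=False, float_format=_FLOAT_FORMAT)
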