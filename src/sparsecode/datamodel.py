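"""Core domain types shared by every analysis stage.

Tables (trials, spike events, stimulus presentations, unit metadata) are
plain pandas DataFrames with a documented column schema; small structured
results are dataclasses.  Conventions used throughout the package:

* times are in seconds, stimulus durations in milliseconds, electrode
  depths in micrometres;
* the two discriminanda are gratings tilted 45 degrees either side of
  vertical, encoded as ``orientation_label`` in ``{"left", "right"}`` with
  ``orientation_deg`` 135 and 45 respectively (vertical = 90 degrees);
* zero-contrast trials carry ``orientation_label == "none"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sparsecode")

#: orientation in degrees of the two discriminanda (45 deg off vertical)
ORIENTATION_DEG = {"left": 135.0, "right": 45.0}

RESPONSE_LABELS = ("left", "right")

TRIAL_COLUMNS = [
    "subject_id",
    "trial_index",
    "orientation_label",
    "orientation_deg",
    "contrast",
    "duration_ms",
    "response",
    "correct",
    "reaction_time_s",
]

UNIT_COLUMNS = [
    "unit_id",
    "session_id",
    "day",
    "electrode",
    "depth_um",
    "spike_width_ms",
    "mean_rate_hz",
    "is_single_unit",
]


@dataclass(frozen=True)
class StimulusCondition:
    """One cell of the stimulus grid: orientation x contrast x duration."""

    orientation_label: str  # {"left", "right", "none"}
    contrast: float
    duration_ms: float

    def __post_init__(self):
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be > 0")
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must lie in [0, 1]")
        if self.contrast == 0.0 and self.orientation_label != "none":
            raise ValueError("zero-contrast stimuli carry no orientation")
        if self.contrast > 0.0 and self.orientation_label not in RESPONSE_LABELS:
            raise ValueError(f"bad orientation_label {self.orientation_label!r}")

    @property
    def orientation_deg(self) -> float:
        return ORIENTATION_DEG.get(self.orientation_label, np.nan)


@dataclass
class SpikeEventTable:
    """Spike events plus the stimulus-presentation table they align to.

    ``events`` has columns (unit_id, spike_time_s), sorted within unit;
    ``presentations`` has one row per trial with columns
    (trial_index, onset_time_s, orientation_label, contrast, duration_ms).
    """

    events: pd.DataFrame
    presentations: pd.DataFrame

    def __post_init__(self):
        pres = self.presentations
        if pres["trial_index"].duplicated().any():
            dups = pres.loc[pres["trial_index"].duplicated(), "trial_index"]
            raise ValueError(f"duplicated trial_index values: {sorted(set(dups))}")
        for uid, grp in self.events.groupby("unit_id", sort=False):
            t = grp["spike_time_s"].to_numpy()
            if np.any(np.diff(t) < 0):
                raise ValueError(f"non-monotone spike times for unit {uid!r}")

    @property
    def unit_ids(self) -> list:
        return list(pd.unique(self.events["unit_id"]))


@dataclass
class SpikeCountMatrix:
    """Units x trials spike counts for one counting window.

    ``conditions`` is a DataFrame aligned with the trial axis carrying at
    least (trial_index, orientation_label, contrast, duration_ms).
    """

    counts: np.ndarray  # (n_units, n_trials) non-negative ints
    unit_ids: list
    conditions: pd.DataFrame
    window_start_ms: float
    window_end_ms: float

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (units x trials)")
        if self.window_end_ms <= self.window_start_ms:
            raise ValueError("window_end_ms must exceed window_start_ms")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")
        if self.counts.shape[0] != len(self.unit_ids):
            raise ValueError("unit_ids length does not match counts")
        if self.counts.shape[1] != len(self.conditions):
            raise ValueError("conditions length does not match counts")

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[1]

    def condition_key(self) -> pd.Series:
        """Per-trial hashable key (orientation_label, contrast, duration_ms)."""
        c = self.conditions
        return pd.Series(
            list(zip(c["orientation_label"], c["contrast"], c["duration_ms"])),
            index=c.index,
        )


@dataclass
class ArousalTrace:
    """Pupil-size (and optional running-speed) time series for a session."""

    time_s: np.ndarray
    pupil_size: np.ndarray
    running_speed: np.ndarray | None = None

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.pupil_size = np.asarray(self.pupil_size, dtype=float)
        if self.time_s.shape != self.pupil_size.shape:
            raise ValueError("time_s and pupil_size must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if self.running_speed is not None:
            self.running_speed = np.asarray(self.running_speed, dtype=float)
            if self.running_speed.shape != self.time_s.shape:
                raise ValueError("running_speed length mismatch")

    @property
    def dt_s(self) -> float:
        return float(np.median(np.diff(self.time_s)))


# ---------------------------------------------------------------------------
# layer assignment and duplicate-unit detection


def assign_layer(depth_um: float) -> str:
    """Assign a cortical layer label from electrode depth.

    Units above 400 um are superficial (L2/3), below 450 um deep (L5/6);
    depths in the 400-450 um gap between the two definitions are labelled
    ``ambiguous`` and excluded from layer contrasts.
    """
    if depth_um < 0:
        raise ValueError("depth_um must be >= 0")
    if depth_um < 400.0:
        return "superficial"
    if depth_um > 450.0:
        return "deep"
    return "ambiguous"


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    """Pearson r, or None when either vector has zero variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0.0 or b.std() == 0.0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def detect_duplicate_units(
    units: pd.DataFrame,
    waveforms: dict,
    isi_histograms: dict,
    r_threshold: float = 0.95,
) -> pd.DataFrame:
    """Identify units recorded on consecutive days that are the same cell.

    Chronic probes can pick up one neuron on several days.  Two units on the
    same electrode at the same depth on consecutive days whose mean waveforms
    AND interspike-interval histograms both correlate with Pearson r > 0.95
    are treated as duplicates; matches are closed transitively and only the
    earliest-day unit of each group is kept for analysis.

    Parameters
    ----------
    units : DataFrame with UNIT_COLUMNS.
    waveforms, isi_histograms : mapping unit_id -> 1-D vector.

    Returns
    -------
    DataFrame with columns (kept_unit, dropped_unit), one row per dropped
    duplicate.  Zero-variance vectors make the correlation undefined; such
    pairs are treated as non-duplicates with a warning.
    """
    units = units.sort_values(["electrode", "depth_um", "day"])
    parent: dict = {u: u for u in units["unit_id"]}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for (_, _), grp in units.groupby(["electrode", "depth_um"], sort=False):
        rows = list(grp.itertuples())
        for a in rows:
            for b in rows:
                if b.day != a.day + 1:
                    continue
                r_wf = _safe_pearson(waveforms[a.unit_id], waveforms[b.unit_id])
                r_isi = _safe_pearson(
                    isi_histograms[a.unit_id], isi_histograms[b.unit_id]
                )
                if r_wf is None or r_isi is None:
                    logger.warning(
                        "zero-variance waveform/ISI for pair (%s, %s); "
                        "treated as non-duplicate",
                        a.unit_id,
                        b.unit_id,
                    )
                    continue
                if r_wf > r_threshold and r_isi > r_threshold:
                    ra, rb = find(a.unit_id), find(b.unit_id)
                    if ra != rb:
                        parent[rb] = ra

    day_of = dict(zip(units["unit_id"], units["day"]))
    groups: dict = {}
    for u in units["unit_id"]:
        groups.setdefault(find(u), []).append(u)

    records = []
    for members in groups.values():
        if len(members) < 2:
            continue
        members = sorted(members, key=lambda u: (day_of[u], str(u)))
        kept = members[0]
        for dropped in members[1:]:
            records.append({"kept_unit": kept, "dropped_unit": dropped})
    out = pd.DataFrame(records, columns=["kept_unit", "dropped_unit"])
    logger.info(
        "duplicate-unit detection: %d units in, %d duplicates dropped",
        len(units),
        len(out),
    )
    return out


def drop_duplicate_units(units: pd.DataFrame, duplicates: pd.DataFrame) -> pd.DataFrame:
    """Remove the dropped side of every duplicate pair from a unit table."""
    return units[~units["unit_id"].isin(duplicates["dropped_unit"])].copy()
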