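"""Per-unit descriptive statistics: counting windows, response probability,
orientation tuning with jackknife errors, waveform classes, arousal split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import medfilt
from sklearn.cluster import KMeans

from .datamodel import ArousalTrace, SpikeCountMatrix, SpikeEventTable, logger


def count_spikes_in_window(events: SpikeEventTable,
                           window_start_ms: float = 0.0,
                           window_end_ms: float = 500.0,
                           unit_ids: list | None = None) -> SpikeCountMatrix:
    """Count spikes per unit x trial in [onset+start, onset+end).

    The interval is half-open.  If the window is longer than the spacing
    between consecutive presentations, overlapping windows are counted and
    a warning is emitted (spikes can then contribute to two trials).
    """
    pres = events.presentations.sort_values("trial_index").reset_index(drop=True)
    onsets = pres["onset_time_s"].to_numpy()
    starts = onsets + window_start_ms / 1e3
    ends = onsets + window_end_ms / 1e3
    n_overlap = int(np.sum(ends[:-1] > starts[1:])) if len(onsets) > 1 else 0
    if n_overlap:
        logger.warning("count window overlaps %d consecutive trial pair(s)",
                       n_overlap)
    if unit_ids is None:
        unit_ids = list(pd.unique(events.events["unit_id"]))
    counts = np.zeros((len(unit_ids), len(pres)), dtype=int)
    grouped = dict(list(events.events.groupby("unit_id", sort=False)))
    for i, uid in enumerate(unit_ids):
        if uid not in grouped:
            continue
        t = np.sort(grouped[uid]["spike_time_s"].to_numpy())
        counts[i] = np.searchsorted(t, ends, side="left") - \
            np.searchsorted(t, starts, side="left")
    cond_cols = ["trial_index", "orientation_label", "contrast", "duration_ms"]
    return SpikeCountMatrix(counts=counts, unit_ids=list(unit_ids),
                            conditions=pres[cond_cols].copy(),
                            window_start_ms=window_start_ms,
                            window_end_ms=window_end_ms)


def response_probability(counts: SpikeCountMatrix,
                         mask: np.ndarray | None = None,
                         by_condition: bool = False):
    """P(count >= 1) per unit, optionally per stimulus condition.

    With ``by_condition=True`` returns a DataFrame indexed by unit with one
    column per (orientation_label, contrast, duration_ms) cell; otherwise a
    per-unit vector over the (optionally masked) trials.
    """
    fired = counts.counts >= 1
    if not by_condition:
        if mask is not None:
            fired = fired[:, np.asarray(mask, dtype=bool)]
        return fired.mean(axis=1)
    key = counts.condition_key()
    out = {}
    for cond in sorted(key.unique()):
        sel = (key == cond).to_numpy()
        out[cond] = fired[:, sel].mean(axis=1)
    return pd.DataFrame(out, index=counts.unit_ids)


def responsive_fraction(counts: SpikeCountMatrix) -> np.ndarray:
    """Per-trial fraction of simultaneously recorded units with >= 1 spike."""
    if counts.n_units == 0:
        raise ValueError("need at least one unit")
    return (counts.counts >= 1).mean(axis=0)


@dataclass
class TuningResult:
    orientations_deg: np.ndarray
    mean_rates: np.ndarray
    osi: float
    pref_orientation_deg: float
    jackknife_sd_osi: float = np.nan
    jackknife_sd_pref_deg: float = np.nan


def osi_and_pref(orientations_deg, mean_rates,
                 method: str = "vector") -> TuningResult:
    """Orientation selectivity and preferred orientation from a tuning curve.

    ``method="vector"`` (default) is 1 - circular variance in doubled-angle
    space: osi = |sum_k R_k exp(2i theta_k)| / sum_k R_k, with the preferred
    orientation at half the argument of the vector sum, mapped to [0, 180).
    ``method="ratio"`` is the classic (Rpref - Rorth) / (Rpref + Rorth),
    with Rpref the peak of the measured curve.
    """
    theta = np.asarray(orientations_deg, dtype=float)
    rates = np.asarray(mean_rates, dtype=float)
    if len(theta) < 4:
        raise ValueError("need >= 4 orientations")
    if np.any(rates < 0):
        raise ValueError("rates must be >= 0")
    total = rates.sum()
    if total == 0:
        raise ValueError("all-zero rates: OSI undefined")
    z = np.sum(rates * np.exp(2j * np.deg2rad(theta)))
    pref = (np.rad2deg(np.angle(z)) / 2.0) % 180.0
    if method == "vector":
        osi = float(np.abs(z) / total)
    elif method == "ratio":
        i_pref = int(np.argmax(rates))
        orth = (theta[i_pref] + 90.0) % 180.0
        i_orth = int(np.argmin(np.abs(((theta - orth + 90) % 180) - 90)))
        denom = rates[i_pref] + rates[i_orth]
        osi = float((rates[i_pref] - rates[i_orth]) / denom) if denom else 0.0
    else:
        raise ValueError("method must be 'vector' or 'ratio'")
    return TuningResult(orientations_deg=theta, mean_rates=rates,
                        osi=osi, pref_orientation_deg=float(pref))


def jackknife_se(values, statistic=np.mean) -> float:
    """Leave-one-out jackknife standard error of an arbitrary statistic.

    For the sample mean this reduces exactly to s / sqrt(n) with s the
    ddof=1 sample standard deviation.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        raise ValueError("need >= 3 observations")
    reps = np.array([statistic(np.delete(values, i)) for i in range(n)])
    return float(np.sqrt((n - 1) / n * np.sum((reps - reps.mean()) ** 2)))


def jackknife_errors(orientations_deg, trial_rates,
                     method: str = "vector") -> tuple[float, float]:
    """Leave-one-trial-out jackknife errors of (OSI, preferred orientation).

    ``trial_rates`` is a sequence over orientations of per-trial rate
    arrays.  The preferred-orientation spread is circular (computed in
    doubled-angle space, reported in degrees of orientation).
    """
    trial_rates = [np.asarray(r, dtype=float) for r in trial_rates]
    if any(len(r) < 3 for r in trial_rates):
        raise ValueError("need >= 3 trials per orientation")
    theta = np.asarray(orientations_deg, dtype=float)
    osis, prefs = [], []
    for k, rates_k in enumerate(trial_rates):
        for j in range(len(rates_k)):
            means = np.array([
                (np.delete(r, j).mean() if i == k else r.mean())
                for i, r in enumerate(trial_rates)
            ])
            res = osi_and_pref(theta, means)
            osis.append(res.osi)
            prefs.append(res.pref_orientation_deg)
    n = len(osis)
    osis = np.asarray(osis)
    se_osi = np.sqrt((n - 1) / n * np.sum((osis - osis.mean()) ** 2))
    # circular spread of preferred orientations, doubled-angle space
    ang = np.deg2rad(2.0 * np.asarray(prefs))
    mean_dir = np.angle(np.mean(np.exp(1j * ang)))
    dev = np.angle(np.exp(1j * (ang - mean_dir)))  # wrapped to (-pi, pi]
    dev_deg = np.rad2deg(dev) / 2.0
    se_pref = np.sqrt((n - 1) / n * np.sum((dev_deg - dev_deg.mean()) ** 2))
    return float(se_osi), float(se_pref)


def classify_waveforms(units: pd.DataFrame, k: int = 2,
                       seed: int = 0) -> tuple[np.ndarray, pd.DataFrame]:
    """k-means split of units into fast- and regular-spiking classes.

    Features are standardized (spike_width_ms, log10 mean rate); the
    cluster with the smaller mean width is labelled ``fast``.  Returns
    (labels, cluster means in original units).
    """
    if len(units) < k:
        raise ValueError("need at least k units")
    width = units["spike_width_ms"].to_numpy(dtype=float)
    rate = units["mean_rate_hz"].to_numpy(dtype=float)
    feats = np.column_stack([width, np.log10(np.clip(rate, 1e-3, None))])
    mu, sd = feats.mean(axis=0), feats.std(axis=0)
    degenerate = np.any(sd == 0)
    sd = np.where(sd == 0, 1.0, sd)
    km = KMeans(n_clusters=k, n_init=50, random_state=seed)
    raw = km.fit_predict((feats - mu) / sd)
    if degenerate:
        logger.warning("classify_waveforms: degenerate features (zero variance)")
    mean_width = np.array([width[raw == c].mean() for c in range(k)])
    fast_cluster = int(np.argmin(mean_width))
    labels = np.where(raw == fast_cluster, "fast", "regular")
    means = pd.DataFrame({
        "label": ["fast" if c == fast_cluster else "regular" for c in range(k)],
        "spike_width_ms": mean_width,
        "mean_rate_hz": [rate[raw == c].mean() for c in range(k)],
    })
    return labels, means


@dataclass
class ArousalSplit:
    trial_labels: np.ndarray  # {"high", "low", "missing"} per trial
    z_trace: np.ndarray
    filter_window_s: float = 1.0


def arousal_split(trace: ArousalTrace, presentations: pd.DataFrame,
                  window_start_ms: float = 0.0, window_end_ms: float = 500.0,
                  filter_window_s: float = 1.0) -> ArousalSplit:
    """Label trials high/low arousal from the pupil trace.

    The pupil series is median-filtered (1 s window) and z-scored over the
    session; a trial is ``high`` iff the mean z over its counting window is
    strictly positive (ties at z = 0 go to ``low``).  Trials not fully
    covered by the trace are labelled ``missing``.
    """
    dt = trace.dt_s
    kernel = max(1, int(round(filter_window_s / dt)))
    if kernel % 2 == 0:
        kernel += 1
    smooth = medfilt(trace.pupil_size, kernel_size=kernel)
    sd = smooth.std()
    z = (smooth - smooth.mean()) / sd if sd > 0 else np.zeros_like(smooth)
    labels = []
    t = trace.time_s
    for rec in presentations.sort_values("trial_index").itertuples():
        lo = rec.onset_time_s + window_start_ms / 1e3
        hi = rec.onset_time_s + window_end_ms / 1e3
        if lo < t[0] or hi > t[-1]:
            labels.append("missing")
            continue
        sel = (t >= lo) & (t < hi)
        if not np.any(sel):
            labels.append("missing")
            continue
        labels.append("high" if z[sel].mean() > 0 else "low")
    return ArousalSplit(trial_labels=np.array(labels), z_trace=z,
                        filter_window_s=filter_window_s)
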