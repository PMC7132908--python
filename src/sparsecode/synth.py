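"""Synthetic behavioral streams and sparse V1 spike populations.

The generator supplies every downstream stage with data whose statistical
structure matches what the analysis assumes:

* behavior -- Bernoulli 2AFC outcomes from a logistic-with-lapse observer,
  with lognormal reaction times and a configurable trickle of RT outliers
  to exercise the exclusion filters;
* physiology -- spike *events* from an inhomogeneous Poisson process with
  three components per unit: a stationary background, an orientation-tuned
  onset transient supported on [latency, duration + 100 ms], and an
  untuned rebound after stimulus offset (V1 activity routinely outlasts
  short stimuli).  All components share a per-trial lognormal gain (doubly
  stochastic counts, hence over-dispersion and tunable noise correlations)
  and an arousal gain driven by a slow two-state process that also writes
  the pupil trace.

Orientation tuning is a von Mises bump in doubled-angle space.
"Informative" units prefer angles near the +/-45 deg discriminanda and so
respond differently to the two labels; uninformative units prefer the
cardinals (0/90 deg), which are exactly symmetric between the obliques --
their rates carry no label information by construction, while still giving
the population its cardinal orientation bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import (
    ORIENTATION_DEG,
    ArousalTrace,
    SpikeCountMatrix,
    SpikeEventTable,
    logger,
)
from .psychometrics import PsychometricModel, predict_performance
from .units import count_spikes_in_window


@dataclass(frozen=True)
class ObserverSpec:
    """Generating psychometric observer for one swept stimulus axis."""

    m: float
    omega: float
    lapse: float = 0.1
    guess: float = 0.5
    rt_median_s: float = 1.0
    rt_sigma: float = 0.5
    fast_outlier_rate: float = 0.001
    slow_outlier_rate: float = 0.005

    def __post_init__(self):
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.lapse + self.guess >= 1.0:
            raise ValueError("lapse + guess must be < 1")

    def performance(self, s) -> float:
        model = PsychometricModel(m=self.m, omega=self.omega,
                                  lapse=self.lapse, guess=self.guess)
        return predict_performance(model, s)


@dataclass(frozen=True)
class PopulationSpec:
    """Generative parameters of a simulated V1 session.

    Rates are in Hz, times in ms unless suffixed otherwise.  Evoked and
    rebound amplitudes are per-unit lognormal draws, given as (mu, sigma)
    of the underlying normal.
    """

    n_units: int = 20
    # stationary background rate distribution (lognormal, Hz)
    baseline_rate_lognorm: tuple[float, float] = (np.log(0.28), 1.0)
    # fraction of units with oblique-preferring (label-informative) tuning
    informative_fraction: float = 0.21
    # onset-transient amplitude (Hz at preferred orientation, full contrast)
    evoked_amp_informative_lognorm: tuple[float, float] = (np.log(1.12), 0.25)
    evoked_amp_uninformative_lognorm: tuple[float, float] = (np.log(0.45), 0.6)
    # untuned post-offset rebound amplitude (Hz)
    off_amp_lognorm: tuple[float, float] = (np.log(1.45), 0.8)
    # von Mises concentration in doubled-angle space (lognormal)
    kappa_lognorm: tuple[float, float] = (np.log(1.5), 0.4)
    pref_jitter_deg: float = 12.0
    # Naka-Rushton contrast gain, normalized to 1 at full contrast
    contrast_c50: float = 0.05
    contrast_exponent: float = 1.2
    # temporal supports (ms relative to stimulus onset / offset)
    onset_latency_ms: float = 50.0
    evoked_tail_ms: float = 100.0
    off_delay_ms: float = 120.0
    off_width_ms: float = 250.0
    # shared per-trial gain (lognormal sd of log-gain); 0 = independent units
    shared_gain_sd: float = 0.2
    # arousal: slow two-state process driving pupil and firing gain
    arousal_gain: float = 1.15
    arousal_dwell_s: float = 20.0
    arousal_pupil_sep: float = 1.0
    arousal_pupil_noise_sd: float = 0.25
    arousal_dt_s: float = 0.05
    trial_period_s: float = 2.0

    def __post_init__(self):
        if not 0.0 <= self.informative_fraction <= 1.0:
            raise ValueError("informative_fraction must lie in [0, 1]")
        if self.shared_gain_sd < 0 or self.arousal_gain < 1.0:
            raise ValueError("shared_gain_sd >= 0 and arousal_gain >= 1 required")

    def contrast_gain(self, contrast: float) -> float:
        if contrast <= 0:
            return 0.0
        c, c50, n = contrast, self.contrast_c50, self.contrast_exponent
        raw = c**n / (c**n + c50**n)
        full = 1.0 / (1.0 + c50**n)
        return raw / full


@dataclass(frozen=True)
class Preset:
    name: str
    observer: ObserverSpec
    population: PopulationSpec
    trial_schedule: pd.DataFrame


def default_schedule(n_per_condition: int = 45,
                     n_zero_contrast: int = 72) -> pd.DataFrame:
    """The study's short-stimulus grid: {0.15, 1} x {50..200 ms} x {left,right},
    plus zero-contrast (blank) trials spread over the same durations."""
    rows = []
    durations = [50.0, 100.0, 150.0, 200.0]
    for c in (0.15, 1.0):
        for d in durations:
            for lab in ("left", "right"):
                rows.append({"orientation_label": lab, "contrast": c,
                             "duration_ms": d, "n_trials": n_per_condition})
    per = n_zero_contrast // len(durations)
    for d in durations:
        rows.append({"orientation_label": "none", "contrast": 0.0,
                     "duration_ms": d, "n_trials": per})
    return pd.DataFrame(rows)


def behavior_schedule(durations_ms=(16, 32, 50, 75, 100, 150, 250, 500),
                      contrast: float = 1.0,
                      n_per_duration: int = 500) -> pd.DataFrame:
    rows = [{"contrast": contrast, "duration_ms": float(d),
             "n_trials": n_per_duration} for d in durations_ms]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# behavior


def simulate_behavior(observer: ObserverSpec, schedule: pd.DataFrame,
                      axis: str = "duration", seed: int = 0,
                      subject_id: str = "s0") -> pd.DataFrame:
    """Draw a 2AFC trial table from a logistic-with-lapse observer.

    ``schedule`` rows carry (contrast, duration_ms, n_trials); the swept
    stimulus strength is the column named by ``axis``.  Zero-contrast
    trials carry no information and are answered (and rewarded) at chance.
    """
    if len(schedule) == 0:
        raise ValueError("schedule must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for rec in schedule.itertuples():
        s = rec.duration_ms if axis == "duration" else rec.contrast
        p = observer.guess if rec.contrast == 0 else observer.performance(s)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"P(s) = {p} outside [0, 1]")
        for _ in range(int(rec.n_trials)):
            if rec.contrast == 0:
                label = "none"
                response = "left" if rng.random() < 0.5 else "right"
                correct = bool(rng.random() < 0.5)
            else:
                label = "left" if rng.random() < 0.5 else "right"
                correct = bool(rng.random() < p)
                flip = {"left": "right", "right": "left"}
                response = label if correct else flip[label]
            u = rng.random()
            if u < observer.fast_outlier_rate:
                rt = rng.uniform(0.005, 0.049)
            elif u < observer.fast_outlier_rate + observer.slow_outlier_rate:
                rt = rng.uniform(5.05, 9.0)
            else:
                rt = observer.rt_median_s * np.exp(
                    observer.rt_sigma * rng.standard_normal())
            rows.append({
                "subject_id": subject_id,
                "orientation_label": label,
                "orientation_deg": ORIENTATION_DEG.get(label, np.nan),
                "contrast": rec.contrast,
                "duration_ms": rec.duration_ms,
                "response": response,
                "correct": correct,
                "reaction_time_s": rt,
            })
    trials = pd.DataFrame(rows).sample(frac=1.0, random_state=rng.integers(2**31))
    trials = trials.reset_index(drop=True)
    trials.insert(1, "trial_index", np.arange(len(trials)))
    return trials


# ---------------------------------------------------------------------------
# population


def _tuning(theta_deg, pref_deg, kappa):
    """von Mises tuning in doubled-angle space, peak value 1."""
    delta = np.deg2rad(2.0 * (np.asarray(theta_deg, dtype=float) - pref_deg))
    return np.exp(kappa * (np.cos(delta) - 1.0))


def draw_units(pop: PopulationSpec, rng: np.random.Generator,
               session_id: str = "sess0", day: int = 1) -> pd.DataFrame:
    """Draw per-unit generative parameters plus recording-style metadata."""
    n = pop.n_units
    informative = rng.random(n) < pop.informative_fraction
    base = rng.lognormal(*pop.baseline_rate_lognorm, size=n)
    kappa = rng.lognormal(*pop.kappa_lognorm, size=n)
    pref = np.where(
        informative,
        (rng.choice([45.0, 135.0], size=n)
         + pop.pref_jitter_deg * rng.standard_normal(n)) % 180.0,
        rng.choice([0.0, 90.0], size=n),
    )
    amp = np.where(
        informative,
        rng.lognormal(*pop.evoked_amp_informative_lognorm, size=n),
        rng.lognormal(*pop.evoked_amp_uninformative_lognorm, size=n),
    )
    off_amp = rng.lognormal(*pop.off_amp_lognorm, size=n)
    fast = rng.random(n) < 0.3
    width = np.where(fast, rng.normal(0.26, 0.05, n), rng.normal(0.54, 0.08, n))
    return pd.DataFrame({
        "unit_id": [f"{session_id}_u{i:03d}" for i in range(n)],
        "session_id": session_id,
        "day": day,
        "electrode": [f"e{i % 8}" for i in range(n)],
        "depth_um": rng.uniform(100.0, 800.0, n),
        "spike_width_ms": np.clip(width, 0.07, 0.9),
        "mean_rate_hz": base,
        "is_single_unit": rng.random(n) < 0.45,
        "informative": informative,
        "baseline_hz": base,
        "evoked_amp_hz": amp,
        "off_amp_hz": off_amp,
        "kappa": kappa,
        "pref_deg": pref,
    })


def evoked_rate(unit, theta_deg, contrast: float, pop: PopulationSpec) -> float:
    """Onset-transient rate (Hz) of one unit row for a given stimulus."""
    if contrast <= 0:
        return 0.0
    return (unit.evoked_amp_hz * pop.contrast_gain(contrast)
            * _tuning(theta_deg, unit.pref_deg, unit.kappa))


def _arousal_process(pop: PopulationSpec, duration_s: float,
                     rng: np.random.Generator):
    """Two-state telegraph arousal: grid times, binary state, pupil trace."""
    dt = pop.arousal_dt_s
    t = np.arange(0.0, duration_s + dt, dt)
    state = np.zeros(len(t), dtype=int)
    cur = int(rng.random() < 0.5)
    next_switch = rng.exponential(pop.arousal_dwell_s)
    for i, ti in enumerate(t):
        while ti >= next_switch:
            cur = 1 - cur
            next_switch += rng.exponential(pop.arousal_dwell_s)
        state[i] = cur
    pupil = (pop.arousal_pupil_sep * state
             + pop.arousal_pupil_noise_sd * rng.standard_normal(len(t)))
    return t, state, pupil


def expand_schedule(schedule: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """One row per trial, in randomized order, with orientation degrees."""
    rows = schedule.loc[schedule.index.repeat(schedule["n_trials"])].drop(
        columns="n_trials")
    rows = rows.sample(frac=1.0, random_state=rng.integers(2**31))
    rows = rows.reset_index(drop=True)
    rows["trial_index"] = np.arange(len(rows))
    if "orientation_deg" not in rows.columns:
        rows["orientation_deg"] = [
            ORIENTATION_DEG.get(lab, np.nan) for lab in rows["orientation_label"]
        ]
    return rows


def simulate_session(pop: PopulationSpec, schedule: pd.DataFrame, seed: int = 0,
                     session_id: str = "sess0", day: int = 1,
                     window_ms: tuple[float, float] = (0.0, 500.0)):
    """Simulate one recording session at the spike-event level.

    Returns a dict with keys ``counts`` (SpikeCountMatrix for ``window_ms``),
    ``events`` (SpikeEventTable), ``units`` (per-unit table including
    generative parameters), and ``arousal`` (ArousalTrace).  Counts are
    obtained by windowing the generated events, so any other window is
    consistent with the same realization.
    """
    rng = np.random.default_rng(seed)
    units = draw_units(pop, rng, session_id=session_id, day=day)
    trials = expand_schedule(schedule, rng)
    n_trials = len(trials)
    period = pop.trial_period_s
    onsets = (1.0 + np.arange(n_trials) * period)
    trials["onset_time_s"] = onsets

    session_len = onsets[-1] + period + 1.0
    t_gr, state_gr, pupil = _arousal_process(pop, session_len, rng)
    arousal = ArousalTrace(time_s=t_gr, pupil_size=pupil)
    trial_state = state_gr[np.searchsorted(t_gr, onsets, side="right") - 1]
    trials["arousal_state"] = np.where(trial_state == 1, "high", "low")

    shared = np.exp(pop.shared_gain_sd * rng.standard_normal(n_trials)
                    - 0.5 * pop.shared_gain_sd**2)
    gain = shared * np.where(trial_state == 1, pop.arousal_gain, 1.0)

    theta = trials["orientation_deg"].to_numpy()
    contrast = trials["contrast"].to_numpy()
    dur = trials["duration_ms"].to_numpy()
    cgain = np.array([pop.contrast_gain(c) for c in contrast])

    ev_t0 = pop.onset_latency_ms / 1e3
    ev_t1 = (dur + pop.evoked_tail_ms) / 1e3
    off_t0 = (dur + pop.off_delay_ms) / 1e3
    off_t1 = off_t0 + pop.off_width_ms / 1e3

    all_uids, all_times = [], []
    n_clipped = 0
    for unit in units.itertuples():
        tun = np.where(contrast > 0,
                       _tuning(np.nan_to_num(theta), unit.pref_deg, unit.kappa),
                       0.0)
        comp = [
            (np.full(n_trials, unit.baseline_hz) * gain,
             np.zeros(n_trials), np.full(n_trials, period)),
            (unit.evoked_amp_hz * cgain * tun * gain, np.full(n_trials, ev_t0), ev_t1),
            (unit.off_amp_hz * cgain * gain, off_t0, off_t1),
        ]
        times = []
        for rate, t0, t1 in comp:
            neg = rate < 0
            if np.any(neg):
                n_clipped += int(neg.sum())
                rate = np.clip(rate, 0.0, None)
            mean = rate * (t1 - t0)
            counts = rng.poisson(mean)
            total = int(counts.sum())
            if total == 0:
                continue
            idx = np.repeat(np.arange(n_trials), counts)
            times.append(onsets[idx] + t0[idx]
                         + rng.random(total) * (t1[idx] - t0[idx]))
        if times:
            tt = np.sort(np.concatenate(times))
            all_times.append(tt)
            all_uids.extend([unit.unit_id] * len(tt))
    if n_clipped:
        logger.warning("simulate_session: clipped %d negative rates", n_clipped)

    events = pd.DataFrame({
        "unit_id": all_uids,
        "spike_time_s": np.concatenate(all_times) if all_times else np.array([]),
    })
    pres_cols = ["trial_index", "onset_time_s", "orientation_label",
                 "contrast", "duration_ms"]
    bundle = SpikeEventTable(events=events, presentations=trials[pres_cols])
    counts = count_spikes_in_window(bundle, window_start_ms=window_ms[0],
                                    window_end_ms=window_ms[1],
                                    unit_ids=list(units["unit_id"]))
    counts.conditions = counts.conditions.merge(
        trials[["trial_index", "orientation_deg", "arousal_state"]],
        on="trial_index")
    return {"counts": counts, "events": bundle, "units": units,
            "arousal": arousal, "trials": trials}


def simulate_population(pop: PopulationSpec, schedule: pd.DataFrame,
                        window_ms: tuple[float, float] = (0.0, 500.0),
                        seed: int = 0) -> SpikeCountMatrix:
    """Convenience wrapper returning only the spike-count matrix."""
    return simulate_session(pop, schedule, seed=seed, window_ms=window_ms)["counts"]


def simulate_tuning_trials(units: pd.DataFrame, pop: PopulationSpec,
                           rng: np.random.Generator,
                           orientations_deg=None, n_trials: int = 20,
                           duration_ms: float = 500.0,
                           window_s: float = 0.5) -> dict:
    """Trial-level spike counts for the orientation-tuning protocol
    (full-contrast flashed gratings over a 12-orientation grid).

    Returns {unit_id: (orientations, counts[n_ori, n_trials])}.
    """
    if orientations_deg is None:
        orientations_deg = np.arange(0.0, 180.0, 15.0)
    orientations_deg = np.asarray(orientations_deg, dtype=float)
    ev_len = min(duration_ms + pop.evoked_tail_ms,
                 window_s * 1e3) - pop.onset_latency_ms
    out = {}
    for unit in units.itertuples():
        tun = _tuning(orientations_deg, unit.pref_deg, unit.kappa)
        mean = (unit.baseline_hz * window_s
                + unit.evoked_amp_hz * tun * max(ev_len, 0.0) / 1e3)
        counts = rng.poisson(mean[:, None], size=(len(orientations_deg), n_trials))
        out[unit.unit_id] = (orientations_deg, counts)
    return out


# ---------------------------------------------------------------------------
# preset and calibration

#: Frozen default preset emulating the study conditions: the observer is the
#: average subject on the duration axis at low contrast, and the population
#: parameters are calibrated once against the printed summaries (responsive
#: fraction, per-trial spike probability, consistent-predictor prevalence
#: and performance) and then fixed.
V1_DEFAULT = Preset(
    name="v1_default",
    observer=ObserverSpec(m=45.0, omega=15.0, lapse=0.26),
    population=PopulationSpec(),
    trial_schedule=default_schedule(),
)


def calibration_report(pop: PopulationSpec | None = None, seed: int = 0,
                       n_sessions: int = 10,
                       schedule: pd.DataFrame | None = None,
                       protocol=None) -> pd.Series:
    """Measure the preset's headline population statistics end to end.

    Simulates ``n_sessions`` sessions, runs the measurement pipeline
    (responsive fraction in 0-500 ms, per-unit spike probability in the
    stimulus+100 ms window at the strongest condition, the repeated-split
    consistency rule), and reports each statistic with its Monte-Carlo SE.
    """
    from .decoding import SplitProtocol, fit_all_units
    from .units import response_probability, responsive_fraction

    pop = pop or V1_DEFAULT.population
    schedule = schedule if schedule is not None else V1_DEFAULT.trial_schedule
    protocol = protocol or SplitProtocol()
    rng = np.random.default_rng(seed)

    resp_frac, p_spike, consistent, perf_consistent = [], [], [], []
    for s in range(n_sessions):
        sess = simulate_session(pop, schedule, seed=int(rng.integers(2**31)),
                                session_id=f"cal{s:02d}")
        counts = sess["counts"]
        resp_frac.append(responsive_fraction(counts).mean())

        strongest = (counts.conditions["contrast"] == 1.0) & \
                    (counts.conditions["duration_ms"] == 200.0)
        window = (0.0, 200.0 + 100.0)
        stim100 = count_spikes_in_window(
            sess["events"], window_start_ms=window[0], window_end_ms=window[1],
            unit_ids=counts.unit_ids)
        probs = response_probability(stim100, mask=strongest.to_numpy())
        p_spike.append(np.nanmean(probs))

        results = fit_all_units(counts, protocol)
        for r in results:
            consistent.append(r.consistent)
            if r.consistent:
                perf_consistent.append(r.performance)

    def mc(x):
        x = np.asarray(x, dtype=float)
        return x.mean(), x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan

    rf, rf_se = mc(resp_frac)
    ps, ps_se = mc(p_spike)
    cf, cf_se = mc(consistent)
    pc, pc_se = mc(perf_consistent) if perf_consistent else (np.nan, np.nan)
    return pd.Series({
        "responsive_fraction": rf, "responsive_fraction_se": rf_se,
        "p_spike_strongest": ps, "p_spike_strongest_se": ps_se,
        "consistent_fraction": cf, "consistent_fraction_se": cf_se,
        "consistent_performance": pc, "consistent_performance_se": pc_se,
        "n_units": len(consistent),
    })
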