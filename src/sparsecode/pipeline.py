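"""End-to-end pipeline: simulate (or load) -> psychometrics -> unit
characterization -> decoding -> virtual-population curves -> required-N.

Every stage writes its table under the output directory; the final
``summary.yaml`` only collects numbers already present in stage CSVs.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .datamodel import assign_layer, logger
from .decoding import (SplitProtocol, consistency_summary, fit_all_units,
                       fit_population_decoder)
from .population import (build_pool, noise_model_requirement, population_curve,
                         required_population_size, shuffle_within_condition)
from .psychometrics import (average_subject, filter_trials, fit_psychometric,
                            total_integration_time)
from .synth import (V1_DEFAULT, behavior_schedule, calibration_report,
                    simulate_behavior, simulate_session, simulate_tuning_trials)
from .units import (arousal_split, classify_waveforms, osi_and_pref,
                    responsive_fraction)


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str
    preset: str = "v1_default"
    trials_path: str | None = None  # optional user-supplied behavior table
    n_sessions: int = 4
    n_behavior_trials_per_level: int = 400
    window_ms: tuple = (0.0, 500.0)
    n_splits: int = 100
    train_fraction: float = 0.7
    curve_sizes: tuple = (1, 2, 4, 8, 16, 32, 64, 128, 256)
    n_resamples: int = 200
    n_virtual_trials: int = 100
    behavioral_target: float = 0.74
    lapse: float = 0.2
    curve_condition: tuple = (1.0, 100.0)
    mcmc: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path, **overrides):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis sequence; returns the summary dict.

    Raises on stage failure after retaining partial outputs; the log names
    the failing stage.
    """
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh)
    if config.preset != "v1_default":
        raise ValueError(f"unknown preset {config.preset!r}")
    preset = V1_DEFAULT
    rng = np.random.default_rng(config.seed)
    summary: dict = {"seed": config.seed}

    # --- behavior ---------------------------------------------------------
    logger.info("stage: behavior")
    if config.trials_path:
        trials = sio.read_trials(config.trials_path)
    else:
        trials = simulate_behavior(
            preset.observer,
            behavior_schedule(n_per_duration=config.n_behavior_trials_per_level),
            axis="duration", seed=int(rng.integers(2**31)))
        sio.write_trials(trials, out / "trials.csv")
    kept, report = filter_trials(trials)
    fit = fit_psychometric(kept, axis="duration", mcmc=config.mcmc,
                           seed=int(rng.integers(2**31)))
    fit.posterior_samples.to_csv(out / "posterior_samples.csv", index=False)
    fit_rows = []
    for name in ("m", "omega", "lapse"):
        lo, hi = fit.ci95.get(name, (np.nan, np.nan))
        fit_rows.append({"parameter": name,
                         "map": getattr(fit.point_estimates, name),
                         "ci_low": lo, "ci_high": hi})
    T = total_integration_time(fit)
    fit_rows.append({"parameter": "total_integration_time_ms", "map": T,
                     "ci_low": np.nan, "ci_high": np.nan})
    pd.DataFrame(fit_rows).to_csv(out / "psychometric_fit.csv", index=False)
    summary["behavior"] = {
        "n_trials": report.n_input, "n_kept": report.n_kept,
        "threshold_integration_time_ms": float(fit.threshold),
        "total_integration_time_ms": float(T),
        "lapse": float(fit.point_estimates.lapse),
    }

    # --- physiology: simulate, characterize, decode -----------------------
    logger.info("stage: physiology")
    protocol = SplitProtocol(n_splits=config.n_splits,
                             train_fraction=config.train_fraction,
                             seed=int(rng.integers(2**31)))
    unit_rows, trial_rows, all_results = [], [], []
    pool = []
    pop_rows = []
    for s in range(config.n_sessions):
        sid = f"sess{s:02d}"
        sess = simulate_session(preset.population, preset.trial_schedule,
                                seed=int(rng.integers(2**31)), session_id=sid,
                                window_ms=tuple(config.window_ms))
        counts, units = sess["counts"], sess["units"]
        wf_labels, _ = classify_waveforms(units, seed=int(rng.integers(2**31)))
        tuning = simulate_tuning_trials(units, preset.population, rng)
        split = arousal_split(sess["arousal"], sess["trials"],
                              window_start_ms=config.window_ms[0],
                              window_end_ms=config.window_ms[1])
        results = fit_all_units(counts, protocol)
        all_results.extend(results)
        pool.extend(build_pool(counts, results, consistent_only=True))
        rf = responsive_fraction(counts)
        for i, rec in enumerate(units.itertuples()):
            ori, cts = tuning[rec.unit_id]
            tun = osi_and_pref(ori, cts.mean(axis=1))
            unit_rows.append({
                "unit_id": rec.unit_id, "session_id": sid,
                "mean_rate_hz": rec.mean_rate_hz,
                "spike_width_ms": rec.spike_width_ms,
                "waveform_class": wf_labels[i],
                "layer": assign_layer(rec.depth_um),
                "osi": tun.osi, "pref_orientation_deg": tun.pref_orientation_deg,
                "decoding_performance": results[i].performance,
                "consistent": results[i].consistent,
            })
        for j in range(counts.n_trials):
            trial_rows.append({
                "session_id": sid, "trial_index": j,
                "responsive_fraction": rf[j],
                "arousal_label": split.trial_labels[j],
            })
        pop_res = fit_population_decoder(
            counts, protocol, session_id=sid,
            n_consistent=sum(r.consistent for r in results))
        shuffled = shuffle_within_condition(counts, seed=int(rng.integers(2**31)))
        pop_shuf = fit_population_decoder(shuffled, protocol, session_id=sid)
        pop_rows.append({"session_id": sid, "n_units": pop_res.n_units,
                         "n_consistent": pop_res.n_consistent,
                         "performance": pop_res.performance,
                         "performance_shuffled": pop_shuf.performance})
    pd.DataFrame(unit_rows).to_csv(out / "units.csv", index=False)
    pd.DataFrame(trial_rows).to_csv(out / "trials_physiology.csv", index=False)
    pd.DataFrame(pop_rows).to_csv(out / "population_decoding.csv", index=False)
    cons = consistency_summary(all_results)
    cons.to_csv(out / "consistency_summary.csv", header=False)
    tr = pd.DataFrame(trial_rows)
    summary["physiology"] = {
        "n_units": int(cons["n_units"]),
        "fraction_consistent": float(cons["fraction_consistent"]),
        "mean_performance_consistent": float(cons["mean_performance_consistent"]),
        "mean_responsive_fraction": float(tr["responsive_fraction"].mean()),
        "fraction_high_arousal": float((tr["arousal_label"] == "high").mean()),
        "mean_population_performance": float(np.mean([r["performance"] for r in pop_rows])),
        "mean_population_performance_shuffled": float(
            np.mean([r["performance_shuffled"] for r in pop_rows])),
    }

    # --- virtual populations ---------------------------------------------
    logger.info("stage: virtual populations")
    if not pool:
        raise RuntimeError("virtual-population stage: no consistent units in pool")
    curve = population_curve(pool, config.curve_sizes, tuple(config.curve_condition),
                             n_trials=config.n_virtual_trials,
                             n_resamples=config.n_resamples,
                             seed=int(rng.integers(2**31)))
    pd.DataFrame({
        "n_units": curve.sizes, "median": curve.median_performance,
        "pct2_5": curve.pct2_5, "pct97_5": curve.pct97_5,
    }).to_csv(out / "population_curve.csv", index=False)
    req = required_population_size(curve, config.behavioral_target)
    req_cog = noise_model_requirement(curve, config.behavioral_target,
                                      config.lapse, "cognitive")
    pd.DataFrame([
        {"model": "sensory", "target": req.target, "n_median": req.n_median,
         "n_low": req.n_low, "n_high": req.n_high},
        {"model": "cognitive", "target": req_cog.target,
         "n_median": req_cog.n_median, "n_low": req_cog.n_low,
         "n_high": req_cog.n_high},
    ]).to_csv(out / "required_population.csv", index=False)
    summary["virtual_population"] = {
        "pool_size": len(pool),
        "behavioral_target": config.behavioral_target,
        "required_n_sensory": req.n_median,
        "required_n_cognitive": req_cog.n_median,
    }

    summary["runtime_s"] = round(time.time() - t_start, 1)
    with open(out / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    logger.info("pipeline complete in %.1f s", summary["runtime_s"])
    return summary
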