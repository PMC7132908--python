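"""Virtual-population simulation: performance vs number of pooled units.

Each recorded unit contributes (i) a response table -- its observed spike
counts indexed by stimulus condition -- and (ii) the logistic coefficients
fitted by the single-unit decoder.  A *virtual session* of size N draws N
units with replacement from the pool, simulates each trial by sampling
every unit's count from its own response table for that condition, and
combines the units as independent regressors: the summed per-unit
log-odds, sum_i (intercept_i + coef_i * x_i), predicts the label by sign.
Repeating over many resampled populations yields a performance-vs-N curve
(median and 95-percentile band), from which the population size required
to match a behavioral target is read off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import SpikeCountMatrix, logger
from .decoding import UnitDecoderResult

_LABELS = ("left", "right")


@dataclass
class VirtualUnit:
    """One pool member: condition-indexed responses plus decoder weights."""

    unit_id: object
    intercept: float
    coef: float
    responses: dict  # (orientation_label, contrast, duration_ms) -> int array
    consistent: bool = True


def build_pool(counts: SpikeCountMatrix, results: list[UnitDecoderResult],
               consistent_only: bool = True) -> list[VirtualUnit]:
    """Tabulate each unit's spike counts by stimulus condition and attach
    its fitted decoder coefficients.  By default only consistent
    predictors enter the pool."""
    key = counts.condition_key()
    by_cond = {cond: (key == cond).to_numpy() for cond in key.unique()}
    pool = []
    for i, res in enumerate(results):
        if consistent_only and not res.consistent:
            continue
        responses = {cond: counts.counts[i, sel] for cond, sel in by_cond.items()}
        pool.append(VirtualUnit(unit_id=res.unit_id,
                                intercept=res.intercept_mean,
                                coef=res.coefficient_mean,
                                responses=responses,
                                consistent=res.consistent))
    return pool


def _condition_keys(condition: tuple, pool: list[VirtualUnit]):
    """Response-table keys for the two labels of a (contrast, duration)
    condition; zero contrast maps both labels onto the blank-trial tables."""
    contrast, duration = condition
    if contrast == 0:
        blanks = [k for k in pool[0].responses if k[1] == 0]
        if not blanks:
            raise ValueError("pool holds no zero-contrast responses")
        return {lab: blanks for lab in _LABELS}
    return {lab: [(lab, contrast, duration)] for lab in _LABELS}


def filter_pool(pool: list[VirtualUnit], condition: tuple) -> list[VirtualUnit]:
    """Drop units with an empty response multiset for the condition."""
    keys = _condition_keys(condition, pool)
    kept = []
    for u in pool:
        ok = all(
            sum(len(u.responses.get(k, ())) for k in keys[lab]) > 0
            for lab in _LABELS
        )
        if ok:
            kept.append(u)
    if len(kept) < len(pool):
        logger.warning("filter_pool: excluded %d unit(s) with empty "
                       "response tables", len(pool) - len(kept))
    return kept


def _pack_pool(pool, condition):
    """Pad per-unit response multisets into dense arrays for fast sampling."""
    keys = _condition_keys(condition, pool)
    packed = {}
    for lab in _LABELS:
        arrs = [np.concatenate([np.asarray(u.responses.get(k, []), dtype=float)
                                for k in keys[lab]]) for u in pool]
        lens = np.array([len(a) for a in arrs])
        mat = np.zeros((len(pool), lens.max()))
        for i, a in enumerate(arrs):
            mat[i, :len(a)] = a
        packed[lab] = (mat, lens)
    intercepts = np.array([u.intercept for u in pool])
    coefs = np.array([u.coef for u in pool])
    return packed, intercepts, coefs


def simulate_virtual_sessions(pool: list[VirtualUnit], n_units: int,
                              condition: tuple, n_trials: int = 100,
                              n_resamples: int = 1, seed: int = 0,
                              rule: str = "logodds") -> np.ndarray:
    """Accuracies of ``n_resamples`` virtual sessions of ``n_units`` units.

    Each session draws units with replacement (each unit equally likely),
    simulates ``n_trials`` label-balanced trials by sampling counts from
    the units' response tables for the condition, and predicts the label
    from the summed per-unit log-odds (``rule="logodds"``) or a per-unit
    majority vote (``rule="vote"``); sums of exactly zero go to 'left'.
    """
    pool = filter_pool(pool, condition)
    if not pool:
        raise ValueError("empty pool after filtering")
    packed, intercepts, coefs = _pack_pool(pool, condition)
    rng = np.random.default_rng(seed)
    n_right = n_trials // 2
    n_left = n_trials - n_right
    units = rng.integers(0, len(pool), size=(n_resamples, n_units))
    accs = np.zeros(n_resamples)
    correct = np.zeros((n_resamples, n_trials), dtype=bool)
    for lab, sl, want in (("left", slice(0, n_left), 0),
                          ("right", slice(n_left, None), 1)):
        mat, lens = packed[lab]
        nt = n_left if want == 0 else n_right
        draw = (rng.random((n_resamples, n_units, nt))
                * lens[units][:, :, None]).astype(int)
        x = mat[units[:, :, None], draw]  # (R, N, nt)
        if rule == "logodds":
            logodds = (intercepts[units].sum(axis=1)[:, None]
                       + np.einsum("rn,rnt->rt", coefs[units], x))
            pred = (logodds > 0).astype(int)
        elif rule == "vote":
            votes = ((intercepts[units][:, :, None] + coefs[units][:, :, None] * x)
                     > 0).sum(axis=1)
            pred = (votes * 2 > n_units).astype(int)
        else:
            raise ValueError("rule must be 'logodds' or 'vote'")
        correct[:, sl] = pred == want
    accs = correct.mean(axis=1)
    return accs


def build_virtual_session(pool, n_units: int, condition: tuple,
                          n_trials: int = 100, seed: int = 0,
                          rule: str = "logodds") -> float:
    """Accuracy of a single virtual session (see simulate_virtual_sessions)."""
    return float(simulate_virtual_sessions(pool, n_units, condition,
                                           n_trials=n_trials, n_resamples=1,
                                           seed=seed, rule=rule)[0])


@dataclass
class PopulationCurve:
    sizes: np.ndarray
    median_performance: np.ndarray
    pct2_5: np.ndarray
    pct97_5: np.ndarray
    n_resamples: int
    condition: tuple
    accuracies: np.ndarray = field(repr=False, default=None)  # (sizes, resamples)


def population_curve(pool, sizes, condition: tuple, n_trials: int = 100,
                     n_resamples: int = 1000, seed: int = 0,
                     rule: str = "logodds") -> PopulationCurve:
    """Decoding performance vs population size N, with a 95-percentile band
    across independently resampled virtual sessions."""
    sizes = np.asarray(sorted(sizes), dtype=int)
    rng = np.random.default_rng(seed)
    accs = np.zeros((len(sizes), n_resamples))
    for j, n in enumerate(sizes):
        accs[j] = simulate_virtual_sessions(
            pool, int(n), condition, n_trials=n_trials,
            n_resamples=n_resamples, seed=int(rng.integers(2**31)), rule=rule)
    return PopulationCurve(
        sizes=sizes,
        median_performance=np.median(accs, axis=1),
        pct2_5=np.percentile(accs, 2.5, axis=1),
        pct97_5=np.percentile(accs, 97.5, axis=1),
        n_resamples=n_resamples,
        condition=condition,
        accuracies=accs,
    )


@dataclass
class RequiredN:
    n_median: int | None
    n_low: int | None   # optimistic bound (97.5th percentile curve)
    n_high: int | None  # conservative bound (2.5th percentile curve)
    target: float
    unreachable: bool


def _first_at_or_above(sizes, values, target):
    idx = np.flatnonzero(values >= target)
    return int(sizes[idx[0]]) if len(idx) else None


def required_population_size(curve: PopulationCurve,
                             behavioral_target: float) -> RequiredN:
    """Smallest population size whose median performance reaches the
    behavioral target; the interval reads the same criterion off the
    2.5/97.5-percentile curves."""
    if not 0.5 < behavioral_target < 1.0:
        raise ValueError("behavioral_target must lie in (0.5, 1)")
    n_med = _first_at_or_above(curve.sizes, curve.median_performance,
                               behavioral_target)
    n_low = _first_at_or_above(curve.sizes, curve.pct97_5, behavioral_target)
    n_high = _first_at_or_above(curve.sizes, curve.pct2_5, behavioral_target)
    return RequiredN(n_median=n_med, n_low=n_low, n_high=n_high,
                     target=behavioral_target, unreachable=n_med is None)


def shuffle_within_condition(counts: SpikeCountMatrix,
                             seed: int = 0) -> SpikeCountMatrix:
    """Destroy across-unit trial-to-trial correlations while preserving
    every unit's per-condition count distribution: per unit, permute
    counts among trials sharing identical stimulus parameters."""
    rng = np.random.default_rng(seed)
    key = counts.condition_key()
    shuffled = counts.counts.copy()
    for cond in key.unique():
        sel = np.flatnonzero((key == cond).to_numpy())
        for i in range(counts.n_units):
            shuffled[i, sel] = shuffled[i, sel[rng.permutation(len(sel))]]
    return SpikeCountMatrix(counts=shuffled, unit_ids=list(counts.unit_ids),
                            conditions=counts.conditions.copy(),
                            window_start_ms=counts.window_start_ms,
                            window_end_ms=counts.window_end_ms)


def cognitive_target(behavioral_performance: float, lapse: float) -> float:
    """Decoder accuracy needed when a lapse-rate fraction of trials is
    answered at chance downstream of the sensory read-out."""
    if not 0.0 <= lapse < 0.5:
        raise ValueError("lapse must lie in [0, 0.5)")
    return (behavioral_performance - 0.5 * lapse) / (1.0 - lapse)


def noise_model_requirement(curve: PopulationCurve,
                            behavioral_performance: float,
                            lapse: float, mode: str) -> RequiredN:
    """Required population size under the sensory- or cognitive-noise model.

    Sensory mode: the decoder must match raw behavioral performance.
    Cognitive mode: a random fraction of trials (the lapse rate) is
    corrupted to chance after the sensory stage, so the decoder must reach
    (p - lapse/2) / (1 - lapse) instead.
    """
    if not 0.5 < behavioral_performance < 1.0:
        raise ValueError("behavioral_performance must lie in (0.5, 1)")
    if mode == "sensory":
        target = behavioral_performance
    elif mode == "cognitive":
        target = cognitive_target(behavioral_performance, lapse)
        if target >= 1.0:
            return RequiredN(n_median=None, n_low=None, n_high=None,
                             target=target, unreachable=True)
    else:
        raise ValueError("mode must be 'sensory' or 'cognitive'")
    return required_population_size(curve, target)
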