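"""Psychometric fitting for 2AFC orientation discrimination.

Performance as a function of stimulus strength ``s`` (duration in ms or
contrast) is modelled as a logistic scaled between the 2AFC guessing rate
``gamma = 0.5`` and ``1 - lapse``::

    P(s) = gamma + (1 - lapse - gamma) / (1 + exp(-(s - m) / omega))

``m`` is the stimulus strength at half-maximum performance -- the threshold
integration time (tau) on the duration axis, the threshold contrast
(upsilon) on the contrast axis.  ``omega`` sets the width of the transition
and ``lapse`` the stimulus-independent error floor at the upper asymptote.

Point estimates are MAP under a Beta(1.2, 12) prior on the lapse rate and
flat priors on (m, omega) over the observed stimulus range; credible
intervals are 2.5/97.5 percentiles of an MCMC posterior sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import emcee
import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit
from statsmodels.stats.proportion import confint_proportions_2indep, proportion_confint

from .datamodel import logger

GUESS_2AFC = 0.5

DEFAULT_PRIORS = {"lapse_beta": (1.2, 12.0)}
DEFAULT_MCMC = {"n_walkers": 32, "n_steps": 3000, "n_warmup": 1000}

AXIS_COLUMN = {"duration": "duration_ms", "contrast": "contrast"}


@dataclass(frozen=True)
class PsychometricModel:
    m: float
    omega: float
    lapse: float = 0.0
    guess: float = GUESS_2AFC

    def __post_init__(self):
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if not 0.0 <= self.lapse < 0.5:
            raise ValueError("lapse must lie in [0, 0.5)")


def predict_performance(model: PsychometricModel, s) -> np.ndarray | float:
    """Expected proportion correct at stimulus strength ``s``."""
    x = (np.asarray(s, dtype=float) - model.m) / model.omega
    p = model.guess + (1.0 - model.lapse - model.guess) * expit(x)
    return float(p) if np.isscalar(s) else p


@dataclass
class FilterReport:
    n_input: int
    n_fast_excluded: int
    n_slow_excluded: int
    n_kept: int


def filter_trials(trials: pd.DataFrame,
                  min_rt_s: float = 0.05,
                  max_rt_s: float = 5.0) -> tuple[pd.DataFrame, FilterReport]:
    """Drop implausibly fast (<50 ms) and unmotivated slow (>5 s) trials.

    Boundaries are inclusive: trials with RT exactly 0.05 s or 5 s are kept.
    """
    rt = trials["reaction_time_s"].to_numpy() if len(trials) else np.array([])
    fast = rt < min_rt_s
    slow = rt > max_rt_s
    kept = trials[~(fast | slow)].copy() if len(trials) else trials.copy()
    report = FilterReport(
        n_input=len(trials),
        n_fast_excluded=int(fast.sum()),
        n_slow_excluded=int(slow.sum()),
        n_kept=len(kept),
    )
    logger.info("filter_trials: kept %d/%d (%d fast, %d slow excluded)",
                report.n_kept, report.n_input,
                report.n_fast_excluded, report.n_slow_excluded)
    return kept, report


@dataclass
class PsychometricFit:
    point_estimates: PsychometricModel | None
    posterior_samples: pd.DataFrame
    ci95: dict
    axis: str
    n_trials_used: int
    degenerate: bool = False
    converged: bool = True
    split_rhat: dict = field(default_factory=dict)

    @property
    def threshold(self) -> float:
        """tau on the duration axis, upsilon on the contrast axis."""
        return self.point_estimates.m if self.point_estimates else float("nan")


def _binned(trials: pd.DataFrame, axis: str):
    col = AXIS_COLUMN[axis]
    grp = trials.groupby(col)["correct"]
    levels = np.array(sorted(grp.groups))
    k = grp.sum().reindex(levels).to_numpy(dtype=float)
    n = grp.count().reindex(levels).to_numpy(dtype=float)
    return levels, k, n


def _log_posterior(theta, levels, k, n, bounds, lapse_beta):
    m, omega, lapse = theta
    for v, (lo, hi) in zip(theta, bounds):
        if not lo <= v <= hi:
            return -np.inf
    p = GUESS_2AFC + (1.0 - lapse - GUESS_2AFC) * expit((levels - m) / omega)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    ll = np.sum(k * np.log(p) + (n - k) * np.log1p(-p))
    lp = stats.beta.logpdf(lapse, *lapse_beta) if lapse > 0 else stats.beta.logpdf(1e-9, *lapse_beta)
    return ll + lp


def split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat convergence diagnostic over an array (n_chains, n_draws)."""
    n_chains, n_draws = chains.shape
    half = n_draws // 2
    segs = np.concatenate([chains[:, :half], chains[:, half: 2 * half]], axis=0)
    m, n = segs.shape
    means = segs.mean(axis=1)
    b = n * means.var(ddof=1)
    w = segs.var(axis=1, ddof=1).mean()
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w)) if w > 0 else np.inf


def _fit_bounds(levels):
    s_min, s_max = float(levels.min()), float(levels.max())
    srange = s_max - s_min
    return [(s_min, s_max), (1e-3 * srange, srange), (0.0, 0.4999)]


def fit_map(trials: pd.DataFrame, axis: str,
            priors: dict | None = None) -> PsychometricModel | None:
    """MAP point estimate by multi-start constrained optimization."""
    priors = {**DEFAULT_PRIORS, **(priors or {})}
    levels, k, n = _binned(trials, axis)
    if len(levels) < 2:
        return None
    bounds = _fit_bounds(levels)
    lapse_beta = priors["lapse_beta"]

    def nlp(theta):
        return -_log_posterior(theta, levels, k, n, bounds, lapse_beta)

    srange = levels.max() - levels.min()
    starts = [
        (q, w * srange, l)
        for q in np.quantile(levels, [0.25, 0.5, 0.75])
        for w in (0.1, 0.3)
        for l in (0.05, 0.2)
    ]
    best, best_val = None, np.inf
    for x0 in starts:
        res = optimize.minimize(nlp, x0, method="L-BFGS-B", bounds=bounds)
        if res.fun < best_val and np.isfinite(res.fun):
            best, best_val = res.x, res.fun
    if best is None:
        return None
    return PsychometricModel(m=float(best[0]), omega=float(best[1]),
                             lapse=float(best[2]))


def fit_psychometric(trials: pd.DataFrame, axis: str,
                     priors: dict | None = None,
                     mcmc: dict | None = None,
                     seed: int = 0) -> PsychometricFit:
    """Fit the logistic-with-lapse model to a 2AFC trial table.

    Binomial likelihood per stimulus level; guessing rate fixed at 0.5.
    Returns MAP point estimates, posterior samples, and 95% credible
    intervals from the 2.5/97.5 percentiles of the marginal posterior.
    Degenerate data (fewer than two stimulus levels, or responses with no
    variation) are flagged rather than fitted.
    """
    if axis not in AXIS_COLUMN:
        raise ValueError(f"axis must be one of {sorted(AXIS_COLUMN)}")
    priors = {**DEFAULT_PRIORS, **(priors or {})}
    mcmc = {**DEFAULT_MCMC, **(mcmc or {})}
    levels, k, n = _binned(trials, axis)
    empty = pd.DataFrame(columns=["m", "omega", "lapse"])
    if len(levels) < 2 or k.sum() == 0 or k.sum() == n.sum():
        logger.warning("fit_psychometric: degenerate data (%d levels)", len(levels))
        return PsychometricFit(point_estimates=None, posterior_samples=empty,
                               ci95={}, axis=axis, n_trials_used=int(n.sum()),
                               degenerate=True, converged=False)

    point = fit_map(trials, axis, priors)
    bounds = _fit_bounds(levels)
    lapse_beta = priors["lapse_beta"]

    rng = np.random.default_rng(seed)
    n_walkers = int(mcmc["n_walkers"])
    p0 = np.array([point.m, point.omega, max(point.lapse, 1e-3)])
    scale = np.array([b[1] - b[0] for b in bounds]) * 0.05
    init = p0 + scale * rng.standard_normal((n_walkers, 3))
    for j, (lo, hi) in enumerate(bounds):
        init[:, j] = np.clip(init[:, j], lo + 1e-9, hi - 1e-9)

    sampler = emcee.EnsembleSampler(
        n_walkers, 3, _log_posterior,
        args=(levels, k, n, bounds, lapse_beta),
    )
    sampler.random_state = np.random.RandomState(seed).get_state()
    state = sampler.run_mcmc(init, int(mcmc["n_warmup"]), progress=False)
    sampler.reset()
    sampler.run_mcmc(state, int(mcmc["n_steps"]) - int(mcmc["n_warmup"]),
                     progress=False)
    chain = sampler.get_chain()  # (draws, walkers, 3)

    rhats = {}
    for j, name in enumerate(["m", "omega", "lapse"]):
        rhats[name] = split_rhat(chain[:, :, j].T)
    converged = all(r < 1.05 for r in rhats.values())
    if not converged:
        logger.warning("fit_psychometric: split-R-hat > 1.05 %s", rhats)

    flat = chain.reshape(-1, 3)
    samples = pd.DataFrame(flat, columns=["m", "omega", "lapse"])
    ci95 = {name: tuple(np.percentile(samples[name], [2.5, 97.5]))
            for name in samples.columns}
    return PsychometricFit(point_estimates=point, posterior_samples=samples,
                           ci95=ci95, axis=axis, n_trials_used=int(n.sum()),
                           degenerate=False, converged=converged,
                           split_rhat=rhats)


def total_integration_time(fit: PsychometricFit, mode: str = "range") -> float:
    """Duration at which performance reaches 90% of its maximum.

    ``mode="range"`` (default) measures 90% of the above-chance dynamic
    range, P(T) - gamma = 0.9 (P(inf) - gamma), which has the lapse-free
    closed form T = m + omega ln 9.  ``mode="absolute"`` instead solves
    P(T) = 0.9 P(inf).
    """
    if fit.degenerate or fit.point_estimates is None:
        raise ValueError("total integration time undefined for degenerate fit")
    if fit.axis != "duration":
        raise ValueError("total integration time is defined on the duration axis")
    p = fit.point_estimates
    if mode == "range":
        return p.m + p.omega * np.log(9.0)
    if mode == "absolute":
        target = 0.9 * (1.0 - p.lapse)  # P(inf) = 1 - lapse
        frac = (target - p.guess) / (1.0 - p.lapse - p.guess)
        if not 0.0 < frac < 1.0:
            raise ValueError("absolute 90% level unreachable for these parameters")
        return p.m + p.omega * np.log(frac / (1.0 - frac))
    raise ValueError("mode must be 'range' or 'absolute'")


def average_subject(per_subject_trials: list[pd.DataFrame], axis: str,
                    n_resamples: int = 1000, seed: int = 0,
                    priors: dict | None = None) -> tuple[pd.DataFrame, pd.Series]:
    """Balanced-resampling pseudo-subject built from several animals.

    Each resample draws the minimum per-subject trial count from every
    subject without replacement (equal weight per animal), concatenates,
    and takes the MAP fit.  Returns the per-resample estimates and their
    mean across resamples.
    """
    if len(per_subject_trials) < 2:
        raise ValueError("average subject requires >= 2 subjects")
    sizes = [len(t) for t in per_subject_trials]
    if min(sizes) == 0:
        raise ValueError("a subject has zero trials")
    n_draw = min(sizes)
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_resamples):
        parts = [t.sample(n=n_draw, replace=False, random_state=rng.integers(2**31))
                 for t in per_subject_trials]
        model = fit_map(pd.concat(parts, ignore_index=True), axis, priors)
        if model is not None:
            rows.append({"m": model.m, "omega": model.omega, "lapse": model.lapse})
    estimates = pd.DataFrame(rows)
    summary = estimates.mean()
    summary["n_trials_per_subject"] = n_draw
    return estimates, summary


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval (Beta-quantile form)."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError("need 0 <= k <= n with n > 0")
    lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")
    return float(lo), float(hi)


def agresti_caffo(k1: int, n1: int, k2: int, n2: int,
                  alpha: float = 0.05) -> tuple[float, tuple[float, float], bool]:
    """Difference of two binomial proportions with the add-one adjustment.

    Returns (estimate p1~ - p2~, Wald interval on the adjusted difference,
    significant), where significance means the interval excludes zero.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both sample sizes must be positive")
    est = (k1 + 1) / (n1 + 2) - (k2 + 1) / (n2 + 2)
    lo, hi = confint_proportions_2indep(k1, n1, k2, n2, method="agresti-caffo",
                                        compare="diff", alpha=alpha)
    significant = bool(lo > 0 or hi < 0)
    return float(est), (float(lo), float(hi)), significant
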