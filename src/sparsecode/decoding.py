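"""Logistic decoding of stimulus orientation from spike counts.

One unit at a time (or all units of a session jointly), trials with a
stimulus are split at random into 70% training / 30% test, stratified by
stimulus condition; a logistic regression of the left/right label on the
spike count is fitted on the training set and scored on the test set.
The split is repeated 100 times.  A unit is a *consistent predictor* when
its slope is significant (two-sided Wald p < 0.05) with a stable sign in
at least 70 of the 100 splits -- it votes for the same orientation no
matter which trials it is fitted on.  Decoding performance is the mean
test accuracy over splits.

Zero-contrast trials have no correct orientation; they are excluded from
both training and accuracy, and the decoder's left/right prediction split
on them is reported as a separate diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

from .datamodel import SpikeCountMatrix, logger
from .units import count_spikes_in_window

LABEL_CODE = {"left": 0, "right": 1}
RIDGE_ALPHA = 1e-4  # penalty strength on the flagged separation path
_COEF_SEPARATION_GUARD = 50.0
_BSE_GUARD = 50.0


@dataclass(frozen=True)
class SplitProtocol:
    train_fraction: float = 0.7
    n_splits: int = 100
    seed: int = 0
    min_per_class: int = 10

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class UnitDecoderResult:
    unit_id: object
    coefficient_mean: float
    intercept_mean: float
    per_split: pd.DataFrame  # columns coef, intercept, p_value, test_accuracy
    performance: float
    consistent: bool
    n_significant: int
    majority_sign: int
    zero_contrast_right_fraction: float = np.nan
    n_separable_splits: int = 0


@dataclass
class PopulationDecoderResult:
    session_id: object
    coefficients: np.ndarray
    intercept: float
    performance: float
    n_units: int
    n_consistent: int | None = None
    penalized: bool = False


def stratified_splits(condition_key: np.ndarray, protocol: SplitProtocol
                      ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Train/test index pairs, stratified so every condition with >= 2
    trials appears on both sides of every split.  Deterministic in
    ``protocol.seed``."""
    rng = np.random.default_rng(protocol.seed)
    key = pd.Series(condition_key)
    groups = [np.flatnonzero((key == k).to_numpy()) for k in sorted(key.unique())]
    splits = []
    for _ in range(protocol.n_splits):
        train_parts, test_parts = [], []
        for idx in groups:
            perm = idx[rng.permutation(len(idx))]
            if len(idx) == 1:
                train_parts.append(perm)
                continue
            n_train = int(round(protocol.train_fraction * len(idx)))
            n_train = min(max(n_train, 1), len(idx) - 1)
            train_parts.append(perm[:n_train])
            test_parts.append(perm[n_train:])
        splits.append((np.sort(np.concatenate(train_parts)),
                       np.sort(np.concatenate(test_parts))))
    return splits


def _fit_logistic(X: np.ndarray, y: np.ndarray):
    """Fit intercept+slopes logistic regression; returns
    (params, pvalues, separable_flag).  Perfect separation (or a diverged
    unpenalized fit) falls back to a small ridge penalty; the slope is then
    scored significant (p = 0) with the separating sign."""
    design = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(method="newton", disp=0, maxiter=50)
        converged = res.mle_retvals.get("converged", True)
        if converged and np.all(np.isfinite(res.params)) and \
                np.max(np.abs(res.params[1:])) < _COEF_SEPARATION_GUARD and \
                np.all(np.isfinite(res.bse)) and np.max(res.bse) < _BSE_GUARD:
            return np.asarray(res.params), np.asarray(res.pvalues), False
    except Exception:
        pass
    clf = LogisticRegression(C=1.0 / RIDGE_ALPHA, max_iter=1000)
    clf.fit(X, y)
    params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
    pvals = np.concatenate([[1.0], np.zeros(X.shape[1])])
    return params, pvals, True


def _predict(params: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Predicted label codes; a predicted probability of exactly 0.5 breaks
    toward 'left' (code 0)."""
    logit = params[0] + X @ params[1:]
    return (logit > 0).astype(int)


def _stimulus_arrays(counts: SpikeCountMatrix):
    cond = counts.conditions
    stim = (cond["contrast"] > 0).to_numpy()
    y = cond["orientation_label"].map(LABEL_CODE).to_numpy(dtype=float)
    key = list(zip(cond["orientation_label"], cond["contrast"],
                   cond["duration_ms"]))
    key = np.asarray(pd.Series(key, dtype=object)[stim])
    return stim, y[stim].astype(int), key


def fit_single_unit_decoder(counts_row: np.ndarray, labels: np.ndarray,
                            zero_contrast_mask: np.ndarray,
                            protocol: SplitProtocol,
                            condition_key: np.ndarray | None = None,
                            splits=None, unit_id=None) -> UnitDecoderResult:
    """Repeated-split logistic decoder for one unit.

    ``labels`` are 0/1 codes (left/right) over *all* trials; trials under
    ``zero_contrast_mask`` are dropped from training and accuracy.
    """
    counts_row = np.asarray(counts_row, dtype=float)
    zero_contrast_mask = np.asarray(zero_contrast_mask, dtype=bool)
    stim = ~zero_contrast_mask
    x = counts_row[stim]
    y = np.asarray(labels, dtype=float)[stim].astype(int)
    classes, n_class = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("single-class data: cannot fit a 2AFC decoder")
    if n_class.min() < protocol.min_per_class:
        raise ValueError(
            f"need >= {protocol.min_per_class} stimulus trials per class, "
            f"got {n_class.min()}")
    if splits is None:
        if condition_key is None:
            condition_key = y
        splits = stratified_splits(np.asarray(condition_key, dtype=object),
                                   protocol)

    x0 = counts_row[zero_contrast_mask]
    rows = []
    zc_right = []
    n_sep = 0
    for train_idx, test_idx in splits:
        xt, yt = x[train_idx], y[train_idx]
        if xt.std() == 0:
            # silent unit on this split: intercept-only prediction
            p1 = yt.mean()
            params = np.array([np.log(p1 / (1 - p1)) if 0 < p1 < 1
                               else (-np.inf if p1 == 0 else np.inf), 0.0])
            pvals = np.array([1.0, 1.0])
            sep = False
        else:
            params, pvals, sep = _fit_logistic(xt[:, None], yt)
        n_sep += sep
        pred = _predict(params, x[test_idx][:, None])
        acc = float(np.mean(pred == y[test_idx]))
        if len(x0):
            zc_right.append(float(np.mean(_predict(params, x0[:, None]))))
        rows.append({"coef": params[1], "intercept": params[0],
                     "p_value": pvals[1], "test_accuracy": acc})
    per_split = pd.DataFrame(rows)

    sig = per_split["p_value"].to_numpy() < 0.05
    signs = np.sign(per_split["coef"].to_numpy())
    ref = signs[sig] if sig.any() else signs
    majority = 1 if (ref > 0).sum() >= (ref < 0).sum() else -1
    qualifying = int(np.sum(sig & (signs == majority)))
    consistent = qualifying >= int(np.ceil(0.7 * protocol.n_splits))
    return UnitDecoderResult(
        unit_id=unit_id,
        coefficient_mean=float(per_split["coef"].mean()),
        intercept_mean=float(per_split["intercept"].mean()),
        per_split=per_split,
        performance=float(per_split["test_accuracy"].mean()),
        consistent=bool(consistent),
        n_significant=int(sig.sum()),
        majority_sign=majority,
        zero_contrast_right_fraction=float(np.mean(zc_right)) if zc_right else np.nan,
        n_separable_splits=int(n_sep),
    )


def fit_all_units(counts: SpikeCountMatrix,
                  protocol: SplitProtocol) -> list[UnitDecoderResult]:
    """Run the single-unit decoder for every unit of a session, sharing one
    set of stratified splits."""
    cond = counts.conditions
    zero = (cond["contrast"] == 0).to_numpy()
    labels = cond["orientation_label"].map(LABEL_CODE).fillna(-1).to_numpy()
    stim_key = counts.condition_key().to_numpy(dtype=object)[~zero]
    splits = stratified_splits(stim_key, protocol)
    results = []
    for i, uid in enumerate(counts.unit_ids):
        results.append(fit_single_unit_decoder(
            counts.counts[i], labels, zero, protocol,
            splits=splits, unit_id=uid))
    return results


def window_sweep(events, window_ends_ms, protocol: SplitProtocol,
                 unit_ids: list | None = None) -> pd.DataFrame:
    """Single-unit decoding as a function of the spike-count window (0, t).

    Returns one row per window with the population mean performance and
    the number of consistent predictors.
    """
    rows = []
    for t in window_ends_ms:
        counts = count_spikes_in_window(events, 0.0, float(t), unit_ids=unit_ids)
        results = fit_all_units(counts, protocol)
        rows.append({
            "window_end_ms": float(t),
            "mean_performance": float(np.mean([r.performance for r in results])),
            "n_consistent": int(sum(r.consistent for r in results)),
        })
    return pd.DataFrame(rows)


def fit_population_decoder(counts: SpikeCountMatrix, protocol: SplitProtocol,
                           session_id=None,
                           n_consistent: int | None = None
                           ) -> PopulationDecoderResult:
    """Multivariate logistic decoder over all simultaneously recorded units.

    Uses the same repeated stratified-split protocol as the single-unit
    path.  When trials are scarce relative to units (n_trials <=
    n_units + 10) or the design is rank-deficient, the fit is ridge
    penalized and flagged."""
    cond = counts.conditions
    zero = (cond["contrast"] == 0).to_numpy()
    labels = cond["orientation_label"].map(LABEL_CODE).fillna(-1).to_numpy()
    X = counts.counts.T.astype(float)[~zero]
    y = labels[~zero].astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class data: cannot fit a 2AFC decoder")
    stim_key = counts.condition_key().to_numpy(dtype=object)[~zero]
    splits = stratified_splits(stim_key, protocol)

    force_penalized = X.shape[0] <= X.shape[1] + 10
    if force_penalized:
        logger.warning("population decoder: %d trials for %d units; "
                       "using penalized fit", X.shape[0], X.shape[1])
    accs, coefs, intercepts = [], [], []
    n_pen = 0
    for train_idx, test_idx in splits:
        Xt, yt = X[train_idx], y[train_idx]
        keep = Xt.std(axis=0) > 0
        if force_penalized or not keep.any():
            clf = LogisticRegression(C=1.0 / RIDGE_ALPHA, max_iter=1000)
            clf.fit(Xt, yt)
            params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
            n_pen += 1
        else:
            sub_params, _, sep = _fit_logistic(Xt[:, keep], yt)
            n_pen += sep
            params = np.zeros(X.shape[1] + 1)
            params[0] = sub_params[0]
            params[1:][keep] = sub_params[1:]
        pred = _predict(params, X[test_idx])
        accs.append(float(np.mean(pred == y[test_idx])))
        coefs.append(params[1:])
        intercepts.append(params[0])
    return PopulationDecoderResult(
        session_id=session_id,
        coefficients=np.mean(coefs, axis=0),
        intercept=float(np.mean(intercepts)),
        performance=float(np.mean(accs)),
        n_units=X.shape[1],
        n_consistent=n_consistent,
        penalized=n_pen > 0,
    )


def consistency_summary(results: list[UnitDecoderResult]) -> pd.Series:
    """Fraction of consistent predictors and performance summaries, with
    exact binomial CIs on the fraction."""
    from .psychometrics import clopper_pearson

    if not results:
        return pd.Series(dtype=float)
    n = len(results)
    k = sum(r.consistent for r in results)
    perf_all = np.array([r.performance for r in results])
    perf_cons = np.array([r.performance for r in results if r.consistent])
    lo, hi = clopper_pearson(k, n)
    return pd.Series({
        "n_units": n,
        "n_consistent": k,
        "fraction_consistent": k / n,
        "fraction_ci_low": lo,
        "fraction_ci_high": hi,
        "mean_performance_all": perf_all.mean(),
        "mean_performance_consistent": perf_cons.mean() if len(perf_cons) else np.nan,
    })
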