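import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import sparsecode as sc
from sparsecode.decoding import SplitProtocol, fit_all_units, fit_population_decoder
from sparsecode.population import (VirtualUnit, build_pool, cognitive_target,
                                   filter_pool, noise_model_requirement,
                                   population_curve, required_population_size,
                                   shuffle_within_condition,
                                   simulate_virtual_sessions)


@pytest.fixture(scope="module")
def informative_pool():
    """Pool of consistent units from a strongly informative population."""
    pop = replace(sc.V1_DEFAULT.population, n_units=15,
                  informative_fraction=0.6,
                  evoked_amp_informative_lognorm=(np.log(2.5), 0.3),
                  shared_gain_sd=0.0, arousal_gain=1.0)
    sched = sc.default_schedule(n_per_condition=30, n_zero_contrast=24)
    sess = sc.simulate_session(pop, sched, seed=50)
    results = fit_all_units(sess["counts"], SplitProtocol(n_splits=60, seed=51))
    pool = build_pool(sess["counts"], results, consistent_only=True)
    assert len(pool) >= 3
    return pool, sess, results


def _toy_unit(uid, p_left, p_right, coef=1.0, intercept=-0.35, n=400, seed=0):
    """Bernoulli-count unit with known per-label response tables."""
    rng = np.random.default_rng(seed)
    return VirtualUnit(
        unit_id=uid, intercept=intercept, coef=coef,
        responses={
            ("left", 1.0, 100.0): (rng.random(n) < p_left).astype(int),
            ("right", 1.0, 100.0): (rng.random(n) < p_right).astype(int),
        })


class TestVirtualSessions:
    def test_single_unit_reduces_to_decoder_accuracy(self, informative_pool):
        pool, sess, results = informative_pool
        unit = max(pool, key=lambda u: abs(u.coef))
        res = {r.unit_id: r for r in results}[unit.unit_id]
        # per-condition virtual accuracy pooled over the stimulus grid
        conds = [(c, d) for c in (0.15, 1.0) for d in (50.0, 100.0, 150.0, 200.0)]
        accs = [simulate_virtual_sessions([unit], 1, cond, n_trials=400,
                                          n_resamples=1, seed=60 + i)[0]
                for i, cond in enumerate(conds)]
        assert np.mean(accs) == pytest.approx(res.performance, abs=0.05)

    def test_zero_contrast_condition_at_chance(self, informative_pool):
        pool, _, _ = informative_pool
        accs = simulate_virtual_sessions(pool, 8, (0.0, 100.0), n_trials=200,
                                         n_resamples=50, seed=61)
        assert np.median(accs) == pytest.approx(0.5, abs=0.05)

    def test_accuracy_non_decreasing_in_copies_of_one_unit(self):
        unit = _toy_unit("a", 0.2, 0.5)
        means = []
        for n_units in (1, 4, 16, 64):
            accs = simulate_virtual_sessions([unit], n_units, (1.0, 100.0),
                                             n_trials=400, n_resamples=30,
                                             seed=62)
            means.append(accs.mean())
        assert all(b >= a - 0.02 for a, b in zip(means, means[1:]))
        # independent evidence accumulates: the plateau approaches 1
        assert means[-1] > 0.95

    def test_vote_rule_available(self):
        unit = _toy_unit("a", 0.2, 0.6)
        accs = simulate_virtual_sessions([unit] * 3, 9, (1.0, 100.0),
                                         n_trials=300, n_resamples=10,
                                         seed=63, rule="vote")
        assert accs.mean() > 0.6

    def test_units_with_empty_tables_excluded(self):
        good = _toy_unit("a", 0.2, 0.6)
        bad = VirtualUnit(unit_id="b", intercept=0.0, coef=1.0,
                          responses={("left", 1.0, 100.0): np.array([1])})
        kept = filter_pool([good, bad], (1.0, 100.0))
        assert [u.unit_id for u in kept] == ["a"]


class TestPopulationCurve:
    def test_uninformative_pool_flat_at_chance(self):
        rng = np.random.default_rng(1)
        pool = [VirtualUnit(
            unit_id=i, intercept=0.0, coef=rng.normal(0, 0.2),
            responses={(lab, 1.0, 100.0): rng.poisson(1.0, 300)
                       for lab in ("left", "right")})
            for i in range(10)]
        curve = population_curve(pool, [1, 8, 64], (1.0, 100.0),
                                 n_resamples=100, seed=2)
        assert np.all(np.abs(curve.median_performance - 0.5) < 0.06)

    def test_informative_pool_monotone_median(self, informative_pool):
        pool, _, _ = informative_pool
        curve = population_curve(pool, [1, 4, 16, 64], (1.0, 200.0),
                                 n_resamples=150, seed=3)
        band = curve.pct97_5 - curve.pct2_5
        assert np.all(np.diff(curve.median_performance) >= -band[:-1])
        assert curve.median_performance[-1] > curve.median_performance[0]

    def test_single_resample_band_collapses(self, informative_pool):
        pool, _, _ = informative_pool
        curve = population_curve(pool, [4], (1.0, 100.0), n_resamples=1, seed=4)
        assert curve.pct2_5[0] == curve.median_performance[0] == curve.pct97_5[0]

    def test_band_contains_median(self, informative_pool):
        pool, _, _ = informative_pool
        curve = population_curve(pool, [2, 8], (1.0, 100.0),
                                 n_resamples=80, seed=5)
        assert np.all(curve.pct2_5 <= curve.median_performance)
        assert np.all(curve.median_performance <= curve.pct97_5)

    def test_reproducible_under_fixed_seed(self, informative_pool):
        pool, _, _ = informative_pool
        c1 = population_curve(pool, [2, 8], (1.0, 100.0), n_resamples=50, seed=6)
        c2 = population_curve(pool, [2, 8], (1.0, 100.0), n_resamples=50, seed=6)
        assert np.array_equal(c1.accuracies, c2.accuracies)


class TestRequiredPopulationSize:
    @staticmethod
    def _curve(medians, lo=None, hi=None):
        medians = np.asarray(medians, dtype=float)
        return sc.PopulationCurve(
            sizes=np.arange(1, len(medians) + 1),
            median_performance=medians,
            pct2_5=np.asarray(lo if lo is not None else medians - 0.05),
            pct97_5=np.asarray(hi if hi is not None else medians + 0.05),
            n_resamples=100, condition=(1.0, 100.0))

    def test_already_above_target_returns_smallest_size(self):
        req = required_population_size(self._curve([0.8, 0.85, 0.9]), 0.74)
        assert req.n_median == 1 and not req.unreachable

    def test_unreachable_target_flagged(self):
        req = required_population_size(self._curve([0.55, 0.6, 0.62]), 0.9)
        assert req.unreachable and req.n_median is None

    def test_interval_brackets_point_estimate(self):
        req = required_population_size(
            self._curve([0.6, 0.7, 0.75, 0.8, 0.9]), 0.74)
        assert req.n_low <= req.n_median <= req.n_high

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            required_population_size(self._curve([0.6, 0.8]), 0.4)


class TestShuffle:
    def test_per_condition_histograms_preserved(self, small_session):
        counts = small_session["counts"]
        shuffled = shuffle_within_condition(counts, seed=7)
        key = counts.condition_key()
        for cond in key.unique():
            sel = (key == cond).to_numpy()
            for i in range(counts.n_units):
                assert sorted(counts.counts[i, sel]) == \
                    sorted(shuffled.counts[i, sel])

    def test_shuffle_noop_for_independent_units(self):
        pop = replace(sc.V1_DEFAULT.population, n_units=12,
                      informative_fraction=0.5, shared_gain_sd=0.0,
                      arousal_gain=1.0)
        sched = sc.default_schedule(n_per_condition=25, n_zero_contrast=16)
        sess = sc.simulate_session(pop, sched, seed=8)
        protocol = SplitProtocol(n_splits=40, seed=9)
        base = fit_population_decoder(sess["counts"], protocol)
        shuf = fit_population_decoder(
            shuffle_within_condition(sess["counts"], seed=10), protocol)
        split_se = base.performance * 0  # accuracies are means over 40 splits
        accs = 0.03  # 2 MC SE at ~120 test trials x 40 splits
        assert abs(base.performance - shuf.performance) < 2 * accs

    def test_shuffle_destroys_shared_gain_correlations(self):
        pop = replace(sc.V1_DEFAULT.population, n_units=10,
                      shared_gain_sd=0.8, arousal_gain=1.0,
                      baseline_rate_lognorm=(np.log(3.0), 0.3))
        sched = sc.default_schedule(n_per_condition=25, n_zero_contrast=16)
        sess = sc.simulate_session(pop, sched, seed=11)
        counts = sess["counts"]
        shuffled = shuffle_within_condition(counts, seed=12)

        def mean_corr(matrix):
            key = counts.condition_key()
            sel = (key == ("right", 1.0, 200.0)).to_numpy()
            r = np.corrcoef(matrix[:, sel].astype(float))
            return np.nanmean(r[np.triu_indices_from(r, k=1)])

        assert mean_corr(counts.counts) > 0.1
        assert abs(mean_corr(shuffled.counts)) < 0.1


class TestNoiseModels:
    def test_zero_lapse_modes_identical(self, informative_pool):
        pool, _, _ = informative_pool
        curve = population_curve(pool, [1, 4, 16, 64], (1.0, 200.0),
                                 n_resamples=100, seed=13)
        sens = noise_model_requirement(curve, 0.7, 0.0, "sensory")
        cog = noise_model_requirement(curve, 0.7, 0.0, "cognitive")
        assert sens.n_median == cog.n_median

    def test_cognitive_target_closed_form(self):
        assert cognitive_target(0.74, 0.2) == pytest.approx(0.80)

    def test_cognitive_needs_at_least_as_many_units(self, informative_pool):
        pool, _, _ = informative_pool
        curve = population_curve(pool, [1, 2, 4, 8, 16, 32, 64, 128],
                                 (1.0, 200.0), n_resamples=150, seed=14)
        for lapse in (0.1, 0.2, 0.3):
            sens = noise_model_requirement(curve, 0.72, lapse, "sensory")
            cog = noise_model_requirement(curve, 0.72, lapse, "cognitive")
            if cog.unreachable:
                continue
            assert cog.n_median >= sens.n_median

    def test_infeasible_cognitive_target_flagged(self):
        curve = TestRequiredPopulationSize._curve([0.6, 0.7, 0.8])
        req = noise_model_requirement(curve, 0.95, 0.3, "cognitive")
        assert req.unreachable
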