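import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

import sparsecode as sc
from sparsecode.datamodel import ArousalTrace, SpikeEventTable
from sparsecode.units import (arousal_split, classify_waveforms,
                              count_spikes_in_window, jackknife_errors,
                              jackknife_se, osi_and_pref)


def _bundle(spike_times, onsets=(1.0,), period=2.0):
    n = len(onsets)
    pres = pd.DataFrame({
        "trial_index": range(n),
        "onset_time_s": onsets,
        "orientation_label": ["right"] * n,
        "contrast": [1.0] * n,
        "duration_ms": [100.0] * n,
    })
    ev = pd.DataFrame({"unit_id": ["u0"] * len(spike_times),
                       "spike_time_s": sorted(spike_times)})
    return SpikeEventTable(events=ev, presentations=pres)


class TestCountWindow:
    def test_half_open_window(self):
        bundle = _bundle([1.1, 1.3, 1.6])  # 100, 300, 600 ms after onset
        counts = count_spikes_in_window(bundle, 0, 500)
        assert counts.counts.tolist() == [[2]]

    def test_empty_spike_train_all_zero(self):
        bundle = _bundle([], onsets=(1.0, 3.0))
        counts = count_spikes_in_window(bundle, 0, 500, unit_ids=["u0"])
        assert counts.counts.sum() == 0

    def test_counts_monotone_in_window_length(self, small_session):
        ev = small_session["events"]
        uids = small_session["counts"].unit_ids
        c100 = count_spikes_in_window(ev, 0, 100, unit_ids=uids)
        c500 = count_spikes_in_window(ev, 0, 500, unit_ids=uids)
        assert np.all(c100.counts <= c500.counts)


class TestResponseStatistics:
    def test_all_zero_counts_give_zero(self, small_schedule):
        pop = replace(sc.V1_DEFAULT.population, n_units=4,
                      baseline_rate_lognorm=(np.log(1e-9), 0.01),
                      evoked_amp_informative_lognorm=(np.log(1e-9), 0.01),
                      evoked_amp_uninformative_lognorm=(np.log(1e-9), 0.01),
                      off_amp_lognorm=(np.log(1e-9), 0.01))
        counts = sc.simulate_population(pop, small_schedule, seed=0)
        assert sc.response_probability(counts).max() == 0.0
        assert sc.responsive_fraction(counts).max() == 0.0

    def test_one_of_two_units_firing(self):
        bundle = _bundle([1.1])
        counts = count_spikes_in_window(bundle, 0, 500, unit_ids=["u0", "u1"])
        assert sc.responsive_fraction(counts).tolist() == [0.5]

    def test_probability_bounded_and_monotone_in_window(self, small_session):
        ev = small_session["events"]
        uids = small_session["counts"].unit_ids
        p100 = sc.response_probability(count_spikes_in_window(ev, 0, 100, unit_ids=uids))
        p500 = sc.response_probability(count_spikes_in_window(ev, 0, 500, unit_ids=uids))
        assert np.all((p100 >= 0) & (p500 <= 1))
        assert np.all(p100 <= p500)

    def test_by_condition_groups(self, small_session):
        df = sc.response_probability(small_session["counts"], by_condition=True)
        assert df.shape[1] == small_session["counts"].condition_key().nunique()
        assert ((df.values >= 0) & (df.values <= 1)).all()


class TestOSI:
    def test_single_orientation_response_is_perfectly_selective(self):
        res = osi_and_pref([0, 45, 90, 135], [0, 7.0, 0, 0])
        assert res.osi == pytest.approx(1.0)
        assert res.pref_orientation_deg == pytest.approx(45.0)

    def test_uniform_rates_are_unselective(self):
        res = osi_and_pref([0, 45, 90, 135], [3.0, 3.0, 3.0, 3.0])
        assert res.osi == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_vector_sum(self):
        # z = 10 e^{i0} + 5 e^{i pi/2} + 2 e^{i pi} + 5 e^{i 3pi/2} = 8
        res = osi_and_pref([0, 45, 90, 135], [10.0, 5.0, 2.0, 5.0])
        assert res.osi == pytest.approx(8.0 / 22.0)
        assert res.pref_orientation_deg == pytest.approx(0.0)

    def test_ratio_form_alternative(self):
        res = osi_and_pref([0, 45, 90, 135], [10.0, 5.0, 2.0, 5.0],
                           method="ratio")
        assert res.osi == pytest.approx((10 - 2) / (10 + 2))

    @given(scale=st.floats(0.1, 50), shift=st.integers(0, 11))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance_and_rotation_equivariance(self, scale, shift):
        rng = np.random.default_rng(3)
        theta = np.arange(0.0, 180.0, 15.0)
        rates = rng.gamma(2.0, 2.0, size=12) + 0.1
        base = osi_and_pref(theta, rates)
        scaled = osi_and_pref(theta, rates * scale)
        assert scaled.osi == pytest.approx(base.osi)
        rotated = osi_and_pref((theta + 15 * shift) % 180, rates)
        expected = (base.pref_orientation_deg + 15 * shift) % 180
        delta = abs(rotated.pref_orientation_deg - expected)
        assert min(delta, 180 - delta) < 1e-6

    def test_all_zero_rates_rejected(self):
        with pytest.raises(ValueError):
            osi_and_pref([0, 45, 90, 135], [0.0, 0.0, 0.0, 0.0])


class TestJackknife:
    def test_identical_trials_zero_error(self):
        trial_rates = [np.full(5, 4.0), np.full(5, 2.0),
                       np.full(5, 1.0), np.full(5, 2.0)]
        sd_osi, sd_pref = jackknife_errors([0, 45, 90, 135], trial_rates)
        assert sd_osi == pytest.approx(0.0, abs=1e-12)
        assert sd_pref == pytest.approx(0.0, abs=1e-12)

    def test_mean_statistic_matches_analytic_se(self):
        rng = np.random.default_rng(4)
        x = rng.normal(5.0, 2.0, size=40)
        assert jackknife_se(x, np.mean) == pytest.approx(
            x.std(ddof=1) / np.sqrt(len(x)))

    def test_sharply_tuned_unit_has_stable_preference(self):
        rng = np.random.default_rng(5)
        theta = np.arange(0.0, 180.0, 15.0)
        true = np.exp(3.0 * (np.cos(np.deg2rad(2 * (theta - 60.0))) - 1)) * 8
        trial_rates = [rng.poisson(t, size=10).astype(float) for t in true]
        sd_osi, sd_pref = jackknife_errors(theta, trial_rates)
        assert sd_pref < 20.0

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            jackknife_errors([0, 45, 90, 135], [np.ones(2)] * 4)


class TestClassifyWaveforms:
    @staticmethod
    def _two_cluster_units(n=60, seed=0):
        rng = np.random.default_rng(seed)
        half = n // 2
        width = np.concatenate([rng.normal(0.26, 0.03, half),
                                rng.normal(0.54, 0.05, half)])
        rate = np.concatenate([rng.lognormal(np.log(15.2), 0.3, half),
                               rng.lognormal(np.log(5.6), 0.3, half)])
        truth = np.array(["fast"] * half + ["regular"] * half)
        return pd.DataFrame({"unit_id": range(n), "spike_width_ms": width,
                             "mean_rate_hz": rate}), truth

    def test_recovers_printed_cluster_geometry(self):
        units, truth = self._two_cluster_units()
        labels, means = classify_waveforms(units, seed=1)
        fast = means[means["label"] == "fast"].iloc[0]
        reg = means[means["label"] == "regular"].iloc[0]
        assert fast["spike_width_ms"] == pytest.approx(0.26, rel=0.10)
        assert reg["spike_width_ms"] == pytest.approx(0.54, rel=0.10)
        assert fast["mean_rate_hz"] == pytest.approx(15.2, rel=0.25)
        assert reg["mean_rate_hz"] == pytest.approx(5.6, rel=0.25)
        assert (labels == truth).mean() >= 0.95

    def test_labels_invariant_to_unit_order(self):
        units, _ = self._two_cluster_units(seed=2)
        labels, _ = classify_waveforms(units, seed=3)
        perm = np.random.default_rng(0).permutation(len(units))
        labels_p, _ = classify_waveforms(units.iloc[perm].reset_index(drop=True),
                                         seed=3)
        assert (labels[perm] == labels_p).all()

    def test_deterministic_given_seed(self):
        units, _ = self._two_cluster_units(seed=4)
        a, _ = classify_waveforms(units, seed=5)
        b, _ = classify_waveforms(units, seed=5)
        assert (a == b).all()


class TestArousalSplit:
    @staticmethod
    def _presentations(n, period=2.0, t0=5.0):
        return pd.DataFrame({"trial_index": range(n),
                             "onset_time_s": t0 + period * np.arange(n)})

    def test_symmetric_trace_splits_half(self):
        t = np.arange(0, 400, 0.05)
        rng = np.random.default_rng(6)
        pupil = np.sin(2 * np.pi * t / 40.0) + 0.05 * rng.standard_normal(len(t))
        trace = ArousalTrace(time_s=t, pupil_size=pupil)
        pres = self._presentations(150)
        split = arousal_split(trace, pres)
        frac_high = (split.trial_labels == "high").mean()
        assert frac_high == pytest.approx(0.5, abs=0.1)

    def test_constant_trace_all_low(self):
        t = np.arange(0, 100, 0.05)
        trace = ArousalTrace(time_s=t, pupil_size=np.full(len(t), 3.0))
        split = arousal_split(trace, self._presentations(20))
        assert set(split.trial_labels) == {"low"}  # z = 0 ties go to low

    def test_step_trace_labels_second_half_high(self):
        t = np.arange(0, 200, 0.05)
        trace = ArousalTrace(time_s=t, pupil_size=np.where(t < 100, 1.0, 2.0))
        pres = self._presentations(40, period=4.0, t0=2.0)
        split = arousal_split(trace, pres)
        onsets = pres["onset_time_s"].to_numpy()
        expected = np.where(onsets >= 100, "high", "low")
        # trials straddling the step may go either way; exclude them
        clear = np.abs(onsets - 100) > 2
        assert (split.trial_labels[clear] == expected[clear]).all()

    def test_uncovered_trials_labeled_missing(self):
        t = np.arange(0, 30, 0.05)
        trace = ArousalTrace(time_s=t, pupil_size=np.sin(t))
        split = arousal_split(trace, self._presentations(20))
        assert split.trial_labels[-1] == "missing"

    def test_recovers_generating_state(self, small_schedule):
        pop = replace(sc.V1_DEFAULT.population, n_units=4,
                      arousal_pupil_noise_sd=0.2, arousal_gain=1.2)
        sess = sc.simulate_session(pop, small_schedule, seed=11)
        split = arousal_split(sess["arousal"], sess["trials"])
        truth = sess["trials"]["arousal_state"].to_numpy()
        ok = split.trial_labels != "missing"
        acc = (split.trial_labels[ok] == truth[ok]).mean()
        assert acc > 0.9
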