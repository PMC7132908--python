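"""Descriptive statistics of a simulated V1 session.

Shows how sparse the population is: per-trial responsive fraction,
per-unit spike probability at the strongest short stimulus, orientation
selectivity, fast/regular waveform classes and the pupil-based arousal
split.
"""

import numpy as np

import sparsecode as sc

preset = sc.V1_DEFAULT
sess = sc.simulate_session(preset.population, preset.trial_schedule, seed=7)
counts = sess["counts"]

rf = sc.responsive_fraction(counts)
print(f"{counts.n_units} units x {counts.n_trials} trials")
print(f"responsive fraction (0-500 ms): {rf.mean():.2f} +/- {rf.std():.2f} "
      "(mean +/- SD over trials) -- most units are silent on most trials")

strongest = ((counts.conditions["contrast"] == 1.0)
             & (counts.conditions["duration_ms"] == 200.0)).to_numpy()
stim100 = sc.count_spikes_in_window(sess["events"], 0, 300,
                                    unit_ids=counts.unit_ids)
p_spike = sc.response_probability(stim100, mask=strongest)
print(f"P(>=1 spike | strongest stimulus, stimulus+100 ms window): "
      f"{p_spike.mean():.2f} averaged over units")

rng = np.random.default_rng(8)
from sparsecode.synth import simulate_tuning_trials
tuning = simulate_tuning_trials(sess["units"], preset.population, rng)
osis = [sc.osi_and_pref(*[t[0], t[1].mean(axis=1)]).osi
        for t in tuning.values()]
print(f"orientation selectivity index: mean {np.mean(osis):.2f} "
      "(0 = untuned, 1 = responds to one orientation only)")

labels, means = sc.classify_waveforms(sess["units"], seed=9)
print("waveform k-means classes:")
print(means.round(2).to_string(index=False))

split = sc.arousal_split(sess["arousal"], sess["trials"])
print(f"high-arousal trials (pupil z > 0): "
      f"{(split.trial_labels == 'high').mean():.0%}")
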