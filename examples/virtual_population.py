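"""How many unreliable neurons must be pooled to match behavior?

Builds a pool of consistent predictors, resamples virtual sessions of
increasing size (units drawn with replacement, counts drawn from each
unit's condition-indexed response table, summed per-unit log-odds), and
reads off the population size needed to reach a behavioral target under
the sensory- and cognitive-noise models.
"""

import numpy as np

import sparsecode as sc

preset = sc.V1_DEFAULT
rng = np.random.default_rng(0)
pool = []
for s in range(6):
    sess = sc.simulate_session(preset.population, preset.trial_schedule,
                               seed=int(rng.integers(2**31)))
    res = sc.fit_all_units(sess["counts"],
                           sc.SplitProtocol(seed=int(rng.integers(2**31))))
    pool += sc.build_pool(sess["counts"], res, consistent_only=True)
print(f"pool: {len(pool)} consistent units")

condition = (1.0, 100.0)  # full contrast, 100 ms
curve = sc.population_curve(pool, [1, 2, 4, 8, 16, 32, 64, 128, 256],
                            condition, n_resamples=500, seed=1)
for n, med in zip(curve.sizes, curve.median_performance):
    print(f"  N = {n:3d}: median decoding performance {med:.3f}")

target = 0.74  # average-subject behavior at this condition
sens = sc.noise_model_requirement(curve, target, lapse=0.2, mode="sensory")
cog = sc.noise_model_requirement(curve, target, lapse=0.2, mode="cognitive")
print(f"required N (sensory noise model, target {target}): {sens.n_median} "
      f"[{sens.n_low}, {sens.n_high}]")
print(f"required N (cognitive noise model, decoder target "
      f"{cog.target:.2f}): {cog.n_median} [{cog.n_low}, {cog.n_high}]")
print("Pooling tens of weakly informative units reproduces behavioral "
      "accuracy; attributing lapses to cognition raises the requirement.")
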