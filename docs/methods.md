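# Methods

`sparsecode` links mouse 2AFC orientation-discrimination behavior to the
statistics of sparse V1 population activity.  It has four analytic stages
(psychometrics, unit characterization, decoding, virtual populations) and a
synthetic-data generator that stands in for behavioral logs and chronic V1
recordings.  This note documents the models, the parameters that matter,
the numerical choices, and what the synthetic data can and cannot show.

## Psychometric model

Performance in a 2AFC task as a function of stimulus strength `s`
(duration in ms, or contrast) is

    P(s) = γ + (1 − λ − γ) · logistic((s − m) / ω),

with the guessing rate fixed at `γ = 0.5` (two alternatives), lapse rate
`λ ∈ [0, 0.5)`, half-maximum point `m` and width `ω`.  On the duration
axis `m` is the threshold integration time τ; on the contrast axis it is
the threshold contrast υ.

Fitting uses a binomial likelihood per stimulus level with a Beta(1.2, 12)
prior on λ and flat priors on `(m, ω)` over the observed stimulus range
(`ω` bounded below at 10⁻³ of the range to exclude step-function
degeneracies).  Point estimates are the MAP, found by multi-start L-BFGS-B;
"most likely estimates" throughout the package mean MAP under these priors
(posterior means are available from the samples if preferred).  Credible
intervals are 2.5/97.5 percentiles of the marginal posterior, sampled with
an affine-invariant ensemble sampler (32 walkers, 3000 steps, 1000
warm-up by default).  The sampler contract is split-R̂ < 1.05 per
parameter, computed over walkers; non-convergent fits are flagged but
still returned.

The **total integration time** T is the duration at which performance
reaches 90% of its maximum.  "Maximum" is ambiguous between the absolute
level 0.9·P(∞) and the above-chance range; the package defaults to the
range-relative reading, P(T) − γ = 0.9·(P(∞) − γ), which is lapse-invariant
and has the closed form T = m + ω·ln 9.  The absolute reading is available
via `total_integration_time(fit, mode="absolute")`.

The **average subject** is built by balanced resampling: each of 1000
resamples draws the minimum per-subject trial count from every animal
without replacement, concatenates, and refits (MAP only); reported values
are means over resamples.  Reaction-time filtering keeps RT ∈ [0.05, 5] s,
boundaries inclusive.  Binomial CIs use Clopper–Pearson (Beta quantiles);
two-proportion comparisons use Agresti–Caffo (add-one adjustment, Wald
interval, significant iff the interval excludes 0).

## Unit characterization

Spike counts are taken in a half-open window [onset, onset + 500 ms) by
default; the window choice is validated by a decoding sweep over window
lengths (see below).  Response probability is P(count ≥ 1) per unit, and
the per-trial responsive fraction is the share of simultaneously recorded
units with at least one spike.

Orientation selectivity uses the doubled-angle vector sum
(1 − circular variance): OSI = |Σ R_k e^{2iθ_k}| / Σ R_k with preferred
orientation at half the argument, mapped to [0°, 180°).  The classic ratio
form (R_pref − R_orth)/(R_pref + R_orth) is available behind
`method="ratio"`.  No baseline subtraction is applied.  Errors are
leave-one-trial-out jackknife SEs; the preferred-orientation spread is
computed circularly in doubled-angle space and reported in orientation
degrees.

Fast/regular classification is k-means (k = 2, 50 restarts, seeded) on
standardized (spike width, log₁₀ rate); the narrower-width cluster is
"fast".  Laminar assignment: superficial < 400 µm, deep > 450 µm; the
400–450 µm gap between the two definitions is labelled "ambiguous" and
excluded from layer contrasts.  Duplicate units recorded across days on
chronic probes are detected on the same electrode and depth across
consecutive days when both the mean waveform and the ISI histogram
correlate at Pearson r > 0.95 (vectors correlated as stored, without
normalization); matches are closed transitively and only the earliest-day
unit is analysed.

Arousal: the pupil trace is median-filtered (1 s), z-scored per session,
and a trial is "high" iff its mean z over the counting window is strictly
positive (z = 0 ties go to "low").  Running speed is accepted as input but
not used for the split; pupil size is the sole arousal measure.

## Decoding protocol

Per unit, zero-contrast trials are removed (they have no correct
orientation), and the remaining trials are split 70/30 into training and
test, stratified by (orientation, contrast, duration) so that every
condition with ≥ 2 trials appears on both sides; the split repeats 100
times.  Each split fits a logistic regression of the left/right label on
the spike count (statsmodels, Newton) and records the slope's two-sided
Wald p and the test accuracy (predicted probability > 0.5 → "right";
exactly 0.5 breaks to "left").  Performance is the mean test accuracy over
splits.

A unit is a **consistent predictor** when p < 0.05 *and* the slope sign
equals the majority sign in at least 70 of 100 splits — the sign condition
operationalizes "predicts the same orientation no matter which trials are
included".  Because the splits overlap, the rule's false-positive rate is
far below the nominal per-split 5%: in null simulations (populations with
no label dependence) essentially no unit is flagged (the suite bounds the
null rate at ≤ 5% on 75 units; typical counts are zero).

Perfect separation (or a diverged unpenalized fit, detected by
non-convergence or exploding standard errors) falls back to a ridge
penalty of strength 10⁻⁴; on this flagged path the slope is scored
significant with the separating sign, so a deterministic discriminator is
consistent by construction.  The population decoder uses the same split
protocol with all simultaneously recorded units as features, switching to
the penalized path when trials ≤ units + 10 or the design is degenerate.
Zero-contrast trials are scored separately as the decoder's left/right
prediction split (a bias diagnostic), not folded into accuracy.

## Virtual populations

Each pooled unit contributes its condition-indexed empirical response
multiset (nonparametric; no refit distribution) and its decoder
coefficients.  A virtual session of size N draws units with replacement
(uniformly), simulates label-balanced trials by sampling each unit's count
from its own multiset for that condition, and combines units as
independent regressors by summing per-unit log-odds, Σᵢ (aᵢ + bᵢxᵢ),
predicting by sign (ties to "left").  A per-unit majority vote is
available behind `rule="vote"` for sensitivity analysis.  Pool membership
defaults to consistent predictors.

The performance-vs-N curve reports the median and 2.5/97.5 percentiles
over resampled sessions (default 1000; tests and the bundled pipeline use
200–500 to keep runtimes in seconds).  The required population size for a
behavioral target is the smallest N whose *median* performance reaches the
target; the interval reads the same criterion off the percentile curves.
Curves (and hence requirements) are computed per stimulus condition.

Noise models: under the sensory-noise reading the decoder must match raw
behavioral performance p; under the cognitive-noise reading a random
lapse-rate fraction of trials is corrupted to chance downstream, so the
decoder target becomes (p − λ/2)/(1 − λ), which is infeasible when ≥ 1.
The cognitive requirement is never smaller than the sensory one.

Within-condition shuffling permutes each unit's counts among trials with
identical (orientation, contrast, duration), preserving all per-unit
marginals while destroying across-unit co-fluctuations; it is the control
for noise-correlation effects on decoding.

## Synthetic-data generator

Behavior: Bernoulli outcomes from the psychometric observer above, with
lognormal reaction times and configurable rates of fast (< 50 ms) and slow
(> 5 s) RT outliers so the filters are exercised.  Zero-contrast trials
are answered and rewarded at chance.

Physiology: spike *events* from an inhomogeneous Poisson process with
three per-unit components:

1. a stationary background (lognormal rates across units, median
   ≈ 0.3 Hz — most units are nearly silent);
2. an orientation-tuned onset transient supported on
   [50 ms, duration + 100 ms] (50 ms latency, 100 ms tail), with a von
   Mises tuning bump in doubled-angle space and Naka–Rushton contrast
   gain;
3. an untuned rebound after stimulus offset, supported on
   [duration + 120 ms, duration + 370 ms].

The rebound reflects the observation that short-stimulus V1 responses
routinely outlast the stimulus; it is also structurally necessary here:
with any time-stationary background plus activity confined to the
stimulus+100 ms window, P(≥1 spike in 0–300 ms) ≥ 0.6 · P(≥1 spike in
0–500 ms) per unit, so a population cannot simultaneously show ≈ 43%
responsive fraction at 500 ms and < 20% spike probability in the
stimulus+100 ms window.  Late, offset-locked activity decouples the two.

Label information enters through tuning geometry: "informative" units
(fraction 0.21 by default) prefer orientations near the ±45° obliques;
the remainder prefer the cardinals (0°/90°), which are exactly symmetric
between the two obliques and therefore carry no label information while
producing the population's cardinal orientation bias.  All components
share a per-trial lognormal gain (mean 1) that makes counts
doubly-stochastic and, when `shared_gain_sd > 0`, induces noise
correlations removable by the shuffle control.  A slow two-state arousal
process (exponential dwells, ≈ 20 s) drives both the pupil trace (plus
observation noise) and a multiplicative firing gain (1.15 in the high
state), so the z-score split is exercised end to end.  The default
inter-unit correlation level is chosen so the shuffle control has a
detectable effect when enabled, not to match any reported value.

The frozen `v1_default` preset (the package defaults) was calibrated once
against four population statistics measured through the full pipeline —
responsive fraction ≈ 43% (0–500 ms), mean spike probability < 20% at the
strongest condition (stimulus+100 ms window), consistent-predictor
fraction ≈ 11%, consistent-unit performance ≈ 0.55 — and then fixed.  Its
schedule is the short-stimulus study grid {0.15, 1} × {50, 100, 150,
200 ms} × {left, right} at 45 trials per cell plus 72 zero-contrast
trials (792 trials/session, 20 units/session); preset-level statistics in
the tests and the acceptance script aggregate 25 sessions (500 units).

### What the generator does not emulate

* Spike-sorting artifacts, drift, refractory structure, bursting, and
  waveform shape beyond a two-cluster width/rate draw.
* Realistic zero-contrast responsive fractions: the background rate is
  capped by the < 20% spike-probability constraint, so blank-trial
  responsive fractions (~0.22) sit below stimulated ones (~0.48), a
  larger stimulus effect than real recordings show.  The grand mean
  across the schedule is the calibrated quantity.
* Stimulus-dependent noise correlations, receptive-field geometry,
  direction selectivity, and eye movements.

Passing tests therefore demonstrate that the *analysis machinery* behaves
correctly on data with the assumed statistical structure, not that real
V1 data have that structure.

## Numerical choices and degenerate inputs

* All stochastic operations take an explicit integer seed; fixed seed ⇒
  bit-identical outputs.
* Logistic ties (probability exactly 0.5) break to "left"; summed
  log-odds of exactly 0 likewise.
* Silent units (zero count variance on a training split) fall back to an
  intercept-only prediction with p = 1 for that split.
* Degenerate psychometric data (single stimulus level, or all-correct /
  all-incorrect responses) are flagged, not fitted; the total integration
  time is undefined there and raises.
* All-zero tuning curves make the OSI undefined and raise; jackknife
  needs ≥ 3 trials per orientation.
* Zero-variance waveforms make the duplicate-unit correlation undefined;
  such pairs are kept (non-duplicates) with a warning.
* Problem sizes in the test suite and acceptance script (25 preset
  sessions, 100 splits, 200–500 curve resamples, 20 recovery replicates
  at 2000 trials/level) were chosen to keep Monte-Carlo error comfortably
  inside the asserted tolerances while the whole suite runs in minutes on
  one CPU.

## Known limitations

* The ensemble sampler treats walkers as chains for split-R̂; this is a
  stricter-than-usual use of the diagnostic and occasionally flags slow
  mixing on very flat posteriors rather than true non-convergence.
* The Agresti–Caffo significance call is a Wald interval on adjusted
  proportions; for very small samples Clopper–Pearson per arm is the
  safer primitive.
* Virtual populations assume independence across pooled units by
  construction (counts drawn independently per unit), which is exactly
  the assumption the shuffle control probes on recorded sessions.
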