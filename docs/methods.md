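# Methods

This note documents the models, conventions, and numerical choices behind
the package, and what the synthetic tests do and do not establish about real
recordings.

## Session model and time base

All times are float seconds relative to the start of the experiment; only
the serialization layer knows calendar time, and it deliberately coarsens
the session start date to the first of the month (a de-identification
convention for patient data). A session is two contiguous blocks — encoding
(100 trials) then recognition (100 trials: 50 repeats labeled old = 0,
50 new = 1) — over five visual categories, balanced 20 per category at
encoding and 10 old + 10 new per category at recognition. The balance is
enforced by the generator for test power; real sessions need not be exactly
balanced and the analysis code does not assume it (only the MS screen
requires both conditions non-empty and the VS screen all five categories).

The event stream is the task's TTL grammar: 55, then per trial
`1 (stimulus onset), 2 (offset), 3 (question screen), response, 6 (end of
trial)`, then 66. Learning responses are 20/21 (animal yes/no); recognition
responses are 31–36, from new-confident to old-confident. A parallel
experiment-id stream of equal length labels each event's block with one
variant pair from (80, 81), (83, 84), (88, 89). The parser consumes events
in strict groups of five and fails loudly on any grammar violation, naming
the trial ordinal and the expected versus found code; ground-truth new/old
labels are not present in the TTL stream and are joined by trial order
(when reading real files they come from the trials table, and the parser
serves as a cross-check).

## Ragged spike-time storage

All units' spike times are stored as one concatenated vector plus a
cumulative end-count index (`spike_times` / `spike_times_index`). The stored
numbers are language-neutral counts: unit *i* occupies the 0-based half-open
slice `data[index[i-1]:index[i]]`, which is the same set of elements as the
1-based inclusive slice `data(index(i)+1 : index(i+1))` used from MATLAB.
Round-trip identity of build/slice is property-tested including empty units.

## NWB-style serialization

Files are written directly with h5py in the NWB:N 2.x organisation
(`acquisition/events`, `acquisition/experiment_ids`, `intervals/trials`,
`units`, `general/{devices,extracellular_ephys,subject}`,
`stimulus/presentation`), with the field-exact column names
(`new_old_labels_recog`, `stimCategory`, `origClusterID`, `SNR`,
`IsolDist`, `origChannel`). Internal-to-file name mapping: `new_old_label`
→ `new_old_labels_recog` (serialized as text "0"/"1", with "NA" for
learning trials), `stim_category` → `stimCategory`, `orig_cluster_id` →
`origClusterID`, `isol_dist` → `IsolDist`, `orig_channel` → `origChannel`,
`phase` → `stim_phase`. Event codes are written as text annotations with
integer payloads (the dialect produced by exporters that stringify the code
column) but read tolerantly whether stored as text, integer, or float.
Waveform matrices carry a `sampling_rate` attribute of 100 kHz. Readers
require `units`, `intervals/trials`, and `acquisition/events` and raise a
load error naming a missing group; the stimulus group is optional. The
analysis stage of the pipeline consumes only these files, never in-memory
bundles, so serialization is load-bearing in every end-to-end test.

## Behavioral model

Recognition behavior is equal-variance Gaussian signal detection: memory
strength is N(d′, σ_old) for old items and N(0, 1) for new items, with five
strictly increasing criteria mapping strength to the six responses
(response = 31 + number of criteria below the strength). Defaults:
d′ = 1.5 (a typical well-performing session), σ_old = 1 (equal variance;
set σ_old > 1 for asymmetric, slope-<1 zROCs), encoding animal judgment
correct with probability 0.95, lognormal reaction times (μ = 0, σ = 0.35,
median ≈ 1 s).

**Criterion placement.** The criteria default to the midpoint between the
two strength means ± {0, 0.6, 1.2} SD. The placement was chosen from the
closed form of the 6-point trapezoid ROC: discretizing a continuous
strength axis onto six responses necessarily loses area relative to the
continuous AUC Φ(d′/√2), and ~0.6-SD spacing minimizes that loss (residual
bias ≈ 0.009 at d′ = 1.5; wider or narrower spacings lose more). The
module tests assert the simulated AUC against the exact discrete closed
form, not the continuous value.

**zROC slope at session size.** The slope is ordinary least squares of
Φ⁻¹(hit) on Φ⁻¹(fa) over points strictly inside (0, 1)²; boundary points
are excluded (probit domain). At n = 100 trials the false-alarm probits are
noisy, which attenuates the estimated slope below its asymptotic value
(classic errors-in-variables bias) — single-session slopes near 0.8 under
the equal-variance generator are expected and the bootstrap CI accounts for
it; the large-n tests confirm slope → 1 (equal variance) and < 1
(σ_old = 1.25). The asymmetry call is "CI excludes 1" with a trial-level
nonparametric bootstrap (default 1,000 resamples), our documented choice of
asymmetry test.

**Accuracy split.** "High confidence" defaults to the two extreme codes
{31, 36}; the grouping is a parameter. Accuracy is the raw fraction of
correct old/new judgments (judged old iff code ≥ 34); across sessions we
report a paired t-statistic on raw accuracies.

## Trial pacing

The task's pacing is not fixed by the data format, so it is explicit
configuration: 1.0 s stimulus, 0.5 s delay to the question screen, lognormal
response time capped at 10 s, 0.5 s from response to end-of-trial, 1.0 s
inter-trial interval. Only window *alignment* (onset + 200 ms, 1 s long)
matters to the analyses; pacing affects nothing but total session length.

## Spike-train model

Each unit is a piecewise-constant-rate Poisson process: baseline rate
(default 5 Hz) everywhere, multiplied by a gain (default 3) inside
[onset + 0.2 s, onset + 1.2 s) of trials matching the unit's preference —
preferred category for VS units (any phase), preferred novelty condition
for MS units (recognition only), both multiplicatively for dual units.
Sampling is by thinning at the maximum rate; spikes closer than 3 ms to the
previously kept spike are then deleted (refractory period by deletion
rather than hazard modulation — simpler and directly testable). The
deletion biases rates low by ≈ rate × refractory ≈ 1.5% at 5 Hz and pulls
the Fano factor slightly below 1; tests budget for both. Waveforms are a
fixed biphasic template (difference of two Gaussians, 256 samples at
100 kHz) scaled to a target peak amplitude plus white noise; SNR stored per
unit is peak/noise-SD by construction.

## Selection statistics

Rates are spike counts in the half-open window [t0, t0 + 1 s), t0 = onset +
200 ms, computed with ≥/< comparisons so edge spikes are never counted
twice. The VS screen is a classical one-way F-test across the five
categories on recognition trials (all five levels with ≥ 2 trials required;
fewer raises rather than silently testing a smaller design; an
encoding-trial variant is a parameter away). The MS screen compares mean
rate between new and old trials against a pooled-resampling null: both
conditions' rates are pooled, resampled with replacement into groups of the
original sizes B times, and p = (1 + #{|d*| ≥ |d|}) / (B + 1) — positive by
construction, deterministic given the seed. Whether the original analyses
resampled pooled or within groups, or baseline-corrected rates, is not
determined by the format; the pooled choice is ours and is calibrated:
400 null units reject at 0.03–0.07 at nominal α = 0.05 (the quantity
`scripts/acceptance.py` recomputes). Dual units are counted in the VS, MS,
and dual tallies.

## QC metrics

ISI violations: fraction of inter-spike intervals < 3 ms; pass iff strictly
< 3% (exactly 3% fails). SNR: max |mean waveform| / noise SD. Isolation
distance: squared Mahalanobis distance, under the cluster's covariance, of
the n-th closest non-cluster spike with n the cluster size (the standard
Harris-style definition); undefined (None) when outside spikes are fewer
than cluster spikes or the covariance is singular. When outside spikes are
drawn from the cluster's own Gaussian this statistic sits at the χ²_d
quantile of rank n/m, which the tests verify.

## Problem sizes and determinism

Simulation experiments use 400 null units for bootstrap calibration,
100 seeds for ANOVA power, 200 units (20% VS / 10% MS, gain 3) for
population recovery, 200 sessions for the chance-AUC check, and 20,000
trials for the large-n AUC check — sizes at which every targeted effect is
resolvable well inside its tolerance. All randomness flows from
`numpy.random.default_rng` seeds; per-unit seeds derive from a master seed,
and the same seed reproduces sessions, files, and result tables exactly.

## Known limitations

The generator emulates the statistics the analyses consume, not raw
physiology: no raw broadband signal, spike detection, or sorting (spike
trains are sampled directly), no LFP, no electrode drift or unit
instability, no within-category image structure (placeholder images carry
only a category-mean intensity), and response windows are homogeneous
step gains rather than realistic latency jitter or adaptation. Passing
tests therefore establish the correctness and calibration of the *pipeline*
(parsing, serialization, statistics), not the realism of any biological
parameter. Estimated VS/MS population proportions are biased upward by the
screens' false positives (≈ +α per non-selective unit), which the recovery
test's ±5-point band anticipates; session-level zROC slopes are attenuated
at n = 100 trials as noted above.
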