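# Methods

This note documents the models, procedures and design choices behind
`middecode`: a pipeline for multivariate decoding of EEG responses to the two
binocular cues to motion in depth (MID) — changing disparity (CD) and
interocular velocity difference (IOVD) — validated end-to-end on synthetic
sessions with known ground truth.

## Stimulus synthesis (`middecode.stimgen`)

Stimuli are random-dot stereograms presented in an annulus (inner radius 1°,
outer radius 6°) at one dot per deg², with Gaussian dot profiles (σ = 0.05°)
and balanced ±1 contrast polarities. A 250 ms probe at 60 frames/s per eye is
15 frames, one full linear ramp.

* **CD**: every frame is a fresh, binocularly paired random-dot field (no
  monocular motion energy); the pair disparity ramps linearly between
  +32 and −32 arcmin. Sign convention: positive = uncrossed/far; TOWARD
  ramps far→near. Antisymmetric ramps are built from integer numerators so
  the stimulus-averaged disparity is *exactly* zero in floating point.
* **IOVD**: each eye sees an independent dot field drifting coherently with
  equal and opposite velocity; the monocular lateral shift ramps from −128
  to +128 arcmin (sign by eye and direction). The ramp-span choice (rather
  than 0→128) mirrors the inclusive ±peak endpoints of the CD ramp. Dots
  live 50 ms (3 frames) and die in staggered cohorts of ⌈N/3⌉, reborn at
  random positions. Per-eye dot fields are confined to alternating 0.5°
  horizontal strips (left eye even strips, right eye odd, counted from the
  annulus bottom). Where a left-eye and right-eye dot each fall within one
  dot width (operationalized as 4σ = 0.2°) of the same strip border and
  within one dot width of each other horizontally, the right-eye dot's
  polarity is flipped to be opposite — a deterministic rule that disrupts
  spurious binocular matches.
* **STATIC**: CD-style refreshing dot fields pinned at −32 (near) or +32
  (far) arcmin with zero stereomotion velocity.

Dot counts are fixed at `round(density × annulus area)` = 110 (not Poisson)
so count invariants are exact. Birth positions are rejection-sampled so a
dot's entire remaining trajectory stays inside the annulus (and inside the
eye's strips for IOVD); this keeps "every dot center inside the annulus" an
exact invariant instead of a statistical one. The cosine contrast ramp
(0.5° at each annulus edge) is recorded as a per-dot weight; rendering is out
of scope.

## Synthetic EEG sessions (`middecode.synth`)

A session emulates the statistical structure the decoding analysis assumes:
64 channels at 1000 Hz, epochs −200..800 ms, 1260 retained trials
(6 blocks × 210) over four equally frequent conditions (CD/IOVD × toward/
away), or 630 trials over two conditions for the static-disparity control.

**Signal model.** Each epoch is a sum of Hann-windowed components
`amplitude × hann(t; onset, duration) × topography`, where each component's
sign/scale per condition is given by a loading map. Default components:

| component        | onset (ms) | duration (ms) | loads on |
|------------------|-----------|---------------|----------|
| visual_onset     | 80        | 200           | all conditions, +1 |
| cue              | 120       | 400           | CD +1, IOVD −1 |
| cd_direction     | 320       | 350           | CD toward +1 / away −1 |
| iovd_direction   | 296       | 340           | IOVD toward +1 / away −1 |
| shared_direction | 500       | 250           | toward +1 / away −1, both cues |
| static_transient | 288       | 24            | near +1 / far −1 |

Topographies are spatially smoothed random vectors, mutually orthogonalized
(Gram–Schmidt) so that cue, direction and shared information are linearly
separable; the shared component uses one topography across both cue types,
which is exactly what makes cross-trained decoding possible. Per-participant
multiplicative amplitude jitter ~ lognormal(0, 0.2) creates between-subject
variance for the group t-test.

**Noise model.** 1/f ("pink") noise with exponent 1 and 10 µV RMS per
channel, spatially mixed by a fixed random operator (strength 0.3); a 10 Hz
alpha oscillation (4 µV RMS at the strongest channel, fixed smooth spatial
profile, random phase per epoch); and 2 µV white sensor noise. These are
conventional EEG assumptions, not measurements.

**Amplitude calibration.** Component amplitudes were calibrated once against
this noise model so that group-mean peak decodabilities land in the upper
part of a 60–85 % band (cue ≈ 0.82, within-cue direction ≈ 0.8, static
≈ 0.74, cross-trained ≈ 0.6), preserving the qualitative ordering
cue > within-cue direction > cross-trained transfer. The upper part of the
band was chosen deliberately: onset-latency recovery requires statistical
power in the first samples of a Hann rise, and amplitudes at the bottom of
the band would make onset estimates systematically late at practical
iteration counts.

**Determinism.** Labels, noise and jitter use independent named RNG streams
derived from the master seed, so e.g. a null session (all amplitudes forced
to zero) retains the exact label sequence of its signal-bearing counterpart.
Participants are generated lazily; a full default session never has to be in
memory at once.

## Preprocessing (`middecode.preprocess`)

* **Low-pass 30 Hz**: 4th-order Butterworth, applied forward–backward
  (zero phase) by default; only the cutoff is prescribed by the analysis
  being modeled, order and phase behavior are exposed in the config.
  Epochs are filtered directly (with the filter's reflection padding); at a
  30 Hz cutoff the difference from filtering continuous data is negligible.
* **Downsampling 1000 → 125 Hz by linear interpolation**: the output grid is
  `t_k = −200 + 8k` ms, k = 0..124. 125 points at 8 ms spacing cover
  −200..792 ms; an inclusive −200..800 endpoint grid is arithmetically
  incompatible with 125 points, so the sample count is fixed at 125 and the
  grid documented. Interpolation is exact (bit-level copy) where grid points
  coincide with raw samples.
* **z-scoring** standardizes each pseudo-epoch *across channels at every
  timepoint* (mean 0, SD 1 over the 64 electrodes). The alternative —
  per-channel over time — is selectable (`zscore_axis="time"`) but not the
  default, for a concrete reason found during validation: a channel's mean
  and SD over the epoch include the evoked response, so time-axis scoring
  leaks post-stimulus signal into baseline samples and produces systematic
  *pre-stimulus* decodability (spurious early clusters). The across-channel
  variant is purely per-timepoint, leaves the baseline at chance, and is the
  natural reading of standardizing "across electrodes".

## Bootstrap pseudo-epochs (`middecode.resample`)

Per condition and iteration, 21 pseudo-epochs are formed by averaging 10
epochs each, then z-scored. Draws are without replacement within a
pseudo-epoch **and disjoint across the 21 pseudo-epochs of one iteration**
(a partition of a random permutation of the pool; 21 × 10 = 210 ≤ 315).
The disjointness matters: if raw epochs are reused across pseudo-epochs,
every pseudo-epoch inherits the pool's realized noise mean, the held-out
pseudo-epoch is correlated with the training set, and leave-one-out accuracy
is inflated far above chance even for pure noise (the label-shuffle chance
control could then never come out at 50 %). When a pool is smaller than
`n_draw × n_means`, the code falls back to independent draws and logs that
leave-one-out optimism is possible. Pooled superclasses (direction pooled
over cue, cue pooled over direction) draw balanced 5+5 from their member
conditions. Iterations use counter-based child seeds, so any iteration can
be regenerated independently and in parallel.

## Decoding (`middecode.decode`)

Per timepoint, a soft-margin linear SVM (C = 1) is trained on the 64-channel
patterns. The default fold scheme holds out one pseudo-epoch per class per
fold: 21 folds, 40 training epochs, 2 test items, accuracy = correct/42 —
this keeps training balanced while honoring a 40-epoch training set; plain
leave-one-out (41 train, 1 test, 42 folds) is selectable. Ties (decision
value exactly 0) predict the class with the lower sort order.

The timecourse loops need millions of tiny (40 × 64) fits, which is
prohibitively slow one-at-a-time through a general-purpose SVM library, so
the inner engine is a vectorized dual coordinate-descent solver that fits
thousands of problems simultaneously (hinge-loss dual; intercept via an
augmented constant feature of scale 5, making its regularization negligible;
float32 internals; a fixed coordinate schedule so results are independent of
batch chunking). At full convergence the solver matches `sklearn.svm.SVC`
predictions essentially exactly; the production sweep cap (40) trades a
little boundary precision for an order-of-magnitude speedup and is validated
against SVC in the test suite. The public single-fit path
(`fit_linear_svm`) uses the libsvm solver directly.

Cross-trained decoding fits on all 42 pseudo-epochs of one condition pair
and tests on all 42 of the other pair (toward/away semantics must match; no
fold overlap is possible by construction). Relabeled decoding
(`relabel_and_decode`) applies identical machinery to arbitrary balanced
2-class relabelings, warning about and re-balancing unbalanced ones by
stratified subsampling.

## Group statistics (`middecode.cluststats`)

Pointwise one-sample t-tests compare decoding accuracy with the 50 % chance
level (one-sided by default — below-chance decoding is not interpretable
here; a two-sided variant is available). Timepoints with t above the
cluster-forming critical value (α = 0.05, df = n−1) form temporally adjacent
clusters with mass = Σt. The null distribution of the maximum cluster mass
is built by flipping the sign of each participant's (accuracy − 0.5)
timecourse — the standard one-sample sign-flip null, valid for symmetric
between-participant variation. Cluster p-values use the add-one formula
`(1 + #{null ≥ mass}) / (1 + n_permutations)` (plain proportion for
exhaustive enumeration, where the identity pattern is already included);
default 5000 permutations. Infinite-t sentinels from zero-variance
timepoints join runs with their mass contribution capped at 100. A
Bonferroni-corrected pointwise test (α / 125 per timepoint) is provided as
the conventional alternative.

## Orchestration (`middecode.pipeline`)

`run_experiment` executes the nine-comparison matrix — pooled direction,
pooled cue, CD direction, IOVD direction, cue within toward, cue within
away, static near/far, and cross-trained decoding both ways — over a main
and a static-disparity session, producing per-participant timecourses, group
cluster results, CSV/JSON artifacts and a manifest. All stage seeds derive
deterministically from the master seed; two runs from the same config are
byte-identical. Epochs travel in an HDF5 container (`middecode-epochs-1`
schema: float64 little-endian arrays, UTF-8 labels) with a JSON sidecar.

## Problem sizes in the test suite

The validation suite runs the full pipeline at deliberately reduced scale,
chosen as the smallest sizes at which each property is statistically
decidable: latency recovery uses 10 participants × 16 bootstrap iterations
with sessions generated at 250 Hz raw rate (the 125 Hz analysis grid is
unchanged; 8 ms onset resolution is preserved); the family-wise error check
decodes 16 genuinely null sessions once and assembles 100 simulated groups
of 8 by participant-level sign flipping (valid under the symmetric null;
reusing rows makes simulations mildly dependent, which the binomial slack
accommodates); the chance control uses one fully default participant with 50
iterations. Onset-recovery tolerance is ±24 ms (3 samples on the 8 ms
grid).

## What the synthetic generator does and does not show

Passing tests demonstrate that the pipeline recovers what was injected:
latencies, chance behavior, error control, transfer only through shared
information. The generator does not emulate eye-blink or movement
artifacts, volume-conduction head geometry, non-stationary noise, trial-order
effects, or realistic between-condition correlations beyond the component
model — so test results validate the *analysis machinery*, not any claim
about real recordings. Decoding accuracies on real EEG depend on effect
sizes and noise that the calibration here only stylizes.

## Onset-latency bias of cluster-based onsets

Reading a component's onset off the first suprathreshold timepoint of the
first significant cluster is systematically *late* for gradually rising
signals. A Hann envelope carries only ~4 % of its peak amplitude 24 ms after
onset (at the default durations), and linear-SVM decoding accuracy is
quadratically suppressed at small SNR — the weak signal both shrinks the
class separation and corrupts the learned weight vector — so the accuracy
bias in the first few samples after onset sits far below the detection floor
set by pool-level accuracy variance (≈0.01 SD per participant and
timepoint). At the calibrated SNRs the achievable onset precision is on the
order of +50–100 ms regardless of participant or iteration count. Users
estimating onsets from cluster starts on real data should expect the same
conservative (late) bias; peak latencies are much better behaved than
onsets.

## Known limitations

* The bootstrap scheme requires `pool ≥ n_draw × n_means` per condition for
  leakage-free leave-one-out; smaller pools fall back to a documented,
  optimistic mode.
* The batched SVM solver's default sweep cap can flip predictions for test
  points essentially on the decision boundary (≈1–2 % of noisy-case
  predictions); accuracies are unaffected beyond that resolution.
* Cluster inference is over time only (no channel-adjacency clustering or
  TFCE); vendor EEG formats are not read.
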