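# Methods

`emgadapt` implements a complete surface-EMG pattern-recognition pipeline
for the *repeated-use* setting: a classifier is trained on one recording
session ("Day 1") and must keep working on later sessions after the
electrodes have been taken off and put back on.  Electrode re-donning
changes electrode positions and skin impedance, which drifts the feature
distribution from day to day and degrades a fixed classifier.  The package
provides the feature extraction, Day-1 feature selection, four
SVM adaptation strategies, the evaluation protocol, and a synthetic
multi-day EMG generator that makes the whole benchmark reproducible
without human recordings.

## Signal model and segmentation

Input data are organised as subject × day × motion × trial: 11
shoulder/elbow motion classes, 5 trials per motion per day, 7 channels at
1500 Hz (band 20–450 Hz), 7-s trials of which the central 5 s are
analysed.  Band-pass and mains-notch filtering are treated as applied at
acquisition; a zero-phase 4th-order Butterworth 20–450 Hz + 50 Hz notch
utility (`data.bandpass_notch`) is provided for external raw data but is
not part of the benchmark path, since the synthetic generator produces
band-limited signals directly.

Trials are segmented with a 250-ms window advanced in 50-ms steps
(N = 375 samples per window at 1500 Hz; consecutive windows overlap by
200 ms).  A 5-s trial yields 96 windows, a day therefore
11 × 5 × 96 = 5280 windows.

## Features

Per channel, 14 features totalling 42 dimensions (294 over 7 channels;
channel-major concatenation):

- **MAV, RMS, WL** — mean absolute value, root mean square, waveform
  length.  **VAR** is the *uncentred* second moment Σx²/(N−1): windowed
  band-passed EMG is essentially zero-mean, and the uncentred form is the
  convention of the myoelectric feature literature this pipeline follows.
- **SSC, ZC** — slope-sign changes with amplitude-product threshold 10
  (amplitude² units) and zero crossings with amplitude-step threshold 25.
  The thresholds assume signals with typical sample magnitudes of order
  10–100 native units; the synthetic generator is calibrated to that
  scale.
- **AR5, AR6** — Burg autoregressive coefficients, two separate fits (not
  a truncation of one fit).  Burg was chosen over Yule–Walker for its
  stability on 375-sample windows; Yule–Walker remains available via
  `FeatureParams(ar_method="yule-walker")`.  The Burg solver is a batch
  lattice recursion vectorised over windows × channels (≈ 37 000 fits per
  subject-day must run in seconds); it agrees with the reference scalar
  implementation in statsmodels to machine precision (asserted in tests).
  Constant signals return zero coefficients with a warning rather than
  failing.
- **CC** — 5 cepstral coefficients from the AR6 fit via the standard
  AR-cepstrum recursion c₁ = −a₁, c_k = −a_k − Σᵢ(1 − i/k) aᵢ c_{k−i}.
  A variant recursion with the a-index held at k is retained behind
  `cc_literal_recursion` for comparison only.
- **MNF, MDF** — mean and median frequency of the one-sided boxcar
  periodogram (no detrending, bin width rate/N = 4 Hz).  MDF is the bin
  at which cumulative power first reaches half the total; the half-total
  power itself is exposed as `half_total_power` for completeness.
- **WTWL, WTVAR, WTMAV** — waveform length, uncentred variance and MAV of
  the six sub-bands (cA5, cD1…cD5) of a 5-level db2 discrete wavelet
  transform, symmetric boundary mode.

All extractors are deterministic; identical windows give bit-identical
features.

## Feature selection (Day 1 only)

Selection runs once on Day-1 features and the chosen dimensions are
reused unchanged on all later days — re-selecting per day would defeat
the purpose of a quick re-calibration.

- **NFS** — no selection; all 294 dimensions.
- **SFS** — greedy forward selection over the 14 feature *groups* (one
  feature across all channels), scored by the Fisher-type criterion
  J3 = trace(S_w⁻¹ S_m), where S_w and S_b are the class-uniform
  (1/M-weighted) within- and between-class scatter matrices and
  S_m = S_w + S_b.  Selection stops when no remaining group strictly
  increases J3 (tolerance 1e−9); ties break by canonical group order, so
  the procedure is deterministic.  S_w gets a ridge of
  1e−8 · trace(S_w)/D before inversion: a 294-dim scatter estimated from a
  few thousand windows is routinely ill-conditioned.  J3 is computed on
  raw (unstandardised) features; J3 is invariant under invertible linear
  maps, so this choice is immaterial up to conditioning.
- **PSO** — particle swarm over individual dimensions.  Particles hold
  continuous positions in [0,1]^D decoded by thresholding at 0.5
  (real-coded PSO with threshold decoding avoids inventing a binary-PSO
  transfer function the formulation does not define).  Update:
  v ← 0.7·v + 2·r₁·(pbest−x) + 2·r₂·(gbest−x), fresh uniform r₁, r₂ per
  dimension per step, velocities clamped to ±0.5, positions clipped to
  [0,1]; velocities start at zero, positions uniform.  Defaults: 80
  particles, 50 iterations.  Fitness is the validation accuracy of a
  linear SVM on a stratified 4/5–1/5 split of the Day-1 windows, drawn
  once per run so fitness is comparable across particles and iterations;
  standardisation is fitted on the training split only; an empty mask
  scores 0.  A single seed governs split, swarm initialisation and the
  random factors, making runs exactly reproducible.

## Classifiers

All four methods share a linear-kernel one-vs-one SVM (C = 1, configurable)
and one standardisation fitted on the Day-1 training set and *frozen* for
every later day — re-fitting it on a new day would be extra unsupervised
adaptation outside the protocol.

- **N-SVM** — train on Day 1, never adapt (the baseline the others must
  beat).
- **I-SVM** — batch-incremental: calibration vectors are consumed in
  arrival order in batches of 48; each step retrains on {current support
  samples} ∪ {batch} and keeps the new support samples.  A shuffled order
  is available behind a seed-controlled flag.
- **T-SVM** — instance-transfer boosting (TrAdaBoost) over
  {Day-1 training set} ∪ {calibration set}, 26 rounds.  Each round trains
  a weighted SVM (weights enter as per-sample cost multipliers — a
  weighted hinge loss, deterministic, no resampling) on the current
  training set, then reweights: misclassified *source* samples shrink by
  β = 1/(1 + √(2 ln n_src / n_rounds)); misclassified *calibration*
  samples grow by (ε/(1−ε))⁻¹ with ε the weighted calibration error
  clipped to [1e−10, 0.499]; weights renormalise to sum 1.  The round's
  training set keeps source samples with weight ≥ 0.1 × mean source
  weight (outdated Day-1 data is discarded) and calibration samples with
  weight ≥ mean calibration weight (hard new-day examples are kept).  The
  returned model is chosen from the last half of the rounds (14–26 for 26
  rounds): the round whose training set contained the most calibration
  samples, ties toward the latest round.  Counting samples rather than
  summing their weights is the default reading of "most data"; the
  weight-sum variant sits behind `select_by_weight`.
- **TI-SVM** — the TrAdaBoost stage rebuilds the training set around the
  target-day distribution, then the selected round's model is
  incrementally adapted with the full calibration set (batches of 48).

## Evaluation protocol

Day-1 windows split 4/5 training / 1/5 validation (stratified).  Each
target day (days 2–5) runs a *reverse* five-fold cross-validation: the
held-in fifth (1056 of 5280 windows; 22 I-SVM batches) is the calibration
set and the remaining four fifths are the test set — inverted relative to
conventional CV because adaptation data is deliberately scarce.  Folds
are stratified by motion (time-contiguous folds available behind a flag).
Test windows touch nothing but the final prediction call; an audit test
verifies that permuting test labels leaves every trained model artifact
hash-identical.

Three indices per (subject, selector, classifier, day, fold):
classification accuracy, training time (base training plus adaptation;
base only for N-SVM), and response time (wall-clock classification of the
test set).  `summarize` reports per-scheme mean ± sd and paired
per-subject differences with Wilcoxon signed-rank p-values as a
nonparametric ordering check.  Training-time medians are asserted in
tests only where the workload difference dominates timer noise (T-SVM and
TI-SVM each > I-SVM > N-SVM); the TI-vs-T margin is ~2% of runtime and is
reported, not asserted.

## Synthetic generator

Each channel is band-limited Gaussian noise (4th-order Butterworth band
around a per-channel centre frequency in 60–150 Hz, bandwidth 50–90 Hz)
whose amplitude follows the motion's activation pattern — the standard
phenomenological surface-EMG model.  A subject profile is an 11 × 7
activation matrix: the five single motions activate distinct 2-channel
synergies over the seven muscles (deltoid heads, biceps, triceps,
brachioradialis, flexor carpi radialis) and the six compound motions are
0.75 × the sum of their shoulder and elbow constituents, which makes
neighbouring classes naturally confusable.  Profiles are redrawn until all
pairwise pattern correlations are < 0.95.

Within-trial realism: a slow lognormal effort envelope (2nd-order low-pass
at 1.5 Hz, log-sd 0.45) modulates each channel, and each trial carries a
lognormal amplitude jitter (log-sd 0.08).  A white-noise floor sits at
−20 dB relative to the weakest motion's strongest channel.  These
constants were calibrated once so that the generator meets its stated
difficulty targets: within-day linear-SVM accuracy in the 85–99% band
(measured ≈ 96–97%), a vanishing cross-day gap (≤ 2%) at zero shift, and
a ≥ 5% gap (measured 12–14%) at full shift.

Electrode re-donning is a per-day `ShiftModel`, all components scaled by
one magnitude s ∈ [0,1] (default 1): per-channel lognormal gain
(σ = 0.25 s), near-identity row-stochastic channel crosstalk (off-diagonal
mass κ = 0.15 s), and per-channel spectral offset (σ = 10 s Hz).  Day 1
is always the identity and s = 0 makes all days identically distributed.

Every trial draws from its own `SeedSequence(master, subject, day,
motion, trial)` stream, so any single trial regenerates identically in
isolation and the whole benchmark is bit-reproducible from one seed.

What the generator does **not** emulate: motor-unit physiology, force
levels, limb-position effects, non-stationary fatigue drift within a day,
or electrode artifacts.  Passing benchmarks on this generator therefore
show that the adaptation machinery behaves as designed under
gain/crosstalk/spectral drift — not that the specific accuracy numbers
transfer to human recordings.

## Problem sizes used in tests and the acceptance script

The structural constants (375-sample windows, 96 windows/trial, 55
trials/day, 5280 windows/day, 1056-vector calibration fifths, 22
incremental batches, 294 feature dimensions) are verified at full per-day
scale.  The classifier-ordering benchmark runs at a reduced scale chosen
as the package's standard desk configuration: 3 subjects, target days
2–3, full 55-trial days, but non-overlapping 250-ms windows (20 per trial
instead of 96) — the same trials, thinner window sampling, which leaves
the per-window feature distribution untouched while cutting the SVM
workload ~25-fold.  PSO toy checks use a 10-dim two-class problem where
exactly two dimensions carry partial (jointly required) signal.

## Known limitations

- The incremental path is order-dependent by design; it is only
  sanity-bounded (within 2%) against a from-scratch retrain on support ∪
  calibration, not equivalent to it.
- With an easy day the TrAdaBoost stage may select a round whose model
  predicts identically to the incremental follow-up, making T-SVM and
  TI-SVM coincide on some folds.
- J3 requires S_w to be invertible after the ridge; heavily collinear
  feature subsets can still fail, and the error suggests reducing the
  dimension.
- Timing indices are wall-clock and environment-dependent; only coarse
  ordinal relations are meaningful.
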