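# Methods

This note documents the models, conventions and numerical choices behind
`touchdecode`, and what the synthetic-session tests do and do not show
about real recordings.

## Task structure and containers

A session is a `SessionBundle`: a `channel × trial × bin` tensor of
firing rates on a uniform half-open bin grid `[t, t+Δ)` with a boundary
exactly at touch onset (t = 0), plus a per-trial table (condition, run,
collection set, catch flag, onset time).  Defaults mirror the study
design: 9 conditions × 7 runs × 10 trials (+1 catch per 11-trial run),
50 ms bins over [−4, +2] s, 5 s ITI with 0–3 s uniform jitter, 1 s touch,
and visual-approach information from 0.5 s before onset in visual
conditions.  Catch trials are generated (labelled with a different
condition and flagged) but excluded from every analysis; their handling
in the original experiment is not documented, and exclusion keeps exactly
70 trials per condition.  Set labels (seen/third-person/object touches =
set 1; blind/VR = set 2) are bookkeeping only — no drift is simulated by
default.

## Simulator

Noise-free rate for a trial of condition c:

    r(ch, t) = baseline(ch) · [1 + (gain(ch,c) − 1) · k(t)]

with a rectangular-rise/exponential-decay kernel k(t): 0 before the
latency, 1 from latency to touch offset (1 s), then exp(−(t−D)/τ) with
τ = 0.3 s by default.  The kernel is integrated analytically within each
bin, so a latency falling mid-bin elevates that bin by the covered
fraction — this is what makes sub-bin latencies recoverable at the
correct bin midpoint, and it is the simplest shape producing a sharp
post-onset peak with a gradual return to baseline.

Noise is multivariate Gaussian on rates, drawn independently per (trial,
bin) from a channel covariance and floored at 0.  The default covariance
is `σ² [(1−c)I + cJ]` with σ = 3 Hz and uniform channel correlation
c = 0.2 on a 10 Hz baseline — a realistic variability for 50 ms
multi-unit counts with a shared common-mode component; the Gaussian
default keeps the covariance analytically checkable (the test suite
verifies empirical convergence at 2000 trials).  A Poisson count stage
can be layered on top.  An entry of the planted gain matrix ≥ 1.2 defines
the ground-truth "tuned" mask used for recovery scoring.

Two optional across-set drifts exercise the stability checks: a
multiplicative rate drift on set-2 trials (visible in raw rates, removed
by run-wise baseline normalization — a uniform gain drift cannot survive
it, which is why the normalization exists) and a noise-amplitude drift
(visible in the normalized ITI variability).

Broadband snippets plant a stereotyped waveform (one-sample downstroke
to the trough, ~1 ms exponential recovery with a small positive rebound)
in white noise; overlapping waveforms are rejected at generation so
detections can be scored one-to-one.  The sharp downstroke pins the
threshold-crossing sample to the planted trough within ±1 sample.

What the simulator does **not** emulate: spike sorting structure
(waveform clusters), non-stationary baselines within a run, bursting or
refractory statistics of real multi-unit counts, eye position, and the
pressure-sensor alignment of touch onset (onsets are given).  Passing
recovery tests therefore demonstrates correctness of the analysis chain,
not robustness to every artifact of real recordings.

## Preprocessing

* Threshold crossings at k × RMS (k = −3.5) of the trace itself; a
  median-based robust RMS is available behind a flag.  A 1 ms refractory
  lockout prevents one waveform being counted twice (the convention is
  not documented in the original description; 1 ms matches the waveform
  length).  A flat (all-zero) trace yields no events.
* Binning divides counts by the bin width (Hz); events outside the epoch
  are silently dropped; an event exactly at onset belongs to [0, Δ).
* Baseline normalization divides each channel, within each run, by the
  across-trial mean of the [−4, −2.5] s window.  Channels with a zero
  baseline in any run are excluded from the normalized bundle and listed
  in `meta["excluded_channels"]` (division undefined; exclusion is
  conservative).  After normalization the baseline-window mean is exactly
  1 per channel per run.
* Rebinning averages constituent bins (not sums), so normalized values
  keep their scale; it requires an integer width multiple.
* Stability checks: two waveform SNR metrics (mean-waveform trough over
  residual RMS; trough over across-event SD at the trough sample),
  averaged over runs per set, plus mean/SD of run-baseline-normalized ITI
  rates over [−4, −1] s, each compared across the two sets with a paired
  Wilcoxon sign-rank over channels.  All-zero differences report p = 1.
  The ITI window deliberately differs from the normalization window; both
  are configurable constants.

## Decoding

Per split: balanced halves per class (odd class sizes floor to equal
halves and drop the remainder), SVD re-fit on the training half only
(train-mean centered; rank-deficiency truncates), projection to
min(40, rank) dimensions, then a two-class linear discriminant with
pooled covariance shrunk toward a scaled identity (λ = 1e−6, raised by
decades on singularity, pseudo-inverse as last resort).  A discriminant
score of exactly zero goes to the first class in sorted label order —
deterministic tie-breaking.  Run and session membership are ignored when
splitting.

The permutation null shuffles labels once per iteration *before*
splitting, then runs identical machinery.  Significance is the most
stringent of the {99, 97.5, 95}% percentile-CI levels at which the
accuracy and null distributions do not overlap (`***`/`**`/`*`, else
`ns`).  Note the CI-overlap rule is conservative: on signal-free data the
`*` tier fires well below 5% of the time (the calibration test bounds it
at the binomial tolerance).

Generalization decoding defines the two classes by condition lists
separately for train and test.  Identical selectors fall back to held-out
halves (reproducing the pairwise decoder); disjoint selectors train on a
balanced random half of the training trials each iteration and test on
all test trials.  Mixed (partially overlapping) selectors are rejected.

## Crossnobis RSA

Distances use run-wise folds: fold m pools the m-th run of every
condition, giving 7 folds with 10 trials per condition each.  The noise
covariance is estimated per time bin from residuals around each
condition × fold mean (so the means entering the distances are not
reused), pooled, and shrunk toward its diagonal with an analytic
optimal-shrinkage intensity (ratio of summed off-diagonal sampling
variances to summed squared off-diagonals) floored at 0.01 — the floor
guarantees invertibility even with duplicated channels.  Distances are
divided by the channel count so values are comparable across simulated
population sizes; only relative structure is interpreted.  The diagonal
is stored as NaN and excluded from every statistic.  Unbiasedness (mean
distance ≈ 0 for identical condition distributions) is verified by
simulation, and small-configuration values against a brute-force
fold-pair enumeration at 1e−10.

RDM–RDM comparisons vectorize the lower off-diagonal triangle, use
Pearson r, and multiply p by the number of comparisons (capped at 1);
constant RDMs return NaN.  MDS clips negative crossnobis values to 0
(embeddings need nonnegative dissimilarities), minimizes metric stress
from seeded random restarts, reports normalized stress-1 and per-pair
absolute distortions, and aligns successive bins by orthogonal
Procrustes.  An all-zero RDM short-circuits to a zero embedding.

## Tuning, bootstrap counts, onsets

The regression stacks, per channel and 0.5 s bin in [−1, 2] s, the
normalized single-trial rates with 70 appended baseline entries that are
identical copies of the channel's mean baseline-window rate across all
trials.  This follows the original procedure exactly; note the copies
deflate residual variance slightly (flagged here, not "fixed").  Each
condition coefficient gets a two-sided t-test of β = 0; the Holm family
is all condition × bin tests of one channel (the bin-inclusive family is
the conservative reading; the family is configurable via the window and
bin-width arguments).  Zero-variance channels return NaN p-values and are
never rejected.

The count bootstrap resamples each condition's trials with replacement
(to its own count), recomputes the baseline entries, refits everything
and counts tuned channels; CIs are percentile intervals and condition
pairs are tiered by CI non-overlap at {95, 97.5, 99}%.  Because
duplicated trials shrink residual variance, resampled counts run slightly
above the point estimate — inherent to refitting t-tests on bootstrap
samples; the intervals are for *comparing* conditions, not for absolute
calibration.  The fits are vectorized across channels (the design matrix
is identical for every channel and every resample), which is what makes
1000 iterations cheap.

Onset/offset: the per-trial traces of the tuned channels are averaged
(50 ms bins); the threshold is the 95th percentile of the across-trial ×
baseline-bin distribution of that average.  Onset = midpoint of the first
bin above threshold in the search window; offset = midpoint of the first
bin below threshold *after the peak bin* (a flag switches to
"after onset"; with a unimodal response both rules agree).  A trace that
never crosses reports an undefined onset rather than a value.  CIs
bootstrap over trials, re-deriving the threshold in every resample; the
resampling unit is trials, not channels.

Overlap sets classify each tuned channel by the locations of its tuned
conditions (arm-only / finger-only / both, overall and within touch
type) and lay channels out on two 48-electrode grids (6 × 8 by default,
configurable).

## Pipeline and problem sizes

`run_pipeline` chains simulate → drop catch → normalize → decode → RSA →
tuning/onsets and scores recovery against the planted truth.  Every stage
seeds from the global seed through `SeedSequence.spawn`, so a fixed
configuration is byte-identical across runs (the output directory is not
part of the summary).  Reduced resampling defaults (100 decode splits,
500 count bootstraps, 1000 onset bootstraps) keep a full run around a
minute on one core; `full_scale=True` switches to the full-scale counts
(1000 / 1000 / 10000).  The test suite and the acceptance script use the
reduced counts and correspondingly sized simulation batches (e.g. 200
signal-free sessions for null calibration, 1000 single-bin simulations
for crossnobis unbiasedness, 102 sessions for latency recovery); these
sizes give binomial/SE tolerances well inside the margins being asserted.

## Known limitations

* The baseline entries in the tuning regression are exact copies, so the
  regression's error model is mildly optimistic; Holm across the 54-test
  family keeps the realized per-channel false-positive rate far below
  α in the recovery tests.
* Crossnobis values scale with the shrinkage intensity chosen by the
  analytic rule; only relative/rank structure should be interpreted.
* The CI-overlap significance tiers are conservative rather than exact
  α-level tests.
* The simulator's Gaussian rate noise cannot produce the mean–variance
  coupling of real spike counts unless the Poisson stage is enabled.
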