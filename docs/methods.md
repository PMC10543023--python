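# Methods

This note documents the models and procedures `nstream` implements, the
defaults that matter, what the synthetic generators do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Stream model

All computation is defined on causal batches. An offline recording of
duration T at rate fs is replayed as sliding windows of `batch_window_ms`
(default 1000 ms) whose end advances by `feature_interval_ms` (default
100 ms); the first feature row is emitted only once a full window exists,
never from zero-padded data, so a recording yields
`floor((T − window)/interval) + 1` rows. Batch emission cadence equals the
feature interval — the stream is a sliding window with hop = interval,
which is what gives the 100-ms feature resolution. Feeding batches one at
a time through `Stream.process_batch` is the same code path as
`Stream.run`, so offline and online results are identical by
construction, and a causality fuzz test checks that perturbing a sample
at time t never changes a feature row ending before t.

Channel roles come from a table modeled on the BIDS iEEG `channels.tsv`
(name/type/status) with extension columns: `used`, `target` (the label
channel, e.g. rectified EMG or a button trace), `rereference`
(`none`, `common_average`, `bipolar:<partner>`), `new_name`, and optional
x/y/z coordinates in mm. Bad channels are retained but unused unless
explicitly overridden. The common average is computed over used, good,
non-target channels only; target channels are never re-referenced and
never enter the average.

## Preprocessing

* **Resampling** (default target 1 kHz): polyphase for rational rate
  ratios, Fourier otherwise; identity when the rates match.
* **Notch filter**: IIR notch (quality factor 20) applied
  forward-backward *within* the batch. A causal single-pass IIR restarted
  on every self-contained batch rings at the batch start and leaves ~10 %
  residual line power over a 1-s window; batch-internal zero-phase
  filtering avoids that while remaining causal at the stream level,
  because a batch only ever contains past samples.
* **Normalization**: features (not raw samples) are z-scored against the
  rows of the trailing 30 s, excluding the current row, and clipped at
  ±3. The standard deviation uses the population (divide-by-n)
  convention. Columns with zero variance normalize to 0, not NaN, so a
  constant feature cannot poison a classifier; rows seen before two rows
  of history exist also emit 0. During warm-up (< 30 s of history) the
  window is whatever history exists. Window membership uses a 1-ns
  timestamp tolerance so online processing and an offline trailing-window
  recomputation agree bit-for-bit at window boundaries.
* **Artifact rule**: a run of unchanged first difference lasting at least
  48 ms (12 samples at the 250-Hz device rate; rounded to samples at
  other rates) is masked over its full extent. One rule covers both
  artifact classes: flatlines (zero derivative, e.g. stored stimulation
  segments) and clipping (constant derivative, amplifier saturation
  ramps). Each stimulation pulse additionally masks [t, t + 2 s] on all
  channels. NaN samples never form runs, so detection is idempotent on
  already-masked data. Feature rows whose batch window overlaps a masked
  sample become NaN and are dropped (never imputed) before decoding.

## Features

**Band power.** Each band is computed on a trailing sub-window of
`max(2 cycles of the band's low edge, 100 ms)`, capped at the batch — low
bands integrate longer history, high bands stay temporally sharp. The
sub-window is Hann-tapered (periodic convention) and band power is the
one-sided periodogram integrated over bins with low ≤ f ≤ high, scaled so
an in-band sinusoid of amplitude A contributes A²/2. With adaptation
disabled and a contiguous band partition, the band powers sum to the
signal power (Parseval, up to windowing loss ~10 %); scaling a channel by
c scales every band power by c². Band powers are kept linear (not
log-transformed) — the trailing z-scoring largely absorbs the difference.

**Coherence.** Magnitude-squared coherence via Welch averaging over 4
half-overlapping Hann segments (single-segment MSC is identically 1 and
is rejected), averaged over band bins. The known small-sample bias
(~1/segments for independent signals) is exercised in tests.

**Waveform shape.** Troughs are strict three-point local minima flanked
by the nearest local maxima (peaks symmetrically); events whose flanks
fall outside the window are dropped, and no prominence-based pre-filter
is applied (a minimum-distance hook exists in the detector). Per event:
prominence = mean of the two flanking amplitudes minus the event
amplitude (sign-flipped for peaks); sharpness = mean deflection against
the samples 5 ms before and after, reported as an absolute value so
trough and peak sharpness share one scale under max-aggregation; the
5-ms offset is `round(0.005·fs)` samples and events whose offset leaves
the window contribute no sharpness. Width is the flank-to-flank span;
decay/rise times are the limb durations into and out of the event
(swapped for peaks, so time reversal exchanges them); steepness is the
maximum one-sample difference on the limb; interval is the spacing to the
previous same-kind event. Window aggregation defaults to max for
prominence/sharpness and mean for the timing metrics.

**Bursts.** The burst trace is a band-power feature column (post-
extraction), not rectified raw amplitude. The threshold is the 75th
percentile (configurable) of the trailing 30-s buffer including the
current row; a burst is a maximal run of rows strictly above threshold —
strict comparison, so a constant trace never bursts. Reported per row:
mean duration and mean amplitude over bursts *completed* inside the
buffer (a run still open at the current row is ongoing, not completed),
the completed-burst rate per second denominated over the actual buffer
span (not a fixed 30 s during warm-up), and the in-burst indicator.

**Hjorth and line length.** Activity = variance, mobility =
sqrt(var Δx / var x), complexity = mobility(Δx)/mobility(x), with
constant signals guarded to zero. Line length is the mean absolute first
difference.

**Kalman smoothing.** A scalar constant-level (random-walk) Kalman filter
for post-smoothing feature traces; the velocity model was deliberately
not made the default since level tracking is the use case. NaNs pass
through with the state held.

## Across-patient spatial methods

Channel values are interpolated to a user-supplied grid of common-space
points by inverse-distance weighting, x_n = Σ x_m d(n,m)⁻¹ / Σ d(n,m)⁻¹,
over channels within `max_dist_mm` (default 20 mm); a channel exactly at
a grid point returns its value (limit convention) and points with no
channel in range are NaN. The packaged 38-point grid is a synthetic
sensorimotor lattice for tests — real analyses supply their own geometry.

A connectomic decoding network map correlates, voxel by voxel across a
cohort, each channel's connectivity fingerprint with its decoding
performance. Spearman is the default (Pearson via config): it is robust
and makes map fitting and channel selection invariant to monotone
transforms of performance. Fingerprints are generic scalar volumes
sharing shape and affine (NIfTI in/out); producing them from real
normative connectomes is upstream of this package. Channel selection
returns the candidate whose fingerprint correlates best with the map over
jointly valid voxels (ties keep channel order, with a warning).
Leave-one-channel/subject-out validation refits the map without the
held-out unit and reports the rank correlation between predicted
(similarity) and actual performance; a leakage audit asserts the held-out
fingerprint cannot perturb the training-side map.

## Decoding harness

Blocked cross-validation splits rows into k = 3 contiguous, ordered,
near-equal segments without shuffling (shuffling would leak through the
temporal autocorrelation of feature estimates); earlier segments absorb
the remainder. The baseline classifier is L2-regularized logistic
regression with C = 1.0 (an open choice — tests use regimes where it is
immaterial) and class weights inversely proportional to class frequency;
SVM and gradient-boosted trees (XGBoost, 60 trees, depth 3) are
alternatives, with balanced sample weights for the trees. Reports carry
per-fold and pooled metrics, labeled, since fold-averaged and pooled
numbers differ. Balanced accuracy is the mean of per-class recalls; the
movement detection rate counts an epoch (a contiguous positive-label run)
as detected when it contains ≥ `min_consecutive` consecutive correctly
positive predictions (3 rows = 300 ms at the 100-ms interval). A
supplementary false-alarms-per-minute rate counts ≥ min_consecutive
positive-prediction runs entirely outside labeled epochs; it has no
external reference and is reported as-is. Multiclass problems are handled
as pairwise one-vs-rest contrasts.

## RNS bandpass detector and optimizer

The simulated detector flags every row of any contiguous run in which the
(optionally inverted) feature stays strictly above the amplitude
threshold for at least `ceil(min_duration_ms / 1000 ms)` rows. Durations
shorter than one feature row round up to one row rather than erroring —
the programming grid includes 100–900 ms settings at the 1-s feature
cadence and they behave as one row on the device too. The grid search
scores sample-wise F1 (pooled over recordings) over 50 durations
(100–5000 ms in 100-ms steps) × 20 amplitudes equally spaced over the
[min, max] of the pooled unmasked trace (endpoints included; under the
strict crossing the max threshold fires on nothing) × both directions,
with no cross-validation — the embedded programming environment has none,
and the simulation mirrors it (an optional blocked-CV mode exists, off by
default). Ties at the best F1 resolve toward shorter duration, lower
amplitude, non-inverted, and the full tie list is reported. Masked
(artifact) rows are removed from the trace before simulation and scoring,
so inserted artifact segments cannot move the optimum; the amplitude
range is pooled across a patient's recordings. F1 is preferred over
balanced accuracy here because true 'seizure present' calls are the
clinically critical quantity. Sample-wise scoring is primary; a
recording-level verdict (any flagged row) is derivable from the flags.

The extended multivariate panel composes, at 1 Hz on 1000-ms segments
without normalization (across-recording discriminability must survive):
the six RNS band powers, line length, Hjorth parameters, waveform shape
on 5–30 Hz and 5–60 Hz band-passed data, burst features for low-beta,
high-beta and low-gamma, and high-beta/low-gamma coherence between
channel pairs. Spectral aperiodic parametrization is out of scope, so the
panel's column census is defined by this composition (164 columns for 4
channels), not by an external count. Burst bands stay below the 125-Hz
Nyquist of the 250-Hz device rate.

## Synthetic data

The generators are pure functions of their spec (seed included) and
define the study conditions for every calibrated test; the reference
seeds live in `nstream.synthetic.REFERENCE_SEEDS`.

* **Movement sessions** (default 60 s at 1 kHz, four ECoG channels, eight
  2-s movements with ≥ 2-s gaps): per-channel 10/22/70-Hz components with
  independent random phases in unit-variance white noise; during movement
  the 70-Hz component is multiplied by `gamma_gain` (3) and the 22-Hz
  component by `beta_attenuation` (0.5) — the canonical sensorimotor
  gamma-increase/beta-decrease signature. The target channel is the
  binary movement trace. White noise was chosen for simplicity; sessions
  are an order of magnitude shorter than clinical recordings, which is
  why the suite runs at desk scale.
* **Seizure recordings** (250 Hz, four channels, 1/f-weighted baseline
  noise so detector thresholds face realistic drift): each ictal episode
  opens with a high-frequency component (60–120 Hz) at full amplitude
  that persists at half amplitude while a high-amplitude low-frequency
  component (2–8 Hz) follows — the ictal rhythm persisting as slower
  activity emerges; a strictly sequential HF-then-LF construction would
  leave no single band separable over the whole annotated window. A
  nonlinear regime encodes the ictal state as exactly one of HF/LF active
  per second with occasional non-ictal co-activation, which a linear
  readout cannot separate but trees can. Artifact plans plant the exact
  flatline/clipping/stimulation morphologies the artifact rule must
  catch. Labels are per second.
* **Fingerprint cohorts**: fingerprints are `planted_map · w + noise`
  with loadings w ~ U(0.2, 1) and noise sd = map sd / SNR; performance is
  a fixed monotone function of w. The `distinct_best` mode plants one
  channel at w = 1 against distractors ≤ 0.8 for selection experiments.
  Geometry is an 8³ smoothed-noise volume — no claim of anatomical
  realism.

What passing tests show is that the algorithms recover planted structure
under the statistical assumptions above; they do not certify performance
on clinical recordings, where nonstationarity, correlated noise, electrode
artifacts and label noise are all harsher than these generators.

## Numerical choices and limitations

* TSV feature output carries ≥ 17 significant digits; HDF5 is the
  bit-exact reference format for equality testing.
* Column names are string-stable: `<ch>_fft_<band>`,
  `<chA>-<chB>_coh_<band>`, `<ch>_sw_<metric>_<agg>`,
  `<ch>_burst_<band>_<metric>`, `<ch>_hjorth_<param>`,
  `<ch>_linelength`.
* Trailing-window membership tolerances (1 ns) make streaming/offline
  equivalence exact; without them, float rounding of row timestamps
  flips boundary rows.
* The permutation null of the leave-one-out validation is evaluated on a
  20-subject (40-channel) cohort; at 20 exchangeable pairs a null rank
  correlation has sd ≈ 0.23 and |ρ| < 0.3 simply is not a 95 % event, so
  the null is asserted at its calibrated frequency.
* Hardware streaming, BIDS writing, MRI processing/fiber filtering, real
  connectomes, spectral aperiodic decomposition, nonlinear-dynamics
  metrics, contrastive embeddings, and feature-selection/resampling
  wrappers are out of scope.
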