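# nstream

Batch-wise, real-time-compatible feature extraction and decoding for
invasive brain signals (ECoG, sEEG, DBS lead recordings).

Closed-loop neuromodulation — adaptive deep brain stimulation for movement
disorders, responsive neurostimulation (RNS) for epilepsy, future
affective-state decoders — needs brain-state classifiers that run causally,
on short windows, and transfer across patients whose electrodes never sit
in the same place. `nstream` is a library for building and evaluating such
decoders. Everything is computed on causal sliding windows so a model
evaluated offline behaves identically on a live stream:

* **Stream simulation** — an offline recording is replayed as trailing
  batches of `batch_window_ms` advancing by `feature_interval_ms`
  (100 ms for movement decoding, 1 s for seizure detection), parametrized
  by a BIDS-iEEG-style channel table and a JSON settings file.
* **Causal preprocessing** — resampling, common-average or bipolar
  re-referencing, notch filtering, per-feature z-scoring over the trailing
  30 s clipped at ±3, and artifact detection (a run of ≥ 48 ms of
  unchanged voltage derivative marks flatline/clipping segments; each
  stimulation pulse masks the following 2 s).
* **Features** — multiband FFT power on frequency-adapted sub-windows
  (θ 4–8, α 8–12, low β 13–20, high β 20–35, low γ 60–80, high γ 90–200,
  HFA 200–400 Hz for movement; a 250-Hz-compatible set with low γ 35–60
  and broadband 20–120 Hz for RNS), Welch magnitude-squared coherence,
  Hjorth parameters, line length, oscillatory bursts against a trailing
  75th-percentile threshold, Kalman post-smoothing, and trough/peak
  waveform shape:

  prominence  V = (V_peak-left + V_peak-right)/2 − V_trough

  sharpness   V = |((V_trough − V_trough−5ms) + (V_trough − V_trough+5ms))/2|

* **Across-patient spatial methods** — inverse-distance interpolation of
  channel values to a common grid (weights 1/d over channels within
  20 mm), connectomic decoding-network maps (voxel-wise Spearman
  correlation of connectivity fingerprints with decoding performance),
  fingerprint-based channel selection, and leave-one-channel/subject-out
  validation.
* **Decoding harness** — ridge-regularized logistic regression with
  balanced class weights (plus SVM and XGBoost), 3-fold blocked
  cross-validation on consecutive segments (never shuffled), balanced
  accuracy, F1, and a movement detection rate (an epoch counts as detected
  when ≥ 300 ms are decoded consecutively).
* **RNS detector optimizer** — a simulation of the embedded bandpass
  detector (feature, inversion, amplitude threshold, minimum duration) and
  an exhaustive 50 × 20 × 2 grid search maximizing sample-wise F1 against
  expert annotations, without cross-validation, mirroring the device's
  programming environment.
* **Synthetic sessions** — generators for movement sessions
  (gamma gain / beta suppression during movement), annotated seizure
  recordings (high-frequency synchronization followed by low-frequency
  activity, plus flatline/clipping/stimulation artifacts), and
  connectivity-fingerprint cohorts, so the whole pipeline runs and is
  tested without any patient data.

## Worked example

```python
import nstream as ns
from nstream.synthetic import MovementSessionSpec, gen_movement_session, REFERENCE_SEEDS

spec = MovementSessionSpec(seed=REFERENCE_SEEDS["movement_high_snr"])
session = gen_movement_session(spec)                   # 60 s, 8 movements, 4 ECoG ch
settings = ns.Settings(sampling_rate_hz=spec.fs)       # CAR + 7-band FFT + 30-s z-score
frame = ns.Stream(settings, session.table).run(session.data)
X, y = ns.extract_labels(frame, "MOV")
report = ns.evaluate(X, y.astype(int), min_consecutive=3)
print(report.pooled)
```

prints

```
{'balanced_accuracy': 0.9783135150812066, 'f1': 0.9492537313432836, 'detection_rate': 1.0}
```

i.e. 97.8 % balanced accuracy at the single-100-ms-sample level and every
one of the eight movements detected with at least 300 ms of consecutive
correct positive predictions. `examples/` contains one narrative script
per capability (feature extraction, movement decoding, RNS parameter
optimization, connectomic channel selection); each prints its numbers with
a line on what they mean. A thin CLI wraps the same workflows:
`nstream run`, `nstream decode`, `nstream rns-optimize`,
`nstream simulate`.

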