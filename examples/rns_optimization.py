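"""Optimize RNS bandpass-detector parameters on synthetic seizure data.

Generates three annotated 250-Hz recordings (high-frequency ictal
synchronization followed by low-frequency activity), extracts the
device's band features at 1 Hz on 1000-ms segments, and grid-searches
threshold direction x amplitude (20 values over the observed range) x
minimum duration (100-5000 ms) to maximize sample-wise F1 — no
cross-validation, exactly like the embedded programming environment.
"""

import nstream as ns
from nstream.rns_detector import AnnotatedRecording, grid_search
from nstream.synthetic import SeizureRecordingSpec, gen_seizure_recording

table = ns.ChannelTable.from_names([f"ch{i}" for i in range(4)])
settings = ns.Settings(
    sampling_rate_hz=250.0, batch_window_ms=1000.0, feature_interval_ms=1000.0,
    bands=ns.RNS_BANDS, enabled_features=("fft",), preprocessing=(),
    normalize_features=False,
)
recordings = []
for seed in range(3):
    spec = SeizureRecordingSpec(ictal_onset_s=25, ictal_len_s=15, n_episodes=2,
                                interictal_gap_s=25, tail_s=10, seed=seed)
    rec = gen_seizure_recording(spec)
    frame = ns.Stream(settings, table).run(rec.data, fs=250.0)
    recordings.append(
        AnnotatedRecording(features=frame, labels=rec.labels[: len(frame)])
    )

result = grid_search(recordings, "ch0_fft_broadband")
best = result.best_params
print(f"grid: {result.scores.shape[0]} durations x "
      f"{result.scores.shape[1]} amplitudes x 2 directions")
print(f"best F1: {result.best_f1:.3f}  ({len(result.ties)} tied settings)")
print(f"best setting: threshold > {best.amplitude_threshold:.3f} "
      f"(invert={best.invert}) for >= {best.min_duration_ms:.0f} ms")
print(
    "\nAn F1 of 1.0 means the broadband 20-120 Hz feature separates every "
    "annotated ictal second from baseline; the tie list shows the slack the "
    "clinician would have when programming the device."
)
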