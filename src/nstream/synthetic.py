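"""Synthetic recordings with the statistical structure the pipeline assumes.

Movement sessions emulate movement-modulated sensorimotor ECoG (gamma
power rises, beta power falls during movement); seizure recordings
emulate annotated RNS corpora (high-frequency synchronization at onset
followed by high-amplitude low-frequency activity, plus the flatline /
clipping / stimulation artifact morphologies); fingerprint cohorts stand
in for normative connectivity fingerprints. All generators are pure
functions of their spec including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage

from .spatial import ChannelPerformanceRecord, VoxelVolume
from .stream_io import ChannelTable, _normalize_channel_frame

__all__ = [
    "MovementSessionSpec",
    "MovementSession",
    "SeizureRecordingSpec",
    "SeizureRecording",
    "gen_oscillatory_signal",
    "gen_movement_session",
    "gen_seizure_recording",
    "gen_fingerprint_cohort",
    "REFERENCE_SEEDS",
]

#: Fixed seeds naming the acceptance-suite reference conditions.
REFERENCE_SEEDS = {
    "movement_high_snr": 17,
    "movement_null_base": 1000,
    "seizure": 7,
    "fingerprints": 11,
}


def gen_oscillatory_signal(
    components: list[tuple[float, float]],
    fs: float,
    duration_s: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    phases: list[float] | None = None,
) -> np.ndarray:
    """Sum of sinusoids at the given (frequency, amplitude) pairs plus
    white noise; deterministic per seed."""
    nyq = fs / 2.0
    for freq, _ in components:
        if freq >= nyq:
            raise ValueError(f"component at {freq} Hz at or above Nyquist")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * fs))) / fs
    x = np.zeros_like(t)
    for i, (freq, amp) in enumerate(components):
        phase = phases[i] if phases is not None else 0.0
        x += amp * np.sin(2 * np.pi * freq * t + phase)
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, t.size)
    return x


# ---------------------------------------------------------------------------


@dataclass
class MovementSessionSpec:
    """Conditions of a synthetic movement-decoding session.

    Defaults: 60-s session at 1 kHz with four ECoG channels, eight 2-s
    movements, gamma power tripled and beta halved during movement over
    unit-amplitude 10 / 22 / 70 Hz components in unit-variance white
    noise. Movements are spaced with at least 2-s gaps.
    """

    fs: float = 1000.0
    duration_s: float = 60.0
    n_channels: int = 4
    n_movements: int = 8
    movement_len_s: float = 2.0
    gamma_gain: float = 3.0
    beta_attenuation: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma_gain <= 0 or self.beta_attenuation <= 0:
            raise ValueError("gains must be positive")
        lead_in = 5.0
        spacing = (self.duration_s - lead_in - 1.0) / self.n_movements
        if spacing < self.movement_len_s + 2.0:
            raise ValueError("movements do not fit the session with 2-s gaps")

    def epoch_times(self) -> list[tuple[float, float]]:
        lead_in = 5.0
        spacing = (self.duration_s - lead_in - 1.0) / self.n_movements
        return [
            (lead_in + i * spacing, lead_in + i * spacing + self.movement_len_s)
            for i in range(self.n_movements)
        ]


@dataclass
class MovementSession:
    data: np.ndarray  # (n_channels + 1) x samples, last row = target
    fs: float
    table: ChannelTable
    label: np.ndarray  # per-sample 0/1
    epochs: list[tuple[float, float]]
    spec: MovementSessionSpec


ALPHA_HZ, BETA_HZ, GAMMA_HZ = 10.0, 22.0, 70.0


def gen_movement_session(spec: MovementSessionSpec) -> MovementSession:
    """Movement session: per-channel oscillations with movement-locked
    gamma gain and beta attenuation, plus a binary target channel."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    label = np.zeros(n)
    epochs = spec.epoch_times()
    for start, stop in epochs:
        label[int(start * spec.fs) : int(stop * spec.fs)] = 1.0
    gamma_env = 1.0 + (spec.gamma_gain - 1.0) * label
    beta_env = 1.0 + (spec.beta_attenuation - 1.0) * label
    channels = []
    for _ in range(spec.n_channels):
        ph = rng.uniform(0, 2 * np.pi, size=3)
        x = (
            np.sin(2 * np.pi * ALPHA_HZ * t + ph[0])
            + beta_env * np.sin(2 * np.pi * BETA_HZ * t + ph[1])
            + gamma_env * np.sin(2 * np.pi * GAMMA_HZ * t + ph[2])
        )
        x += rng.normal(0.0, spec.noise_sd, n)
        channels.append(x)
    data = np.vstack(channels + [label])
    rows = pd.DataFrame(
        {
            "name": [f"ECOG_{i}" for i in range(spec.n_channels)] + ["MOV"],
            "type": ["ecog"] * spec.n_channels + ["misc"],
            "status": "good",
            "used": 1,
            "target": [0] * spec.n_channels + [1],
            "rereference": ["common_average"] * spec.n_channels + ["none"],
        }
    )
    table = ChannelTable(_normalize_channel_frame(rows))
    return MovementSession(
        data=data, fs=spec.fs, table=table, label=label, epochs=epochs, spec=spec
    )


# ---------------------------------------------------------------------------


@dataclass
class SeizureRecordingSpec:
    """Conditions of a synthetic RNS seizure recording.

    250-Hz four-channel recording; the ictal window opens with
    high-frequency synchronization for its first third, followed by
    high-amplitude low-frequency activity. The baseline is 1/f-weighted
    noise so detector thresholds face realistic drift. ``artifact_plan``
    entries are dicts {kind: flatline|clip|stim, time_s, len_s}. In the
    nonlinear regime the ictal state is encoded as exactly one of the
    HF / LF components being active (with occasional non-ictal
    co-activation), which a linear readout cannot separate.
    """

    fs: float = 250.0
    n_channels: int = 4
    ictal_onset_s: float = 40.0
    ictal_len_s: float = 15.0
    n_episodes: int = 1
    interictal_gap_s: float = 30.0
    tail_s: float = 5.0
    hf_burst_hz: tuple[float, float] = (60.0, 120.0)
    lf_follow_hz: tuple[float, float] = (2.0, 8.0)
    hf_amp: float = 4.0
    lf_amp: float = 8.0
    noise_sd: float = 1.0
    artifact_plan: list[dict] = field(default_factory=list)
    nonlinear_regime: bool = False
    seed: int = 0

    @property
    def duration_s(self) -> float:
        return (
            self.ictal_onset_s
            + self.n_episodes * self.ictal_len_s
            + (self.n_episodes - 1) * self.interictal_gap_s
            + self.tail_s
        )

    def episode_windows(self) -> list[tuple[float, float]]:
        return [
            (
                self.ictal_onset_s + i * (self.ictal_len_s + self.interictal_gap_s),
                self.ictal_onset_s
                + i * (self.ictal_len_s + self.interictal_gap_s)
                + self.ictal_len_s,
            )
            for i in range(self.n_episodes)
        ]


@dataclass
class SeizureRecording:
    data: np.ndarray
    fs: float
    labels: np.ndarray  # per 1-s feature row (end times 1..duration)
    label_times_s: np.ndarray
    ictal_windows_s: list[tuple[float, float]]
    stim_times_s: list[float]
    artifact_truth: list[dict]
    spec: SeizureRecordingSpec


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec /= np.sqrt(np.maximum(freqs, 1.0))
    x = np.fft.irfft(spec, n)
    return x / x.std()


def gen_seizure_recording(spec: SeizureRecordingSpec) -> SeizureRecording:
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    hf = rng.uniform(*spec.hf_burst_hz)
    lf = rng.uniform(*spec.lf_follow_hz)
    windows = spec.episode_windows()
    data = np.vstack(
        [spec.noise_sd * _pink_noise(rng, n, spec.fs) for _ in range(spec.n_channels)]
    )

    def _ictal_at(second_mid: float) -> bool:
        return any(on <= second_mid < off for on, off in windows)

    if spec.nonlinear_regime:
        # per-second band activation: ictal = exactly one of HF/LF active,
        # interictal confound = occasional HF and LF co-activation
        hf_env = np.zeros(n)
        lf_env = np.zeros(n)
        for sec in range(int(spec.duration_s)):
            s0, s1 = int(sec * spec.fs), int((sec + 1) * spec.fs)
            if _ictal_at(sec + 0.5):
                if rng.random() < 0.5:
                    hf_env[s0:s1] = 1.0
                else:
                    lf_env[s0:s1] = 1.0
            elif rng.random() < 0.3:
                hf_env[s0:s1] = 1.0
                lf_env[s0:s1] = 1.0
    else:
        # high-frequency synchronization opens the seizure at full amplitude,
        # persists at half amplitude while low-frequency activity follows
        hf_env = np.zeros(n)
        lf_env = np.zeros(n)
        for on, off in windows:
            first_third = on + spec.ictal_len_s / 3.0
            hf_env += ((t >= on) & (t < first_third)).astype(float)
            hf_env += 0.5 * ((t >= first_third) & (t < off)).astype(float)
            lf_env += ((t >= first_third) & (t < off)).astype(float)
    for c in range(spec.n_channels):
        ph = rng.uniform(0, 2 * np.pi, size=2)
        data[c] += spec.hf_amp * hf_env * np.sin(2 * np.pi * hf * t + ph[0])
        data[c] += spec.lf_amp * lf_env * np.sin(2 * np.pi * lf * t + ph[1])

    stim_times: list[float] = []
    truth: list[dict] = []
    for event in spec.artifact_plan:
        i0 = int(round(event["time_s"] * spec.fs))
        n_ev = int(round(event.get("len_s", 0.048) * spec.fs))
        kind = event["kind"]
        if kind == "flatline":
            data[0, i0 : i0 + n_ev] = data[0, i0]
        elif kind == "clip":
            bound = np.abs(data[0]).max()
            data[0, i0 : i0 + n_ev] = bound
        elif kind == "stim":
            stim_times.append(float(event["time_s"]))
            data[:, i0 : i0 + n_ev] = 0.0
        else:
            raise ValueError(f"unknown artifact kind {kind!r}")
        truth.append({"kind": kind, "start": i0, "stop": i0 + n_ev})

    label_times = np.arange(1.0, spec.duration_s + 0.5, 1.0)
    labels = np.array(
        [int(_ictal_at(t_end - 0.5)) for t_end in label_times], dtype=int
    )
    return SeizureRecording(
        data=data,
        fs=spec.fs,
        labels=labels,
        label_times_s=label_times,
        ictal_windows_s=windows,
        stim_times_s=stim_times,
        artifact_truth=truth,
        spec=spec,
    )


# ---------------------------------------------------------------------------


def gen_fingerprint_cohort(
    n_channels: int = 20,
    volume_shape: tuple[int, int, int] = (8, 8, 8),
    planted_map: np.ndarray | None = None,
    snr: float = 5.0,
    perf_noise_sd: float = 0.0,
    channels_per_subject: int = 2,
    distinct_best: bool = False,
    seed: int = 0,
) -> tuple[list[ChannelPerformanceRecord], dict]:
    """Cohort of channels whose fingerprints load a hidden network map.

    Each fingerprint is ``planted_map * w + noise`` with loading
    ``w ~ U(0.2, 1)`` and noise sd = map sd / snr; performance is a fixed
    monotone function of ``w`` plus optional noise. With ``distinct_best``
    one channel carries the full template (w = 1, its fingerprint is the
    map plus small noise) while distractors stay at w <= 0.8. Returns the
    records and the ground truth (loadings, map, best-channel index).
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    if planted_map is None:
        planted_map = scipy.ndimage.gaussian_filter(
            rng.normal(size=volume_shape), sigma=1.0
        )
        planted_map /= planted_map.std()
    planted_map = np.asarray(planted_map, dtype=float)
    noise_sd = planted_map.std() / snr
    if distinct_best:
        w = rng.uniform(0.2, 0.8, size=n_channels)
        w[rng.integers(n_channels)] = 1.0
    else:
        w = rng.uniform(0.2, 1.0, size=n_channels)
    records = []
    for i in range(n_channels):
        fp = planted_map * w[i] + rng.normal(0.0, noise_sd, planted_map.shape)
        perf = 0.5 + 0.45 * (w[i] - 0.2) / 0.8
        if perf_noise_sd > 0:
            perf += rng.normal(0.0, perf_noise_sd)
        records.append(
            ChannelPerformanceRecord(
                name=f"ch{i:02d}",
                performance=float(np.clip(perf, 0.0, 1.0)),
                fingerprint=VoxelVolume(data=fp),
                subject=f"sub{i // channels_per_subject:02d}",
            )
        )
    truth = {
        "loadings": w,
        "planted_map": planted_map,
        "best_channel": int(np.argmax(w)),
    }
    return records, truth
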