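"""Causal per-batch preprocessing.

Resampling, re-referencing (common average / bipolar), notch filtering,
trailing-window feature normalization, and flatline/clipping/stimulation
artifact detection.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import scipy.signal

from .stream_io import ChannelTable, SignalBatch

__all__ = [
    "NormalizerState",
    "ArtifactMask",
    "resample",
    "rereference",
    "notch_filter",
    "running_normalize",
    "detect_artifacts",
]

#: Minimum unchanged-derivative span flagged as a flatline/clipping artifact.
ARTIFACT_RULE_S = 0.048
#: Post-stimulation mask duration in seconds.
POST_STIM_MASK_S = 2.0


def resample(batch: SignalBatch, target_fs: float) -> SignalBatch:
    """Resample a batch to ``target_fs`` Hz, preserving duration.

    Identity (bit-exact) when ``target_fs == fs``. Polyphase resampling is
    used when the rate ratio is rational with small terms, Fourier
    resampling otherwise.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs == batch.fs:
        return batch
    n_out = int(round(batch.data.shape[1] * target_fs / batch.fs))
    if n_out < 2:
        raise ValueError("target_fs implies fewer than 2 samples per batch")
    frac = Fraction(target_fs / batch.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    if (batch.data.shape[1] * up) % down == 0 and up * down <= 10_000:
        data = scipy.signal.resample_poly(batch.data, up, down, axis=1)
    else:
        data = scipy.signal.resample(batch.data, n_out, axis=1)
    return replace(batch, data=np.ascontiguousarray(data[:, :n_out]), fs=target_fs)


def rereference(batch: SignalBatch, table: ChannelTable) -> SignalBatch:
    """Re-reference batch channels per the channel table.

    Common-average channels subtract the mean over used, good, non-target
    channels; bipolar channels subtract their named partner; target and
    unreferenced channels pass through unchanged. A bipolar partner flagged
    bad is an error.
    """
    names = batch.channel_names
    idx = {n: i for i, n in enumerate(names)}
    car_names = [n for n in table.car_names if n in idx]
    car = (
        batch.data[[idx[n] for n in car_names]].mean(axis=0)
        if car_names
        else np.zeros(batch.data.shape[1])
    )
    out = batch.data.copy()
    rows = table.frame.set_index("name")
    for i, name in enumerate(names):
        row = rows.loc[name]
        scheme = row["rereference"]
        if bool(row["target"]) or scheme == "none":
            continue
        if scheme == "common_average":
            out[i] = batch.data[i] - car
        elif scheme.startswith("bipolar:"):
            partner = scheme.split(":", 1)[1]
            if rows.loc[partner, "status"] == "bad":
                raise ValueError(
                    f"bipolar partner {partner!r} of channel {name!r} is flagged bad"
                )
            out[i] = batch.data[i] - batch.data[idx[partner]]
        else:  # pragma: no cover - schemes validated at table load
            raise ValueError(f"unknown re-reference scheme {scheme!r}")
    return replace(batch, data=out)


def notch_filter(
    batch: SignalBatch, line_noise_hz: float, harmonics: int = 1, q: float = 20.0
) -> SignalBatch:
    """Notch out the line frequency (and ``harmonics`` multiples).

    Zero-phase IIR notch applied within the batch; batches contain only
    past samples, so batch-internal bidirectional filtering remains causal
    at the stream level.
    """
    nyq = batch.fs / 2.0
    if line_noise_hz >= nyq:
        raise ValueError(f"line frequency {line_noise_hz} Hz at or above Nyquist")
    out = batch.data
    for h in range(1, harmonics + 1):
        f0 = line_noise_hz * h
        if f0 >= nyq:
            break
        b, a = scipy.signal.iirnotch(f0, q, fs=batch.fs)
        out = scipy.signal.filtfilt(b, a, out, axis=1)
    return replace(batch, data=np.ascontiguousarray(out))


@dataclass
class NormalizerState:
    """Trailing buffer of past feature rows for streaming z-scoring.

    Holds rows strictly older than the current one, within ``window_s``
    seconds. Population (divide-by-n) standard deviation; the state after
    processing a prefix equals the state from processing it in one pass.
    """

    window_s: float = 30.0
    clip: float = 3.0
    times: deque = field(default_factory=deque)
    rows: deque = field(default_factory=deque)


def running_normalize(
    values: np.ndarray,
    clock_s: float,
    state: NormalizerState,
) -> np.ndarray:
    """Z-score one feature row against the trailing window, clipped.

    ``out = clip((x - mean_past) / sd_past, -clip, +clip)`` with mean/sd
    over rows in the past ``window_s`` seconds (current row excluded).
    Columns with sd = 0, and rows seen before two rows of history exist,
    yield 0 so constant features never poison downstream models. NaNs pass
    through as NaN.
    """
    x = np.asarray(values, dtype=float)
    # boundary row (exactly window_s old) is kept; the epsilon keeps the
    # decision stable against accumulated float error in row timestamps
    while state.times and state.times[0] < clock_s - state.window_s - 1e-9:
        state.times.popleft()
        state.rows.popleft()
    n_past = len(state.rows)
    if n_past < 2:
        out = np.zeros_like(x)
    else:
        past = np.vstack(state.rows)
        mean = np.nanmean(past, axis=0)
        sd = np.nanstd(past, axis=0)  # population convention
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (x - mean) / sd
        out = np.clip(out, -state.clip, state.clip)
        out[(sd == 0) & ~np.isnan(x)] = 0.0
    out[np.isnan(x)] = np.nan
    state.times.append(float(clock_s))
    state.rows.append(x)
    return out


@dataclass
class ArtifactMask:
    """Per-sample artifact mask with an event list.

    ``mask`` is channels x samples; events are dicts with ``kind``
    (``flatline_or_clip`` or ``post_stimulation``), ``channel`` (or None
    for all-channel stimulation masks), ``start_s`` and ``end_s``.
    """

    mask: np.ndarray
    events: list[dict]

    @property
    def any_channel(self) -> np.ndarray:
        """1-D mask: sample masked on any channel."""
        return self.mask.any(axis=0)


def detect_artifacts(
    recording: np.ndarray,
    fs: float,
    stim_times_s: list[float] | None = None,
) -> ArtifactMask:
    """Flag flatline/clipping artifacts and post-stimulation windows.

    A run of at least 48 ms (12 samples at 250 Hz) of unchanged first
    difference — flatlines (zero derivative) and clipping ramps/saturation
    (constant derivative) alike — is masked over its full extent. Each
    stimulation time masks [t, t + 2 s] on all channels. NaN samples never
    form runs, so detection is idempotent on already-masked data.
    """
    data = np.atleast_2d(np.asarray(recording, dtype=float))
    n_ch, n_samp = data.shape
    n_min = max(2, int(round(ARTIFACT_RULE_S * fs)))
    mask = np.zeros((n_ch, n_samp), dtype=bool)
    events: list[dict] = []
    for c in range(n_ch):
        d = np.diff(data[c])
        if d.size == 0:
            continue
        # boundaries where the derivative changes (NaN != NaN breaks runs)
        same = d[1:] == d[:-1]
        run_start = 0
        for j in range(1, d.size + 1):
            if j == d.size or not same[j - 1]:
                run_len_samples = (j - run_start) + 1  # diffs -> samples
                if run_len_samples >= n_min:
                    mask[c, run_start : j + 1] = True
                    events.append(
                        {
                            "kind": "flatline_or_clip",
                            "channel": c,
                            "start_s": run_start / fs,
                            "end_s": j / fs,
                        }
                    )
                run_start = j
    for t in stim_times_s or []:
        i0 = int(round(t * fs))
        i1 = int(round((t + POST_STIM_MASK_S) * fs))
        mask[:, max(i0, 0) : min(i1 + 1, n_samp)] = True
        events.append(
            {
                "kind": "post_stimulation",
                "channel": None,
                "start_s": float(t),
                "end_s": float(t) + POST_STIM_MASK_S,
            }
        )
    return ArtifactMask(mask=mask, events=events)
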