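"""Time-domain features.

Trough/peak waveform-shape metrics (prominence, sharpness, interval, width,
rise/decay times and steepness), oscillatory burst statistics against a
trailing-percentile threshold, Hjorth parameters, and line length.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WaveformEvent",
    "BurstState",
    "detect_troughs_peaks",
    "waveform_shape",
    "burst_features",
    "hjorth",
    "line_length",
    "DEFAULT_AGGREGATES",
]


@dataclass
class WaveformEvent:
    """One trough or peak with its flanking opposite-kind extrema.

    Indices are sample positions inside the analysis window; metric fields
    are filled by :func:`waveform_shape`.
    """

    kind: str  # "trough" | "peak"
    index: int
    amplitude: float
    left_extremum_idx: int
    right_extremum_idx: int
    prominence: float = float("nan")
    sharpness: float = float("nan")
    interval_ms: float = float("nan")
    width_ms: float = float("nan")
    rise_time_ms: float = float("nan")
    decay_time_ms: float = float("nan")
    rise_steepness: float = float("nan")
    decay_steepness: float = float("nan")


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict three-point local minima and maxima."""
    interior = np.arange(1, x.size - 1)
    mins = interior[(x[1:-1] < x[:-2]) & (x[1:-1] < x[2:])]
    maxs = interior[(x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])]
    return mins, maxs


def detect_troughs_peaks(x: np.ndarray) -> list[WaveformEvent]:
    """Detect troughs (strict local minima flanked by the nearest local
    maxima) and peaks (symmetrically), ordered by sample index.

    Events whose flanking extrema fall outside the window are dropped, so
    the first and last extremum of a window never produce an event. A
    monotone signal yields an empty list.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return []
    mins, maxs = _local_extrema(x)
    events: list[WaveformEvent] = []
    for kind, centers, flanks in (("trough", mins, maxs), ("peak", maxs, mins)):
        for i in centers:
            left = flanks[flanks < i]
            right = flanks[flanks > i]
            if left.size == 0 or right.size == 0:
                continue
            events.append(
                WaveformEvent(
                    kind=kind,
                    index=int(i),
                    amplitude=float(x[i]),
                    left_extremum_idx=int(left[-1]),
                    right_extremum_idx=int(right[0]),
                )
            )
    events.sort(key=lambda e: e.index)
    return events


#: Window-aggregation statistic per waveform metric: extremal metrics take
#: the max over events, timing metrics the mean.
DEFAULT_AGGREGATES: dict[str, str] = {
    "prominence": "max",
    "sharpness": "max",
    "interval_ms": "mean",
    "width_ms": "mean",
    "rise_time_ms": "mean",
    "decay_time_ms": "mean",
    "rise_steepness": "mean",
    "decay_steepness": "mean",
}


def waveform_shape(
    events: list[WaveformEvent],
    signal: np.ndarray,
    fs: float,
    aggregates: dict[str, str] | None = None,
) -> dict[str, float]:
    """Per-window waveform-shape features from detected troughs/peaks.

    For a trough at sample i with flanking peaks l < i < r:

    * prominence  = (V[l] + V[r]) / 2 - V[i]   (sign-flipped for peaks)
    * sharpness   = |((V[i] - V[i - 5ms]) + (V[i] - V[i + 5ms])) / 2|
    * interval    = spacing to the previous same-kind event
    * width       = r - l
    * decay/rise  = time into the event from the left extremum / out of the
      event to the right extremum (swapped for peaks: rise in, decay out)
    * steepness   = max |one-sample difference| on the corresponding limb

    The 5-ms sharpness offset is rounded to ``round(0.005 * fs)`` samples;
    events whose offset leaves the window contribute no sharpness. Events
    are aggregated per metric with the statistic in ``aggregates``
    (default: max for prominence/sharpness/steepness-free metrics per
    :data:`DEFAULT_AGGREGATES`). With no events every metric is NaN.
    """
    aggregates = dict(DEFAULT_AGGREGATES, **(aggregates or {}))
    x = np.asarray(signal, dtype=float)
    off = int(round(0.005 * fs))
    prev_same: dict[str, int] = {}
    for ev in events:
        i, l, r = ev.index, ev.left_extremum_idx, ev.right_extremum_idx
        sign = 1.0 if ev.kind == "trough" else -1.0
        ev.prominence = sign * ((x[l] + x[r]) / 2.0 - x[i])
        if off > 0 and i - off >= 0 and i + off < x.size:
            ev.sharpness = abs(((x[i] - x[i - off]) + (x[i] - x[i + off])) / 2.0)
        ev.width_ms = (r - l) / fs * 1000.0
        into_ms = (i - l) / fs * 1000.0
        out_ms = (r - i) / fs * 1000.0
        steep_in = float(np.max(np.abs(np.diff(x[l : i + 1])))) if i > l else 0.0
        steep_out = float(np.max(np.abs(np.diff(x[i : r + 1])))) if r > i else 0.0
        if ev.kind == "trough":
            ev.decay_time_ms, ev.rise_time_ms = into_ms, out_ms
            ev.decay_steepness, ev.rise_steepness = steep_in, steep_out
        else:
            ev.rise_time_ms, ev.decay_time_ms = into_ms, out_ms
            ev.rise_steepness, ev.decay_steepness = steep_in, steep_out
        if ev.kind in prev_same:
            ev.interval_ms = (i - prev_same[ev.kind]) / fs * 1000.0
        prev_same[ev.kind] = i

    out: dict[str, float] = {}
    for metric, agg in aggregates.items():
        vals = np.array(
            [getattr(ev, metric) for ev in events if np.isfinite(getattr(ev, metric))]
        )
        if vals.size == 0:
            out[f"{metric}_{agg}"] = float("nan")
        else:
            out[f"{metric}_{agg}"] = float(vals.max() if agg == "max" else vals.mean())
    return out


@dataclass
class BurstState:
    """Trailing buffer of one band-amplitude trace for burst detection.

    The threshold is the ``percentile``-th percentile of the values in the
    trailing ``window_s`` seconds (current row included); a burst is a
    maximal run of strictly supra-threshold rows. Only causal history is
    ever buffered.
    """

    window_s: float = 30.0
    percentile: float = 75.0
    times: deque = field(default_factory=deque)
    values: deque = field(default_factory=deque)
    flags: deque = field(default_factory=deque)


def burst_features(
    value: float, state: BurstState, clock_s: float
) -> dict[str, float]:
    """Streaming burst statistics at one feature row.

    Returns mean duration (s) and mean amplitude over bursts *completed*
    within the trailing buffer, the completed-burst rate per second
    (denominated over the actual buffer span), and the in-burst indicator
    for the current row. Cold state (< 2 rows) reports zeros.
    """
    state.times.append(float(clock_s))
    state.values.append(float(value))
    # boundary row (exactly window_s old) is evicted; epsilon keeps the
    # decision stable against float error in row timestamps
    while state.times and state.times[0] <= clock_s - state.window_s + 1e-9:
        state.times.popleft()
        state.values.popleft()
        state.flags.popleft()
    vals = np.fromiter(state.values, dtype=float)
    threshold = float(np.percentile(vals, state.percentile))
    in_burst = bool(value > threshold)
    state.flags.append(in_burst)

    if len(state.times) < 2:
        return {
            "duration": 0.0,
            "amplitude": 0.0,
            "rate_per_s": 0.0,
            "in_burst": float(in_burst),
        }

    flags = np.fromiter(state.flags, dtype=bool)
    # completed bursts: supra-threshold runs that ended before the last row
    durations: list[float] = []
    amplitudes: list[float] = []
    times = np.fromiter(state.times, dtype=float)
    dt = times[-1] - times[-2]
    run_start: int | None = None
    for idx in range(flags.size):
        if flags[idx] and run_start is None:
            run_start = idx
        elif not flags[idx] and run_start is not None:
            durations.append((idx - run_start) * dt)
            amplitudes.extend(vals[run_start:idx])
            run_start = None
    # a run still open at the current row is ongoing, not completed
    span = times[-1] - times[0] + dt
    return {
        "duration": float(np.mean(durations)) if durations else 0.0,
        "amplitude": float(np.mean(amplitudes)) if amplitudes else 0.0,
        "rate_per_s": len(durations) / span if span > 0 else 0.0,
        "in_burst": float(in_burst),
    }


def hjorth(x: np.ndarray) -> dict[str, float]:
    """Hjorth activity (variance), mobility and complexity.

    Constant signals report activity 0 with mobility/complexity guarded
    to 0 rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("hjorth needs >= 3 samples")
    activity = float(np.var(x))
    if activity == 0.0:
        return {"activity": 0.0, "mobility": 0.0, "complexity": 0.0}
    d1 = np.diff(x)
    d2 = np.diff(d1)
    var_d1 = float(np.var(d1))
    mobility = float(np.sqrt(var_d1 / activity))
    if var_d1 == 0.0 or mobility == 0.0:
        return {"activity": activity, "mobility": mobility, "complexity": 0.0}
    mobility_d1 = float(np.sqrt(np.var(d2) / var_d1))
    return {
        "activity": activity,
        "mobility": mobility,
        "complexity": mobility_d1 / mobility,
    }


def line_length(x: np.ndarray) -> float:
    """Mean absolute first difference of the window — the classic
    seizure-detection line-length feature (nonnegative, scale-equivariant)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("line_length needs >= 2 samples")
    return float(np.mean(np.abs(np.diff(x))))
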