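"""Batch-wise feature-extraction pipeline.

`Stream` composes the offline batch generator, causal preprocessing and
the feature operators into a time-indexed feature frame. Feeding batches
one at a time through :meth:`Stream.process_batch` is exactly equivalent
to :meth:`Stream.run` on the whole recording — the offline path simulates
the real-time path, never the other way round.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import scipy.signal

from . import preprocess, spectral_features, temporal_features
from .stream_io import ChannelTable, Settings, SignalBatch, offline_stream

__all__ = ["Stream", "extract_labels"]


class Stream:
    """Stateful batch-wise feature extractor.

    Parameters
    ----------
    settings : Settings
        Windowing, preprocessing order, enabled features, normalization.
    channels : ChannelTable
        Channel roles; features come from used non-target channels, the
        target channel passes through as a label column.
    """

    def __init__(self, settings: Settings, channels: ChannelTable) -> None:
        self.settings = settings
        self.channels = channels
        self.reset()

    def reset(self) -> None:
        """Drop all trailing state (normalizer and burst buffers)."""
        s = self.settings
        self._normalizer = preprocess.NormalizerState(
            window_s=s.normalization_window_s, clip=s.normalization_clip
        )
        burst_cfg = s.feature_params.get("bursts", {})
        self._burst_states: dict[tuple[str, str], temporal_features.BurstState] = {}
        self._burst_cfg = {
            "bands": burst_cfg.get("bands")
            or [b.name for b in s.bands[:1]],
            "percentile": burst_cfg.get("percentile", 75.0),
            "window_s": burst_cfg.get("window_s", 30.0),
        }
        self._columns: list[str] | None = None

    # -- per-batch processing -----------------------------------------
    def _preprocess(self, batch: SignalBatch) -> SignalBatch:
        for step in self.settings.preprocessing:
            name = step["name"]
            if name == "resample":
                batch = preprocess.resample(
                    batch, float(step.get("target_fs", 1000.0))
                )
            elif name == "re_reference":
                batch = preprocess.rereference(batch, self.channels)
            elif name == "notch_filter":
                batch = preprocess.notch_filter(
                    batch,
                    float(step.get("line_noise_hz", self.settings.line_noise_hz)),
                    harmonics=int(step.get("harmonics", 1)),
                )
        return batch

    def _burst_state(self, ch: str, band: str) -> temporal_features.BurstState:
        key = (ch, band)
        if key not in self._burst_states:
            self._burst_states[key] = temporal_features.BurstState(
                window_s=self._burst_cfg["window_s"],
                percentile=self._burst_cfg["percentile"],
            )
        return self._burst_states[key]

    def _extract(self, batch: SignalBatch) -> dict[str, float]:
        s = self.settings
        params = s.feature_params
        row: dict[str, float] = {}
        data_names = [n for n in batch.channel_names if n in set(self.channels.data_names)]
        band_by_name = {b.name: b for b in s.bands}
        for ch in data_names:
            x = batch.channel(ch)
            if "fft" in s.enabled_features:
                powers = spectral_features.fft_bandpower(x, batch.fs, s.bands)
                for band, val in powers.items():
                    row[f"{ch}_fft_{band}"] = val
            if "bursts" in s.enabled_features:
                for band_name in self._burst_cfg["bands"]:
                    band = band_by_name[band_name]
                    trace_val = spectral_features.fft_bandpower(
                        x, batch.fs, [band]
                    )[band.name]
                    feats = temporal_features.burst_features(
                        trace_val, self._burst_state(ch, band_name), batch.end_time_s
                    )
                    for metric, val in feats.items():
                        row[f"{ch}_burst_{band_name}_{metric}"] = val
            if "sharpwaves" in s.enabled_features:
                sw = params.get("sharpwaves", {})
                ranges = sw.get("filter_ranges") or [None]
                for rng in ranges:
                    if rng is None:
                        sig, tag = x, ""
                    else:
                        lo, hi = float(rng[0]), float(rng[1])
                        sos = scipy.signal.butter(
                            2, [lo, hi], btype="bandpass", fs=batch.fs, output="sos"
                        )
                        sig = scipy.signal.sosfiltfilt(sos, x)
                        tag = f"{lo:g}to{hi:g}_"
                    events = temporal_features.detect_troughs_peaks(sig)
                    feats = temporal_features.waveform_shape(
                        events, sig, batch.fs, sw.get("aggregates")
                    )
                    for name, val in feats.items():
                        row[f"{ch}_sw_{tag}{name}"] = val
            if "hjorth" in s.enabled_features:
                for name, val in temporal_features.hjorth(x).items():
                    row[f"{ch}_hjorth_{name}"] = val
            if "line_length" in s.enabled_features:
                row[f"{ch}_linelength"] = temporal_features.line_length(x)
        if "coherence" in s.enabled_features:
            coh = params.get("coherence", {})
            pairs = coh.get("pairs") or list(itertools.combinations(data_names, 2))
            bands = [band_by_name[n] for n in coh.get("bands", band_by_name)]
            for a, b in pairs:
                values = spectral_features.coherence(
                    batch.channel(a), batch.channel(b), batch.fs, bands
                )
                for band, val in values.items():
                    row[f"{a}-{b}_coh_{band}"] = val
        return row

    def process_batch(
        self, batch: SignalBatch, masked: bool = False
    ) -> dict[str, float]:
        """Preprocess one batch and return its (normalized) feature row."""
        batch = self._preprocess(batch)
        row = self._extract(batch)
        if self._columns is None:
            self._columns = list(row)
        values = np.array([row[c] for c in self._columns], dtype=float)
        if masked:
            values = np.full_like(values, np.nan)
        if self.settings.normalize_features:
            values = preprocess.running_normalize(
                values, batch.end_time_s, self._normalizer
            )
        out = dict(zip(self._columns, values))
        for name in self.channels.target_names:
            if name in batch.channel_names:
                out[name] = float(batch.channel(name)[-1])
        return out

    # -- whole-recording driver ---------------------------------------
    def run(
        self,
        recording: np.ndarray,
        fs: float | None = None,
        artifact_mask: np.ndarray | None = None,
    ) -> pd.DataFrame:
        """Simulate the stream over an offline recording.

        ``recording`` rows follow the full channel-table order; only used
        rows are streamed. ``artifact_mask`` is an optional per-sample
        boolean (any-channel); a feature row is NaN-masked when its batch
        window overlaps a masked sample. Returns the feature frame indexed
        by batch end time, with target channels appended as label columns.
        """
        fs = fs or self.settings.sampling_rate_hz
        data = np.atleast_2d(np.asarray(recording, dtype=float))
        if data.shape[0] != len(self.channels.frame):
            raise ValueError(
                f"recording has {data.shape[0]} rows but channel table has "
                f"{len(self.channels.frame)}"
            )
        used_idx = list(np.flatnonzero(self.channels.frame["used"].to_numpy()))
        used_names = list(self.channels.frame.loc[used_idx, "name"])
        masked_cum = None
        if artifact_mask is not None:
            masked_cum = np.concatenate(
                [[0], np.cumsum(np.asarray(artifact_mask, bool).astype(int))]
            )
        n_window = int(round(self.settings.batch_window_ms * fs / 1000.0))
        rows: dict[float, dict[str, float]] = {}
        for batch in offline_stream(data[used_idx], fs, self.settings, used_names):
            masked = False
            if masked_cum is not None:
                end = int(round(batch.end_time_s * fs))
                masked = masked_cum[end] - masked_cum[end - n_window] > 0
            rows[batch.end_time_s] = self.process_batch(batch, masked=masked)
        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame.index.name = "end_time_s"
        return frame


def extract_labels(frame: pd.DataFrame, target: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Split a :meth:`Stream.run` frame into features and a label vector."""
    if target not in frame.columns:
        raise KeyError(f"target column {target!r} not in frame")
    labels = frame[target].to_numpy()
    features = frame.drop(
        columns=[c for c in frame.columns if c == target]
    )
    return features, labels
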