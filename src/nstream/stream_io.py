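"""Parametrization files, offline batch streaming and feature I/O.

The channel table mirrors the BIDS iEEG ``channels.tsv`` layout (name,
type, status) with extension columns (used, target, rereference, new_name,
x/y/z coordinates in mm). Settings are a JSON document with defaults
filled and cross-field checks applied on load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import h5py
import numpy as np
import pandas as pd

from .spectral_features import BandDefinition, MOVEMENT_BANDS

__all__ = [
    "ChannelTable",
    "ChannelTableError",
    "DuplicateChannelError",
    "UnknownChannelTypeError",
    "MissingReferenceError",
    "NoDataChannelsError",
    "Settings",
    "SettingsError",
    "SignalBatch",
    "load_channel_table",
    "load_settings",
    "offline_stream",
    "write_features",
    "read_features",
]

CHANNEL_TYPES = {"ecog", "dbs", "seeg", "eeg", "emg", "misc"}

KNOWN_FEATURES = {"fft", "coherence", "sharpwaves", "bursts", "hjorth", "line_length"}
KNOWN_PREPROCESSING = {"resample", "re_reference", "notch_filter"}


class ChannelTableError(ValueError):
    """Invalid channel table."""


class DuplicateChannelError(ChannelTableError):
    pass


class UnknownChannelTypeError(ChannelTableError):
    pass


class MissingReferenceError(ChannelTableError):
    pass


class NoDataChannelsError(ChannelTableError):
    pass


@dataclass
class ChannelTable:
    """Validated per-channel metadata table.

    ``frame`` columns: name, type, status, used, target, rereference,
    new_name, x, y, z (coordinates NaN when unknown).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @classmethod
    def from_names(
        cls,
        names: list[str],
        type: str = "seeg",
        target: str | None = None,
        rereference: str = "none",
    ) -> "ChannelTable":
        """Minimal all-good table: data channels of one type, optionally a
        target channel, all used."""
        rows = pd.DataFrame(
            {
                "name": list(names) + ([target] if target else []),
                "type": [type] * len(names) + (["misc"] if target else []),
                "status": "good",
                "used": 1,
                "target": [0] * len(names) + ([1] if target else []),
                "rereference": [rereference] * len(names)
                + (["none"] if target else []),
            }
        )
        return cls(_normalize_channel_frame(rows))

    # -- derived views -------------------------------------------------
    @property
    def used_names(self) -> list[str]:
        return list(self.frame.loc[self.frame["used"], "name"])

    @property
    def data_names(self) -> list[str]:
        sel = self.frame["used"] & ~self.frame["target"]
        return list(self.frame.loc[sel, "name"])

    @property
    def target_names(self) -> list[str]:
        sel = self.frame["used"] & self.frame["target"]
        return list(self.frame.loc[sel, "name"])

    @property
    def car_names(self) -> list[str]:
        """Channels entering the common average: used, good, non-target."""
        sel = (
            self.frame["used"]
            & ~self.frame["target"]
            & (self.frame["status"] == "good")
        )
        return list(self.frame.loc[sel, "name"])

    def coords(self, names: list[str] | None = None) -> np.ndarray:
        rows = self.frame.set_index("name").loc[names or self.data_names]
        return rows[["x", "y", "z"]].to_numpy(dtype=float)

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        df = self.frame
        dupes = df.loc[df["name"].duplicated(), "name"]
        if len(dupes):
            raise DuplicateChannelError(f"duplicate channel name(s): {list(dupes)}")
        bad_types = df.loc[~df["type"].isin(CHANNEL_TYPES)]
        if len(bad_types):
            row = bad_types.iloc[0]
            raise UnknownChannelTypeError(
                f"channel {row['name']!r}: unknown type {row['type']!r}"
            )
        names = set(df["name"])
        for _, row in df.iterrows():
            ref = row["rereference"]
            if ref.startswith("bipolar:"):
                partner = ref.split(":", 1)[1]
                if partner not in names:
                    raise MissingReferenceError(
                        f"channel {row['name']!r}: bipolar reference to missing "
                        f"channel {partner!r}"
                    )
            elif ref not in {"none", "common_average"}:
                raise ChannelTableError(
                    f"channel {row['name']!r}: unknown rereference {ref!r}"
                )
        if not self.data_names:
            raise NoDataChannelsError("no data channels (used, non-target)")


def _normalize_channel_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    required = {"name", "type", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ChannelTableError(f"channel table missing column(s): {sorted(missing)}")
    df["name"] = df["name"].astype(str)
    df["type"] = df["type"].astype(str).str.lower()
    df["status"] = df["status"].astype(str).str.lower()
    if "target" not in df.columns:
        df["target"] = 0
    df["target"] = df["target"].fillna(0).astype(bool)
    if "used" in df.columns:
        df["used"] = df["used"].fillna(0).astype(bool)
    else:
        # bad channels are retained but unused unless explicitly overridden
        df["used"] = df["status"] == "good"
    if "rereference" not in df.columns:
        df["rereference"] = "none"
    df["rereference"] = df["rereference"].fillna("none").astype(str)
    if "new_name" not in df.columns:
        df["new_name"] = df["name"]
    df["new_name"] = df["new_name"].fillna(df["name"]).astype(str)
    for col in ("x", "y", "z"):
        if col not in df.columns:
            df[col] = np.nan
        df[col] = pd.to_numeric(df[col], errors="coerce")
    cols = ["name", "type", "status", "used", "target", "rereference", "new_name",
            "x", "y", "z"]
    return df[cols].reset_index(drop=True)


def load_channel_table(path: str | Path) -> ChannelTable:
    """Load and validate a channel table from a TSV/CSV file."""
    df = pd.read_csv(path, sep=None, engine="python")
    return ChannelTable(_normalize_channel_frame(df))


# ---------------------------------------------------------------------------


class SettingsError(ValueError):
    """Invalid settings document."""


@dataclass
class Settings:
    """Stream parametrization: windowing, bands, features, preprocessing.

    Defaults follow the movement-decoding configuration: 100-ms feature
    interval, 1000-ms batches, the seven-band movement set, FFT features,
    common-average re-referencing, and 30-s / clip-3 feature normalization.
    """

    sampling_rate_hz: float
    batch_window_ms: float = 1000.0
    feature_interval_ms: float = 100.0
    bands: tuple[BandDefinition, ...] = MOVEMENT_BANDS
    enabled_features: tuple[str, ...] = ("fft",)
    preprocessing: tuple[dict, ...] = ({"name": "re_reference"},)
    normalization_window_s: float = 30.0
    normalization_clip: float = 3.0
    normalize_features: bool = True
    line_noise_hz: float = 50.0
    feature_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def window_samples(self) -> int:
        return int(round(self.batch_window_ms * self.sampling_rate_hz / 1000.0))

    @property
    def hop_samples(self) -> int:
        return int(round(self.feature_interval_ms * self.sampling_rate_hz / 1000.0))

    def validate(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise SettingsError("sampling_rate_hz must be positive")
        if self.batch_window_ms <= 0 or self.feature_interval_ms <= 0:
            raise SettingsError("window and interval must be positive")
        if self.feature_interval_ms > self.batch_window_ms:
            raise SettingsError(
                f"feature_interval_ms {self.feature_interval_ms} exceeds "
                f"batch_window_ms {self.batch_window_ms}"
            )
        if self.normalization_window_s <= 0 or self.normalization_clip <= 0:
            raise SettingsError("normalization window and clip must be positive")
        seen = set()
        for band in self.bands:
            if band.name in seen:
                raise SettingsError(f"duplicate band name {band.name!r}")
            seen.add(band.name)
        for feat in self.enabled_features:
            if feat not in KNOWN_FEATURES:
                raise SettingsError(f"unknown feature {feat!r}")
        if "bursts" in self.enabled_features:
            burst_bands = self.feature_params.get("bursts", {}).get("bands")
            if burst_bands:
                unknown = set(burst_bands) - seen
                if unknown:
                    raise SettingsError(
                        f"burst feature enabled for unknown band(s) {sorted(unknown)}"
                    )
        for step in self.preprocessing:
            if step["name"] not in KNOWN_PREPROCESSING:
                raise SettingsError(f"unknown preprocessing step {step['name']!r}")


def load_settings(path: str | Path) -> Settings:
    """Load settings from JSON, fill defaults and run cross-field checks."""
    with open(path) as fh:
        doc = json.load(fh)
    return settings_from_dict(doc)


def settings_from_dict(doc: dict) -> Settings:
    doc = dict(doc)
    fs = doc.pop("sampling_rate_hz", doc.pop("fs", None))
    if fs is None:
        raise SettingsError("settings must specify sampling_rate_hz (or fs)")
    kwargs: dict = {"sampling_rate_hz": float(fs)}
    for key in ("batch_window_ms", "feature_interval_ms", "line_noise_hz"):
        if key in doc:
            kwargs[key] = float(doc.pop(key))
    if "bands" in doc:
        bands = []
        for b in doc.pop("bands"):
            if isinstance(b, dict):
                bands.append(BandDefinition(b.get("name", f"{b['low']}-{b['high']}"),
                                            float(b["low"]), float(b["high"])))
            else:
                bands.append(BandDefinition(str(b[0]), float(b[1]), float(b[2])))
        kwargs["bands"] = tuple(bands)
    if "enabled_features" in doc:
        kwargs["enabled_features"] = tuple(doc.pop("enabled_features"))
    if "preprocessing" in doc:
        steps = []
        for s in doc.pop("preprocessing"):
            steps.append({"name": s} if isinstance(s, str) else dict(s))
        kwargs["preprocessing"] = tuple(steps)
    norm = doc.pop("normalization", {})
    if "window_s" in norm:
        kwargs["normalization_window_s"] = float(norm["window_s"])
    if "clip" in norm:
        kwargs["normalization_clip"] = float(norm["clip"])
    if "enabled" in norm:
        kwargs["normalize_features"] = bool(norm["enabled"])
    if "feature_params" in doc:
        kwargs["feature_params"] = dict(doc.pop("feature_params"))
    return Settings(**kwargs)


# ---------------------------------------------------------------------------


@dataclass
class SignalBatch:
    """One causal window of multichannel raw signal.

    ``data`` is channels x samples in the channel-table used-row order;
    ``end_time_s`` stamps the last sample relative to recording start.
    """

    data: np.ndarray
    fs: float
    end_time_s: float
    channel_names: list[str]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]


def offline_stream(
    recording: np.ndarray,
    fs: float,
    settings: Settings,
    channel_names: list[str] | None = None,
) -> Iterator[SignalBatch]:
    """Simulate a real-time stream from an offline recording.

    Emits sliding batches of ``batch_window_ms`` trailing data advancing by
    ``feature_interval_ms``; the first batch ends at the first instant a
    full window exists (no zero-padding). Raises if the recording is
    shorter than one window.
    """
    data = np.atleast_2d(np.asarray(recording, dtype=float))
    n_window = int(round(settings.batch_window_ms * fs / 1000.0))
    hop = int(round(settings.feature_interval_ms * fs / 1000.0))
    if data.shape[1] < n_window:
        raise ValueError(
            f"recording of {data.shape[1]} samples shorter than one "
            f"{n_window}-sample window"
        )
    names = channel_names or [f"ch{i}" for i in range(data.shape[0])]
    for end in range(n_window, data.shape[1] + 1, hop):
        yield SignalBatch(
            data=data[:, end - n_window : end].copy(),
            fs=fs,
            end_time_s=end / fs,
            channel_names=list(names),
        )


# ---------------------------------------------------------------------------


def write_features(frame: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    """Write a feature frame (rows indexed by end_time_s) to disk.

    ``tsv`` writes >= 17 significant digits; ``hdf5`` is the bit-exact
    reference format. NaN values (artifact-masked rows) round-trip.
    """
    if frame.empty:
        raise ValueError("refusing to write an empty feature frame")
    path = Path(path)
    if format == "tsv":
        frame.to_csv(path, sep="\t", index_label="end_time_s", float_format="%.17g")
    elif format == "hdf5":
        with h5py.File(path, "w") as fh:
            fh.create_dataset("values", data=frame.to_numpy(dtype=float))
            fh.create_dataset("end_time_s", data=frame.index.to_numpy(dtype=float))
            fh.create_dataset(
                "columns",
                data=np.array([c.encode() for c in frame.columns]),
            )
    else:
        raise ValueError(f"unknown format {format!r}")


def read_features(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Round-trip reader for :func:`write_features` output."""
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix in {".h5", ".hdf5"} else "tsv"
    if format == "tsv":
        return pd.read_csv(path, sep="\t", index_col="end_time_s")
    with h5py.File(path, "r") as fh:
        values = fh["values"][()]
        index = fh["end_time_s"][()]
        columns = [c.decode() for c in fh["columns"][()]]
    return pd.DataFrame(values, index=pd.Index(index, name="end_time_s"),
                        columns=columns)
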