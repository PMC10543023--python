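"""Per-window oscillatory features.

Multiband FFT power with frequency-adapted sub-windows, magnitude-squared
coherence between channel pairs (Welch-averaged), and causal Kalman
post-smoothing of feature traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

__all__ = [
    "BandDefinition",
    "MOVEMENT_BANDS",
    "RNS_BANDS",
    "fft_bandpower",
    "coherence",
    "kalman_smooth",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band, ``low`` < ``high`` in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got [{self.low}, {self.high}]"
            )


#: Canonical band set for cortical movement decoding: theta through
#: high-frequency activity.
MOVEMENT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("low_beta", 13.0, 20.0),
    BandDefinition("high_beta", 20.0, 35.0),
    BandDefinition("low_gamma", 60.0, 80.0),
    BandDefinition("high_gamma", 90.0, 200.0),
    BandDefinition("hfa", 200.0, 400.0),
)

#: Band set matching the embedded RNS bandpass detector conventions
#: (device sampling rate 250 Hz, so everything stays below 125 Hz).
RNS_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("low_beta", 13.0, 20.0),
    BandDefinition("high_beta", 20.0, 35.0),
    BandDefinition("low_gamma", 35.0, 60.0),
    BandDefinition("broadband", 20.0, 120.0),
)


def _band_window_samples(
    low: float, fs: float, n_total: int, min_window_ms: float
) -> int:
    """Trailing sub-window length for one band: max(2 cycles of `low`,
    `min_window_ms`), capped at the full window."""
    n_cycles = int(round(2.0 * fs / low))
    n_min = int(round(min_window_ms * fs / 1000.0))
    return int(min(n_total, max(n_cycles, n_min, 2)))


def fft_bandpower(
    x: np.ndarray,
    fs: float,
    bands: tuple[BandDefinition, ...] | list[BandDefinition],
    *,
    min_window_ms: float = 100.0,
    adapt_windows: bool = True,
) -> dict[str, float]:
    """Total in-band power per band from a Hann-tapered FFT of the window.

    Each band is evaluated on a trailing sub-window of
    ``max(2 cycles of band.low, min_window_ms)`` samples (capped at the
    window), so slow bands integrate over longer history. Power is the sum
    of the one-sided, amplitude-scaled periodogram over bins with
    ``low <= f <= high`` — a pure sinusoid of amplitude A inside a band
    contributes ~A^2/2.

    Raises ``ValueError`` if a band extends above Nyquist.
    """
    x = np.asarray(x, dtype=float)
    nyq = fs / 2.0
    out: dict[str, float] = {}
    # cache per sub-window length
    spectra: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for band in bands:
        if band.high > nyq:
            raise ValueError(
                f"band {band.name!r} high edge {band.high} Hz above Nyquist {nyq} Hz"
            )
        n = (
            _band_window_samples(band.low, fs, x.size, min_window_ms)
            if adapt_windows
            else x.size
        )
        if n not in spectra:
            seg = x[-n:]
            w = scipy.signal.windows.hann(n, sym=False)  # periodic DFT convention
            X = np.fft.rfft(seg * w)
            freqs = np.fft.rfftfreq(n, d=1.0 / fs)
            # one-sided PSD integrated per bin: band sums estimate total
            # in-band power (A^2/2 for an in-band sinusoid of amplitude A)
            denom = n * np.sum(w**2)
            scale = np.full(X.size, 2.0 / denom)
            scale[0] = 1.0 / denom
            if n % 2 == 0:
                scale[-1] = 1.0 / denom
            spectra[n] = (freqs, np.abs(X) ** 2 * scale)
        freqs, power = spectra[n]
        sel = (freqs >= band.low) & (freqs <= band.high)
        out[band.name] = float(power[sel].sum())
    return out


def coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    bands: tuple[BandDefinition, ...] | list[BandDefinition],
    *,
    n_segments: int = 4,
) -> dict[str, float]:
    """Band-averaged magnitude-squared coherence between two channels.

    Welch averaging over ``n_segments`` half-overlapping Hann segments;
    single-segment coherence is identically 1 and is rejected
    (``n_segments`` must be >= 2, windows must support it).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("channel length mismatch")
    if n_segments < 2:
        raise ValueError("coherence needs >= 2 Welch segments")
    nperseg = int(2 * x.size // (n_segments + 1))
    if nperseg < 8:
        raise ValueError(
            f"window of {x.size} samples too short for {n_segments} Welch segments"
        )
    freqs, cxy = scipy.signal.coherence(
        x, y, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    out: dict[str, float] = {}
    for band in bands:
        if band.high > fs / 2.0:
            raise ValueError(f"band {band.name!r} above Nyquist")
        sel = (freqs >= band.low) & (freqs <= band.high)
        out[band.name] = float(np.mean(cxy[sel])) if sel.any() else float("nan")
    return out


def kalman_smooth(
    series: np.ndarray, process_var: float, obs_var: float
) -> np.ndarray:
    """Causal constant-level (random-walk) Kalman filter over a feature trace.

    NaN entries are passed through and the filter state is held. With
    ``obs_var >> process_var`` this heavily smooths stationary noise; the
    steady-state variance reduction follows the closed-form scalar gain.
    """
    if process_var <= 0 or obs_var <= 0:
        raise ValueError("process_var and obs_var must be positive")
    z = np.asarray(series, dtype=float)
    out = np.full_like(z, np.nan)
    x_hat: float | None = None
    p = obs_var
    for i, zi in enumerate(z):
        if np.isnan(zi):
            continue
        if x_hat is None:
            x_hat = float(zi)
            out[i] = x_hat
            continue
        p_pred = p + process_var
        gain = p_pred / (p_pred + obs_var)
        x_hat = x_hat + gain * (float(zi) - x_hat)
        p = (1.0 - gain) * p_pred
        out[i] = x_hat
    return out
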