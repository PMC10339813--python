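"""Epoching, re-referencing and FIR band decomposition of multichannel recordings.

A :class:`Recording` holds a raw channels-by-time matrix at a known sampling
rate.  Analysis proceeds on fixed-length non-overlapping epochs, each
decomposed into the five canonical EEG bands (delta through gamma) with a
zero-phase windowed-sinc FIR filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import firwin, fftconvolve

__all__ = [
    "BANDS",
    "BAND_ORDER",
    "Recording",
    "BandLimitedEpoch",
    "segment_epochs",
    "common_average_reference",
    "bandpass",
    "design_fir",
]

#: Canonical band edges in Hz.  Order is fixed and used everywhere a
#: band-major layout is required (feature tables, particle encodings).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 60.0),
}
BAND_ORDER: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")


@dataclass
class Recording:
    """Multichannel time series: ``samples`` is channels x time, in any
    consistent amplitude unit."""

    samples: np.ndarray
    fs: float
    channel_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a channels x time matrix")
        if self.samples.shape[0] < 2:
            raise ValueError("a recording needs at least 2 channels")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if np.isnan(self.samples).any():
            raise ValueError("samples contain NaN values")
        if self.channel_names is None:
            self.channel_names = [f"ch{i}" for i in range(self.samples.shape[0])]
        elif len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("channel_names length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs


@dataclass
class BandLimitedEpoch:
    """One epoch restricted to a single frequency band."""

    samples: np.ndarray
    band: str
    fs: float
    epoch_id: int = 0
    group_label: str | None = None
    channel_names: Sequence[str] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}; expected one of {list(BANDS)}")
        self.samples = np.asarray(self.samples, dtype=float)


def segment_epochs(rec: Recording, epoch_len: float) -> list[np.ndarray]:
    """Cut a recording into non-overlapping epochs of ``epoch_len`` seconds.

    Returns ``floor(duration / epoch_len)`` arrays of shape
    ``(n_channels, fs * epoch_len)``; the trailing remainder is discarded.
    """
    n_per = int(round(rec.fs * epoch_len))
    if n_per <= 0:
        raise ValueError("epoch_len must be positive")
    if rec.samples.shape[1] < n_per:
        raise ValueError("recording shorter than one epoch")
    n_epochs = rec.samples.shape[1] // n_per
    return [
        rec.samples[:, i * n_per : (i + 1) * n_per].copy() for i in range(n_epochs)
    ]


def common_average_reference(rec: Recording) -> Recording:
    """Subtract the per-sample mean across channels from every channel.

    A plain spatial re-reference: after it, the channel mean is zero at every
    time point.  Idempotent.
    """
    car = rec.samples - rec.samples.mean(axis=0, keepdims=True)
    return Recording(car, rec.fs, list(rec.channel_names))


def design_fir(fs: float, band: str | tuple[float, float]) -> np.ndarray:
    """Windowed-sinc (Hamming) band-pass FIR taps for one canonical band.

    The filter order scales with the lowest passband edge so that the impulse
    response spans about three cycles of the slowest component, with a floor
    of 257 taps; the tap count is forced odd (type-I linear phase).
    """
    lo, hi = BANDS[band] if isinstance(band, str) else band
    if not fs > 2.0 * hi:
        raise ValueError(
            f"sampling rate {fs} Hz too low for band {band!r} (upper edge {hi} Hz)"
        )
    numtaps = max(int(round(3.0 * fs / lo)), 257)
    if numtaps % 2 == 0:
        numtaps += 1
    return firwin(numtaps, [lo, hi], pass_zero=False, window="hamming", fs=fs)


def _zero_phase_filter(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Forward-backward FIR application with reflection padding.

    Filtering twice (second pass time-reversed) squares the magnitude
    response and cancels the phase response.  Reflection padding of one
    filter length on each side suppresses edge transients; output length
    equals input length.  Uses FFT convolution, so cost is near-linear in
    the epoch length even for the long low-band filters.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[-1]
    pad = min(len(taps), n - 1)
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")
    y = fftconvolve(xp, taps[np.newaxis, :], mode="same", axes=-1)
    y = fftconvolve(y[..., ::-1], taps[np.newaxis, :], mode="same", axes=-1)[..., ::-1]
    return y[..., pad : pad + n]


def bandpass(
    epoch_samples: np.ndarray,
    fs: float,
    band: str,
    *,
    epoch_id: int = 0,
    group_label: str | None = None,
    channel_names: Sequence[str] | None = None,
) -> BandLimitedEpoch:
    """Zero-phase FIR band-pass of one epoch into a canonical band.

    Accepts a 1-D series or a channels x time matrix; output has the same
    shape and length as the input.
    """
    x = np.asarray(epoch_samples, dtype=float)
    one_d = x.ndim == 1
    taps = design_fir(fs, band)
    y = _zero_phase_filter(x, taps)
    if one_d:
        y = y[0]
    return BandLimitedEpoch(
        y, band, fs, epoch_id=epoch_id, group_label=group_label,
        channel_names=channel_names,
    )
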