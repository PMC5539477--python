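"""Accelerometer windowing and the four per-minute movement features.

Raw tri-axial acceleration is reduced to its vector magnitude, segmented
into non-overlapping 2-s windows (256 samples at 128 Hz), and four features
are computed per window:

* ``rms``   — sqrt(mean(m^2)) of the raw magnitude m (gravity included), g
* ``sd``    — sample standard deviation of the mean-removed magnitude m~, g
* ``f_dominant`` — frequency of the largest non-DC FFT bin of m~, Hz
* ``energy`` — (1/N) * sum over non-DC bins of \\|X_k\\|^2, g^2; by Parseval
  this equals the time-domain sum of m~^2.

The spectral features and sd remove the window mean (the gravity DC
component) so they respond to movement, not orientation; rms keeps it,
which is the conventional definition and keeps rms and sd linearly
independent (on a mean-removed signal they would be exactly proportional).
The 30 window-level feature vectors of one minute are averaged element-wise
into the minute-level vector aligned with the HRV window of the same
minute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AccelSignal",
    "IMU_NAMES",
    "IMUFeatureSet",
    "magnitude",
    "segment",
    "window_features",
    "minute_average",
    "minute_features",
]

IMU_NAMES: tuple[str, ...] = ("rms", "sd", "f_dominant", "energy")


@dataclass(frozen=True)
class AccelSignal:
    """Tri-axial acceleration in g, sampled uniformly at ``fs`` Hz."""

    samples: np.ndarray  # shape (n, 3)
    fs: float = 128.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("accelerometer samples must have shape (n, 3)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "samples", arr)

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.fs


@dataclass(frozen=True)
class IMUFeatureSet:
    rms: float
    sd: float
    f_dominant: float
    energy: float

    def to_array(self) -> np.ndarray:
        return np.array([self.rms, self.sd, self.f_dominant, self.energy])


def magnitude(signal: AccelSignal) -> np.ndarray:
    """Vector magnitude sqrt(ax^2+ay^2+az^2) of a tri-axial signal."""
    return np.sqrt(np.sum(signal.samples**2, axis=1))


def segment(
    signal: "AccelSignal | np.ndarray", window_s: float = 2.0, fs: float | None = None
) -> list[np.ndarray]:
    """Split into non-overlapping windows; trailing partial window dropped.

    Accepts either an :class:`AccelSignal` (reduced to its magnitude) or an
    already-combined 1-D magnitude array with ``fs`` given.
    """
    if isinstance(signal, AccelSignal):
        x = magnitude(signal)
        fs = signal.fs
    else:
        x = np.asarray(signal, dtype=float)
        if fs is None:
            raise ValueError("fs is required for a bare magnitude array")
    n = int(round(window_s * fs))
    n_win = x.size // n
    if n_win == 0:
        warnings.warn("signal shorter than one window; no windows produced")
        return []
    return [x[k * n:(k + 1) * n] for k in range(n_win)]


def window_features(window: np.ndarray, fs: float = 128.0) -> IMUFeatureSet:
    """The four features of one window of combined-magnitude samples."""
    x = np.asarray(window, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("window must be a 1-D array of at least 2 samples")
    xc = x - x.mean()
    rms = float(np.sqrt(np.mean(x**2)))
    sd = float(np.std(xc, ddof=1))
    spec = np.fft.rfft(xc)
    mag2 = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    if np.max(mag2[1:]) <= 0:
        fdom = 0.0  # silent window: convention
    else:
        fdom = float(freqs[1 + int(np.argmax(mag2[1:]))])
    # one-sided spectrum: double the interior bins to cover negative freqs
    weights = np.ones_like(mag2)
    weights[1:] = 2.0
    if x.size % 2 == 0:
        weights[-1] = 1.0  # Nyquist bin is unique
    energy = float(np.sum(weights[1:] * mag2[1:]) / x.size)
    return IMUFeatureSet(rms=rms, sd=sd, f_dominant=fdom, energy=energy)


def minute_average(
    windows: list[IMUFeatureSet], min_windows: int = 25
) -> IMUFeatureSet | None:
    """Element-wise mean of the window features of one minute.

    Returns ``None`` (flagged-missing minute) when fewer than
    ``min_windows`` windows are available.
    """
    if len(windows) < min_windows:
        return None
    arr = np.mean([w.to_array() for w in windows], axis=0)
    return IMUFeatureSet(*arr)


def minute_features(
    signal: AccelSignal, window_s: float = 2.0, min_windows: int = 25
) -> list[IMUFeatureSet | None]:
    """Per-minute feature vectors for a whole session."""
    per_min = int(round(60.0 / window_s))
    wins = segment(signal, window_s)
    feats = [window_features(w, signal.fs) for w in wins]
    out: list[IMUFeatureSet | None] = []
    for k in range(len(feats) // per_min):
        out.append(minute_average(feats[k * per_min:(k + 1) * per_min],
                                  min_windows))
    return out
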