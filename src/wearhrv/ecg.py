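"""ECG R-peak detection and RR-interval series handling.

The detector is a Pan-Tompkins-style pipeline: band-pass filter (5-30 Hz,
zero-phase Butterworth), differentiate, square, moving-window integration
(150 ms), then an adaptive signal/noise threshold with a 250 ms refractory
period.  Each accepted detection is refined to the local maximum of the
band-passed signal inside the integration window, so on clean signals the
reported peak time is sample-exact.

RR intervals are the successive differences of the detected peak times.
Intervals outside a physiological band (default 300-2000 ms) are treated as
artifacts and dropped (no interpolation); the series records how many were
removed.  One-minute windows are non-overlapping and anchored to the session
start; an interval belongs to the window that contains its *terminating*
peak, and a trailing partial window is discarded.  For a metronomic 1000 ms
rhythm whose first interval terminates at t = 1 s, over 120 s this
convention yields 59 intervals in the first window (the interval ending
exactly at 60 s belongs to the second) and 60 in the second.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "ECGSignal",
    "RRSeries",
    "detect_r_peaks",
    "build_rr",
    "window_rr",
    "RR_BAND_MS",
]

#: Default physiological band for accepted RR intervals (ms).
RR_BAND_MS: tuple[float, float] = (300.0, 2000.0)

#: Minimum separation between two detections (s).
REFRACTORY_S = 0.25


@dataclass(frozen=True)
class ECGSignal:
    """A single-lead ECG trace sampled uniformly at ``fs`` Hz."""

    samples: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("ECG samples must be one-dimensional")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class RRSeries:
    """An artifact-filtered RR-interval series.

    ``times`` holds the absolute time (s) of the terminating R peak of each
    interval; ``rr_ms`` the interval lengths in ms.  ``n_dropped`` counts
    intervals removed by the physiological-band filter.
    """

    times: np.ndarray
    rr_ms: np.ndarray
    n_dropped: int = 0
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        rr = np.asarray(self.rr_ms, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "rr_ms", rr)
        if t.shape != rr.shape:
            raise ValueError("times and rr_ms must have equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("interval times must be strictly increasing")
        if np.any(rr <= 0):
            raise ValueError("RR intervals must be positive")

    def __len__(self) -> int:
        return self.rr_ms.size

    @classmethod
    def from_peak_times(
        cls,
        peak_times: np.ndarray,
        band_ms: tuple[float, float] | None = RR_BAND_MS,
    ) -> "RRSeries":
        return build_rr(peak_times, band_ms=band_ms)

    @classmethod
    def from_intervals(
        cls, rr_ms: np.ndarray, t0: float = 0.0
    ) -> "RRSeries":
        """Build a series from a bare interval list.

        R times are taken as the cumulative sums of the intervals, i.e. the
        first beat falls one interval after ``t0``.
        """
        rr = np.asarray(rr_ms, dtype=float)
        times = t0 + np.cumsum(rr) / 1000.0
        return cls(times=times, rr_ms=rr)


def _bandpass(x: np.ndarray, fs: float, lo: float = 5.0, hi: float = 30.0) -> np.ndarray:
    nyq = fs / 2.0
    hi = min(hi, 0.95 * nyq)
    sos = sps.butter(3, [lo / nyq, hi / nyq], btype="band", output="sos")
    return sps.sosfiltfilt(sos, x)


def detect_r_peaks(ecg: ECGSignal) -> np.ndarray:
    """Detect R-peak times (s) in a single-lead ECG.

    Returns a strictly increasing array of peak times honouring a 250 ms
    refractory period.  A zero-variance signal yields an empty array; a
    signal shorter than 2 s is an error.
    """
    x = ecg.samples
    fs = ecg.fs
    if x.size < 2 * fs:
        raise ValueError("ECG shorter than 2 s; cannot detect R peaks")
    if np.ptp(x) == 0:
        return np.empty(0)

    filtered = _bandpass(x, fs)
    deriv = np.gradient(filtered) * fs
    squared = deriv**2
    win = max(1, int(round(0.150 * fs)))
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")

    refr = int(round(REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(integrated, distance=refr)
    if cand.size == 0:
        return np.empty(0)

    # Adaptive signal/noise levels (Pan-Tompkins running estimates).
    lead = integrated[: int(2 * fs)]
    spki = float(np.max(lead))
    npki = float(np.mean(lead))
    accepted: list[int] = []
    for idx in cand:
        level = integrated[idx]
        thresh = npki + 0.25 * (spki - npki)
        if level >= thresh:
            spki = 0.125 * level + 0.875 * spki
            accepted.append(idx)
        else:
            npki = 0.125 * level + 0.875 * npki
    if not accepted:
        return np.empty(0)

    # Refine each detection to the local max of the band-passed signal.
    half = win
    peaks: list[int] = []
    for idx in accepted:
        lo = max(0, idx - half)
        hi = min(x.size, idx + half + 1)
        peaks.append(lo + int(np.argmax(filtered[lo:hi])))
    peaks_arr = np.unique(peaks)

    # Enforce the refractory period after refinement.
    kept: list[int] = []
    for p in peaks_arr:
        if not kept or p - kept[-1] >= refr:
            kept.append(p)
        elif filtered[p] > filtered[kept[-1]]:
            kept[-1] = p
    return ecg.start_time + np.asarray(kept, dtype=float) / fs


def build_rr(
    peak_times: np.ndarray,
    band_ms: tuple[float, float] | None = RR_BAND_MS,
) -> RRSeries:
    """Convert R-peak times to an artifact-filtered :class:`RRSeries`."""
    t = np.asarray(peak_times, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two R peaks to form an RR interval")
    if not np.all(np.diff(t) > 0):
        raise ValueError("peak times must be strictly increasing")
    rr = np.diff(t) * 1000.0
    term = t[1:]
    if band_ms is None:
        keep = np.ones(rr.size, dtype=bool)
    else:
        keep = (rr >= band_ms[0]) & (rr <= band_ms[1])
    return RRSeries(times=term[keep], rr_ms=rr[keep], n_dropped=int((~keep).sum()))


def window_rr(
    rr: RRSeries,
    window_s: float = 60.0,
    t0: float = 0.0,
    span_s: float | None = None,
) -> list[RRSeries]:
    """Split a series into non-overlapping windows anchored at ``t0``.

    ``span_s`` optionally fixes the covered span (e.g. the known session
    length); by default the span runs to the last interval time.  The
    trailing partial window is discarded.  Returns an empty list (with a
    warning) when the span is shorter than one window.
    """
    if window_s <= 0:
        raise ValueError("window length must be positive")
    span = (rr.times[-1] - t0) if span_s is None else span_s
    n_win = int(span // window_s)
    if n_win < 1:
        warnings.warn("RR span shorter than one window; no windows produced")
        return []
    out: list[RRSeries] = []
    for k in range(n_win):
        lo = t0 + k * window_s
        hi = lo + window_s
        mask = (rr.times >= lo) & (rr.times < hi)
        out.append(
            RRSeries(
                times=rr.times[mask],
                rr_ms=rr.rr_ms[mask],
                meta={"window_index": k, "t_start": lo, "t_end": hi},
            )
        )
    return out
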