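"""Heart-rate-variability parameters for one-minute RR windows.

Thirty-one parameters are computed per window, in three families:

* time domain — mRR, SDRR, mHR, SDHR, RMSSD, NN50, pNN50;
* frequency domain — band peak frequencies (VLF, LF, HF), absolute band
  powers (pVLF, pLF, pHF), relative powers (prcVLF, prcLF, prcHF),
  normalized powers (nLF, nHF) and the LF/HF ratio, from a Welch spectrum
  of the cubic-spline-resampled (4 Hz) RR tachogram;
* nonlinear — Poincaré SD1/SD2, approximate and sample entropy, correlation
  dimension D2, DFA scaling exponents Alpha1/Alpha2, and recurrence-plot
  statistics Lmean, Lmax, REC, DET, ShanEn.

Conventions (fixed here because the parameter definitions alone do not pin
them down):

* sample standard deviations (``ddof=1``) throughout;
* pNN50 divides NN50 by the number of RR intervals in the window;
* relative powers use the band-limited total pVLF+pLF+pHF as denominator
  (the full-spectrum denominator is selectable via ``HRVParams``);
* spectral bands: VLF (0, 0.04], LF (0.04, 0.15], HF (0.15, 0.4] Hz;
* entropies use m=2, r=0.2*SDRR with Chebyshev distance; ApEn includes
  self-matches, SampEn excludes them;
* DFA box sizes 4-16 (Alpha1) and 17-64 (Alpha2), restricted to sizes that
  fit at least twice into the series;
* RQA and D2 use embedding dimension 10 at delay 1 with Euclidean distance;
  the RQA radius is sqrt(m)*SDRR and diagonal statistics use lmin=2,
  excluding the line of identity;
* degenerate windows (zero variance, no spectral power, no recurrences) take
  documented convention values and are flagged, never silently zeroed.

SD1 relates to RMSSD exactly by ``SD1^2 = M/(M-1) * (RMSSD^2 - dbar^2) / 2``
where ``M`` is the number of successive differences and ``dbar`` their mean;
when the mean difference vanishes this is the familiar proportionality
between short-term Poincaré width and RMSSD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from scipy.interpolate import CubicSpline
from scipy.spatial.distance import cdist, pdist

from .ecg import RRSeries

__all__ = [
    "HRV_NAMES",
    "HRVParams",
    "HRVFeatureSet",
    "time_domain",
    "frequency_domain",
    "poincare",
    "entropy",
    "dfa",
    "correlation_dimension",
    "rqa",
    "compute_all",
]

#: Canonical order of the 31 parameters.
HRV_NAMES: tuple[str, ...] = (
    "mRR", "SDRR", "mHR", "SDHR", "RMSSD", "NN50", "pNN50",
    "VLF", "LF", "HF", "pVLF", "pLF", "pHF",
    "prcVLF", "prcLF", "prcHF", "nLF", "nHF", "LF_HF",
    "SD1", "SD2", "ApEn", "SampEn", "D2", "Alpha1", "Alpha2",
    "Lmean", "Lmax", "REC", "DET", "ShanEn",
)

BANDS: dict[str, tuple[float, float]] = {
    "VLF": (0.0, 0.04),
    "LF": (0.04, 0.15),
    "HF": (0.15, 0.4),
}


@dataclass(frozen=True)
class HRVParams:
    """Tunable constants of the HRV computation."""

    resample_fs: float = 4.0        # tachogram resampling rate, Hz
    welch_nperseg_s: float = 32.0   # Welch segment length, s
    welch_overlap: float = 0.5      # fractional segment overlap
    band_limited_total: bool = True  # prc* denominator = pVLF+pLF+pHF
    entropy_m: int = 2
    entropy_r_frac: float = 0.2     # r = frac * SDRR
    dfa_short: tuple[int, int] = (4, 16)
    dfa_long: tuple[int, int] = (17, 64)
    d2_m: int = 10
    rqa_m: int = 10
    rqa_delay: int = 1
    rqa_lmin: int = 2
    rqa_r_scale: float = 1.0        # radius = scale * sqrt(m) * SDRR


@dataclass
class HRVFeatureSet:
    """The 31 named HRV values for one window, with missing/convention flags."""

    values: dict[str, float]
    flags: dict[str, str] = field(default_factory=dict)
    window_index: int | None = None

    def __post_init__(self) -> None:
        missing = [n for n in HRV_NAMES if n not in self.values]
        if missing:
            raise ValueError(f"feature set incomplete, missing {missing}")

    def to_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in HRV_NAMES], dtype=float)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __len__(self) -> int:
        return len(HRV_NAMES)


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


# ---------------------------------------------------------------- time domain

def time_domain(rr: RRSeries) -> dict[str, float]:
    """mRR, SDRR, mHR, SDHR (sample SDs), RMSSD, NN50 and pNN50."""
    x = rr.rr_ms
    if x.size < 2:
        raise ValueError("time_domain needs at least 2 RR intervals (mRR/SDRR)")
    if x.size < 3:
        raise ValueError("time_domain needs at least 3 RR intervals for RMSSD/NN50")
    hr = 60000.0 / x
    d = np.diff(x)
    nn50 = int(np.sum(np.abs(d) > 50.0))
    return {
        "mRR": float(np.mean(x)),
        "SDRR": _sd(x),
        "mHR": float(np.mean(hr)),
        "SDHR": _sd(hr),
        "RMSSD": float(np.sqrt(np.mean(d**2))),
        "NN50": float(nn50),
        "pNN50": 100.0 * nn50 / x.size,
    }


# ----------------------------------------------------------- frequency domain

def _tachogram_psd(rr: RRSeries, params: HRVParams) -> tuple[np.ndarray, np.ndarray]:
    fs = params.resample_fs
    t = rr.times
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    tach = CubicSpline(t, rr.rr_ms)(grid)
    tach = tach - tach.mean()
    nper = min(int(round(params.welch_nperseg_s * fs)), tach.size)
    nover = int(nper * params.welch_overlap)
    freqs, psd = sps.welch(
        tach, fs=fs, window="hann", nperseg=nper, noverlap=nover,
        detrend="constant",
    )
    return freqs, psd


def frequency_domain(
    rr: RRSeries, params: HRVParams | None = None
) -> tuple[dict[str, float], dict[str, str]]:
    """Band peaks, powers, relative/normalized powers and LF/HF ratio.

    Returns ``(values, flags)``; ratio quantities fall back to flagged zeros
    when the relevant power vanishes.
    """
    params = params or HRVParams()
    if len(rr) < 30:
        raise ValueError("frequency_domain needs at least 30 intervals")
    freqs, psd = _tachogram_psd(rr, params)

    vals: dict[str, float] = {}
    flags: dict[str, str] = {}
    powers: dict[str, float] = {}
    span = rr.times[-1] - rr.times[0]
    for name, (lo, hi) in BANDS.items():
        mask = (freqs > lo) & (freqs <= hi)
        if not mask.any() or psd[mask].max() <= 0:
            vals[name] = 0.0
            powers[name] = 0.0
            flags[name] = "no-power"
            continue
        vals[name] = float(freqs[mask][np.argmax(psd[mask])])
        # trapezoid over the band, with PSD interpolated at the band edges
        # so single-bin bands still integrate to a finite power
        fgrid = np.concatenate(([max(lo, freqs[0])], freqs[mask], [min(hi, freqs[-1])]))
        pgrid = np.interp(fgrid, freqs, psd)
        powers[name] = float(np.trapezoid(pgrid, fgrid))
    # a one-minute window holds ~2 VLF periods at most: estimable, not trustworthy
    if span < 120.0:
        for key in ("VLF", "pVLF", "prcVLF"):
            flags.setdefault(key, "unreliable-window")
    vals["pVLF"], vals["pLF"], vals["pHF"] = (
        powers["VLF"], powers["LF"], powers["HF"],
    )

    if params.band_limited_total:
        total = powers["VLF"] + powers["LF"] + powers["HF"]
    else:
        total = float(np.trapezoid(psd, freqs))
    for name in BANDS:
        key = f"prc{name}"
        if total > 0:
            vals[key] = 100.0 * powers[name] / total
        else:
            vals[key] = 0.0
            flags[key] = "zero-total-power"

    lfhf = powers["LF"] + powers["HF"]
    if lfhf > 0:
        vals["nLF"] = powers["LF"] / lfhf
        vals["nHF"] = powers["HF"] / lfhf
    else:
        vals["nLF"] = vals["nHF"] = 0.0
        flags["nLF"] = flags["nHF"] = "zero-total-power"
    if powers["HF"] > 0:
        vals["LF_HF"] = powers["LF"] / powers["HF"]
    else:
        vals["LF_HF"] = 0.0
        flags["LF_HF"] = "zero-hf-power"
    return vals, flags


# ------------------------------------------------------------------ nonlinear

def poincare(rr: RRSeries) -> dict[str, float]:
    """Poincaré SD1 (short-term) and SD2 (long-term), in ms."""
    x = rr.rr_ms
    if x.size < 3:
        raise ValueError("poincare needs at least 3 RR intervals")
    d = (x[1:] - x[:-1]) / math.sqrt(2.0)
    s = (x[1:] + x[:-1]) / math.sqrt(2.0)
    return {"SD1": _sd(d), "SD2": _sd(s)}


def _embed(x: np.ndarray, m: int, delay: int = 1) -> np.ndarray:
    n = x.size - (m - 1) * delay
    if n < 1:
        raise ValueError("series too short for embedding")
    return sliding_window_view(x, (m - 1) * delay + 1)[:, ::delay][:n]


def entropy(
    rr: RRSeries, m: int = 2, r: float | None = None
) -> tuple[dict[str, float], dict[str, str]]:
    """Approximate and sample entropy (Chebyshev distance).

    ``r`` defaults to 0.2*SDRR.  A constant window returns flagged zeros; a
    window with no length-(m+1) matches returns a flagged ceiling value
    ``-ln(2 / ((N-m-1)(N-m)))`` for SampEn.
    """
    x = rr.rr_ms
    n = x.size
    if n < m + 2:
        raise ValueError(f"entropy needs at least {m + 2} intervals")
    sdrr = _sd(x)
    if r is None:
        r = 0.2 * sdrr
    if sdrr == 0 or r <= 0:
        return {"ApEn": 0.0, "SampEn": 0.0}, {
            "ApEn": "constant-series", "SampEn": "constant-series"
        }

    def _phi(mm: int) -> float:
        emb = _embed(x, mm)
        dist = cdist(emb, emb, metric="chebyshev")
        counts = np.sum(dist <= r, axis=1)  # self-matches included
        return float(np.mean(np.log(counts / emb.shape[0])))

    apen = _phi(m) - _phi(m + 1)

    def _pairs(mm: int) -> int:
        emb = _embed(x, mm)[: n - m]  # N-m templates for both m and m+1
        return int(np.sum(pdist(emb, metric="chebyshev") <= r))

    b = _pairs(m)
    a = _pairs(m + 1)
    flags: dict[str, str] = {}
    if b == 0 or a == 0:
        sampen = -math.log(2.0 / ((n - m - 1) * (n - m)))
        flags["SampEn"] = "no-matches"
    else:
        sampen = -math.log(a / b)
    return {"ApEn": apen, "SampEn": sampen}, flags


def dfa(
    rr: RRSeries,
    short: tuple[int, int] = (4, 16),
    long: tuple[int, int] = (17, 64),
) -> tuple[dict[str, float], dict[str, str]]:
    """Detrended fluctuation analysis scaling exponents Alpha1 and Alpha2.

    Box sizes are restricted to those fitting at least twice into the
    series; a band with fewer than three usable sizes is flagged missing
    (NaN).  Alpha2's nominal box range (17-64) wants >= 70 intervals; on
    shorter series the exponent is still estimated from the usable sizes
    but flagged ``short-window``.  A zero-fluctuation (constant) series is
    an error.
    """
    x = rr.rr_ms
    if x.size < 20:
        raise ValueError("dfa needs at least 20 intervals for Alpha1")
    if np.ptp(x) == 0:
        raise ValueError("dfa undefined for a zero-fluctuation series")
    y = np.cumsum(x - np.mean(x))
    n_tot = y.size

    def _fluct(n: int) -> float:
        k = n_tot // n
        seg = y[: k * n].reshape(k, n)
        t = np.arange(n, dtype=float)
        # per-box linear detrend
        tm = t - t.mean()
        slope = seg @ tm / np.sum(tm**2)
        resid = seg - seg.mean(axis=1, keepdims=True) - np.outer(slope, tm)
        return float(np.sqrt(np.mean(resid**2)))

    def _alpha(lo: int, hi: int) -> float | None:
        sizes = [n for n in range(lo, hi + 1) if n_tot >= 2 * n]
        if len(sizes) < 3:
            return None
        f = np.array([_fluct(n) for n in sizes])
        if np.any(f <= 0):
            return None
        return float(np.polyfit(np.log10(sizes), np.log10(f), 1)[0])

    vals: dict[str, float] = {}
    flags: dict[str, str] = {}
    a1 = _alpha(*short)
    a2 = _alpha(*long)
    vals["Alpha1"] = a1 if a1 is not None else float("nan")
    if a1 is None:
        flags["Alpha1"] = "too-short"
    vals["Alpha2"] = a2 if a2 is not None else float("nan")
    if a2 is None:
        flags["Alpha2"] = "too-short"
    elif n_tot < 70:
        flags["Alpha2"] = "short-window"
    return vals, flags


def correlation_sums(
    x: np.ndarray, radii: np.ndarray, m: int, delay: int = 1
) -> np.ndarray:
    """Grassberger-Procaccia correlation sums C(r) in delay embedding."""
    emb = _embed(np.asarray(x, dtype=float), m, delay)
    npts = emb.shape[0]
    d = pdist(emb)
    return np.array([2.0 * np.sum(d < r) / (npts * (npts - 1)) for r in radii])


def correlation_dimension(
    rr: RRSeries, m: int = 10, delay: int = 1, n_radii: int = 20
) -> tuple[float, str | None]:
    """Correlation dimension D2 (Grassberger-Procaccia).

    The radius grid is log-spaced between the 5th and 95th percentile of
    pairwise embedded distances and the slope is fit over the central half
    of the grid.  Degenerate (constant) series return a flagged 0.
    """
    x = rr.rr_ms
    if x.size < m + 10:
        raise ValueError(f"correlation_dimension needs at least {m + 10} intervals")
    emb = _embed(x, m, delay)
    d = pdist(emb)
    d = d[d > 0]
    if d.size == 0:
        return 0.0, "degenerate"
    r_lo, r_hi = np.percentile(d, [5.0, 95.0])
    if r_lo <= 0 or r_hi <= r_lo:
        return 0.0, "degenerate"
    radii = np.geomspace(r_lo, r_hi, n_radii)
    c = correlation_sums(x, radii, m, delay)
    lo, hi = n_radii // 4, n_radii - n_radii // 4
    sel = slice(lo, hi)
    cc, rr_sel = c[sel], radii[sel]
    ok = cc > 0
    if ok.sum() < 2:
        return 0.0, "degenerate"
    slope = float(np.polyfit(np.log(rr_sel[ok]), np.log(cc[ok]), 1)[0])
    return slope, None


def _diagonal_lengths(rec: np.ndarray) -> list[int]:
    """Maximal diagonal run lengths of a boolean recurrence matrix,
    excluding the line of identity, both triangles."""
    npts = rec.shape[0]
    lengths: list[int] = []
    for k in range(1, npts):
        for diag in (np.diagonal(rec, k), np.diagonal(rec, -k)):
            run = 0
            for v in diag:
                if v:
                    run += 1
                elif run:
                    lengths.append(run)
                    run = 0
            if run:
                lengths.append(run)
    return lengths


def rqa(
    rr: RRSeries,
    m: int = 10,
    delay: int = 1,
    r: float | None = None,
    lmin: int = 2,
) -> tuple[dict[str, float], dict[str, str]]:
    """Recurrence quantification: Lmean, Lmax, REC, DET, ShanEn.

    The recurrence matrix uses Euclidean distance in delay embedding with
    radius ``r`` (default sqrt(m)*SDRR).  REC is the percentage of recurrent
    points among the M(M-1) off-diagonal pairs; diagonal statistics exclude
    the line of identity and count lines of length >= lmin; ShanEn is the
    natural-log Shannon entropy of the line-length distribution.
    """
    x = rr.rr_ms
    if x.size < m + lmin:
        raise ValueError(f"rqa needs at least {m + lmin} intervals")
    if r is None:
        r = math.sqrt(m) * _sd(x)
    emb = _embed(x, m, delay)
    npts = emb.shape[0]
    dist = cdist(emb, emb)
    rec = dist <= r
    np.fill_diagonal(rec, False)
    n_rec = int(rec.sum())
    total = npts * (npts - 1)
    vals = {"Lmean": 0.0, "Lmax": 0.0, "REC": 0.0, "DET": 0.0, "ShanEn": 0.0}
    flags: dict[str, str] = {}
    vals["REC"] = 100.0 * n_rec / total
    if n_rec == 0:
        for k in ("Lmean", "Lmax", "DET", "ShanEn"):
            flags[k] = "no-recurrences"
        flags["REC"] = "no-recurrences"
        return vals, flags
    lengths = np.array(_diagonal_lengths(rec))
    lines = lengths[lengths >= lmin]
    if lines.size == 0:
        for k in ("Lmean", "Lmax", "DET", "ShanEn"):
            flags[k] = "no-diagonals"
        return vals, flags
    vals["Lmean"] = float(lines.mean())
    vals["Lmax"] = float(lines.max())
    vals["DET"] = 100.0 * float(lines.sum()) / n_rec
    _, counts = np.unique(lines, return_counts=True)
    p = counts / counts.sum()
    vals["ShanEn"] = float(-np.sum(p * np.log(p)))
    return vals, flags


# ----------------------------------------------------------------- aggregator

def compute_all(
    rr: RRSeries, params: HRVParams | None = None
) -> HRVFeatureSet:
    """All 31 parameters for one window, in the canonical order.

    Sub-computations whose preconditions a short or degenerate window cannot
    satisfy yield their documented convention value (or NaN) with a flag.
    """
    params = params or HRVParams()
    if len(rr) == 0:
        raise ValueError("cannot compute HRV features on an empty window")
    vals: dict[str, float] = {}
    flags: dict[str, str] = {}

    def _guard(names: tuple[str, ...], fn, fallback: float = float("nan")):
        try:
            out = fn()
        except ValueError as exc:
            for n in names:
                vals[n] = fallback
                flags[n] = f"unavailable: {exc}"
            return
        if isinstance(out, tuple):
            v, f = out
            vals.update(v)
            flags.update(f)
        else:
            vals.update(out)

    _guard(("mRR", "SDRR", "mHR", "SDHR", "RMSSD", "NN50", "pNN50"),
           lambda: time_domain(rr))
    _guard(("VLF", "LF", "HF", "pVLF", "pLF", "pHF",
            "prcVLF", "prcLF", "prcHF", "nLF", "nHF", "LF_HF"),
           lambda: frequency_domain(rr, params))
    _guard(("SD1", "SD2"), lambda: poincare(rr))
    _guard(("ApEn", "SampEn"),
           lambda: entropy(rr, m=params.entropy_m,
                           r=params.entropy_r_frac * _sd(rr.rr_ms)
                           if _sd(rr.rr_ms) > 0 else None))

    try:
        d2, d2_flag = correlation_dimension(rr, m=params.d2_m)
        vals["D2"] = d2
        if d2_flag:
            flags["D2"] = d2_flag
    except ValueError as exc:
        vals["D2"] = float("nan")
        flags["D2"] = f"unavailable: {exc}"

    try:
        dvals, dflags = dfa(rr, short=params.dfa_short, long=params.dfa_long)
        vals.update(dvals)
        flags.update(dflags)
    except ValueError as exc:
        vals["Alpha1"] = vals["Alpha2"] = 0.0
        flags["Alpha1"] = flags["Alpha2"] = f"convention-zero: {exc}"

    _guard(("Lmean", "Lmax", "REC", "DET", "ShanEn"),
           lambda: rqa(rr, m=params.rqa_m, delay=params.rqa_delay,
                       r=(params.rqa_r_scale * math.sqrt(params.rqa_m)
                          * _sd(rr.rr_ms)) if _sd(rr.rr_ms) > 0 else 1e-12,
                       lmin=params.rqa_lmin))

    widx = rr.meta.get("window_index") if rr.meta else None
    return HRVFeatureSet(values={n: vals[n] for n in HRV_NAMES},
                         flags=flags, window_index=widx)
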