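"""Per-pulse fiducial point detection and detector comparison.

Five characteristic points are sought on each pulse: the max slope point
(MSP) on the systolic upstroke, the systolic peak (SP), the dicrotic notch
(DN), the inflection point (IP) and the diastolic peak (DP).

Two detectors are provided.  The derivative-based detector works on the
filtered pulse (xFILT) using first- and second-derivative rules; when the DP
is not visible as a peak it falls back to the second-derivative
zero-crossing after the notch.  The wavelet detector works on the enhanced
pulse (xMODWT), where SP, DN and DP appear as the first peak, the following
minimum and the next peak respectively.

``compare_detectors`` reproduces the error statistics between the two
detectors: signed per-pulse location differences (derivative minus wavelet)
in seconds, on the sample grid, summarized by mean and standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "FiducialPoint",
    "FiducialSet",
    "PointErrorStats",
    "detect_modwt",
    "detect_derivative",
    "compare_detectors",
    "dp_visibility_rate",
    "has_dp_peak",
    "stiffness_index",
]


@dataclass
class FiducialPoint:
    """Location of one fiducial: sample index, time from pulse onset, amplitude."""

    index: int
    time: float
    amplitude: float


@dataclass
class FiducialSet:
    """Per-pulse fiducial locations; missing points are ``None`` (never fabricated)."""

    msp: FiducialPoint | None = None
    sp: FiducialPoint | None = None
    dn: FiducialPoint | None = None
    ip: FiducialPoint | None = None
    dp: FiducialPoint | None = None
    detector: str = ""
    fs: float = np.nan
    dp_from_peak: bool = False  # DP found as a true local maximum of the view

    def present(self, name: str) -> bool:
        return getattr(self, name) is not None


@dataclass
class PointErrorStats:
    """Signed location-difference statistics for one fiducial point."""

    point: str
    errors: np.ndarray
    mean: float
    std: float
    resolution: float

    @property
    def n(self) -> int:
        return int(self.errors.size)


def _point(x: np.ndarray, i: int, fs: float) -> FiducialPoint:
    return FiducialPoint(index=int(i), time=float(i) / fs, amplitude=float(x[int(i)]))


def _strict_local_maxima(x: np.ndarray, prominence: float) -> np.ndarray:
    peaks, _ = find_peaks(x, prominence=prominence)
    return peaks


def detect_modwt(x: np.ndarray, fs: float, prominence_frac: float = 0.05) -> FiducialSet:
    """Extrema-based detection on the enhanced (xMODWT) pulse.

    SP is the first interior local maximum with prominence at least
    ``prominence_frac`` of the signal range (small boundary ripples from the
    circular decomposition are ignored); DN is the first strict local
    minimum after SP and DP the first strict local maximum after DN (no
    prominence filter: the whole point of the enhancement is that these are
    plain extrema, however small).  MSP is the steepest point of the
    upstroke preceding SP.  A monotone pulse yields an empty set.
    """
    x = np.asarray(x, dtype=float)
    out = FiducialSet(detector="modwt", fs=fs)
    if x.size < 5 or np.ptp(x) == 0:
        return out
    prom = prominence_frac * np.ptp(x)
    maxima = _strict_local_maxima(x, prom)
    if maxima.size == 0:
        return out
    sp = int(maxima[0])
    out.sp = _point(x, sp, fs)
    d1 = np.gradient(x)
    rise = d1[:sp]
    if rise.size:
        out.msp = _point(x, int(np.argmax(rise)), fs)
    minima_all, _ = find_peaks(-x)
    after_min = minima_all[minima_all > sp]
    if after_min.size == 0:
        return out
    dn = int(after_min[0])
    out.dn = _point(x, dn, fs)
    maxima_all, _ = find_peaks(x)
    after_max = maxima_all[maxima_all > dn]
    if after_max.size:
        dp = int(after_max[0])
        out.dp = _point(x, dp, fs)
        out.dp_from_peak = True
        d2 = np.gradient(d1)
        seg = d2[dn : dp + 1]
        ch = np.nonzero(np.diff(np.signbit(seg)))[0]
        if ch.size:
            out.ip = _point(x, dn + int(ch[0]), fs)
    return out


def detect_derivative(x: np.ndarray, fs: float, d2_prominence_frac: float = 0.02) -> FiducialSet:
    """First/second-derivative detection on the filtered (xFILT) pulse.

    MSP is the first-derivative argmax; SP the first downward zero-crossing
    of the first derivative after MSP (the systolic maximum); DN the first
    signal local minimum after SP when the notch is distinct, otherwise the
    first prominent local maximum of the second derivative after SP (the
    notch signature in a notch-less decay); DP the first signal local
    maximum after DN when one exists, otherwise the second-derivative
    downward zero-crossing after DN; IP the first second-derivative sign
    change between DN and DP.  Derivatives use central finite differences;
    a flat pulse yields an empty set.
    """
    x = np.asarray(x, dtype=float)
    out = FiducialSet(detector="derivative", fs=fs)
    if x.size < 5 or np.ptp(x) == 0:
        return out
    d1 = np.gradient(x)
    d2 = np.gradient(d1)

    msp = int(np.argmax(d1))
    out.msp = _point(x, msp, fs)

    sp = None
    for i in range(msp, x.size - 1):
        if d1[i] >= 0.0 > d1[i + 1]:
            sp = i if x[i] >= x[i + 1] else i + 1
            break
    if sp is None:
        return out
    out.sp = _point(x, sp, fs)

    sig_minima, _ = find_peaks(-x[sp + 1 :])
    if sig_minima.size:
        dn = sp + 1 + int(sig_minima[0])
    else:
        d2_prom = d2_prominence_frac * np.ptp(d2)
        d2_peaks, _ = find_peaks(d2[sp + 1 :], prominence=d2_prom)
        if d2_peaks.size == 0:
            return out
        dn = sp + 1 + int(d2_peaks[0])
    out.dn = _point(x, dn, fs)

    sig_peaks, _ = find_peaks(x[dn:])
    dp = None
    if sig_peaks.size:
        dp = dn + int(sig_peaks[0])
        out.dp_from_peak = True
    else:
        for i in range(dn + 1, x.size - 1):
            if d2[i] >= 0.0 > d2[i + 1]:
                dp = i
                break
    if dp is not None:
        out.dp = _point(x, dp, fs)
        seg = d2[dn : dp + 1]
        ch = np.nonzero(np.diff(np.signbit(seg)))[0]
        if ch.size:
            out.ip = _point(x, dn + int(ch[0]), fs)
        elif not out.dp_from_peak:
            out.ip = _point(x, dp, fs)
    return out


def compare_detectors(pairs, fs: float, points=("sp", "dp", "dn")) -> list[PointErrorStats]:
    """Signed location differences (derivative minus wavelet) per point.

    ``pairs`` is an iterable of ``(derivative_set, modwt_set)``; only pulses
    where both detectors report the point contribute.  Times live on the
    sample grid, so every error is an integer multiple of ``1/fs``.
    """
    out = []
    for name in points:
        errs = []
        for d_set, m_set in pairs:
            pd_, pm = getattr(d_set, name), getattr(m_set, name)
            if pd_ is None or pm is None:
                continue
            errs.append(pd_.time - pm.time)
        errs = np.asarray(errs, dtype=float)
        mean = float(errs.mean()) if errs.size else np.nan
        std = float(errs.std(ddof=1)) if errs.size > 1 else np.nan
        out.append(PointErrorStats(point=name.upper(), errors=errs, mean=mean,
                                   std=std, resolution=1.0 / fs))
    return out


def has_dp_peak(x: np.ndarray, prominence_frac: float = 0.01) -> bool:
    """Whether a pulse view shows the DP as a true local maximum.

    True when a second prominent local maximum follows a local minimum after
    the first (systolic) peak.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5 or np.ptp(x) == 0:
        return False
    prom = prominence_frac * np.ptp(x)
    maxima = _strict_local_maxima(x, prom)
    if maxima.size < 2:
        return False
    minima = _strict_local_maxima(-x, prom)
    sp = maxima[0]
    after_min = minima[minima > sp]
    if after_min.size == 0:
        return False
    return bool(np.any(maxima > after_min[0]))


def dp_visibility_rate(views, prominence_frac: float = 0.01) -> float:
    """Fraction of pulses whose view shows a distinct diastolic peak."""
    views = list(views)
    if not views:
        raise ValueError("dp_visibility_rate needs at least one pulse")
    hits = sum(has_dp_peak(v, prominence_frac) for v in views)
    return hits / len(views)


def stiffness_index(fiducials: FiducialSet, height: float) -> float:
    """Arterial stiffness index ``SI = h / (TDP - TSP)`` in m/s.

    ``height`` is the subject height in meters.  NaN when SP or DP is
    missing or their ordering is degenerate (``TDP <= TSP``).
    """
    if fiducials.sp is None or fiducials.dp is None:
        return np.nan
    dt = fiducials.dp.time - fiducials.sp.time
    if dt <= 0:
        return np.nan
    return height / dt
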