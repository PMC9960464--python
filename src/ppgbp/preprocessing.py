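"""Record alignment, chunking and per-chunk signal conditioning.

The conditioning chain for the PPG channel is: zero-phase second-order
Butterworth band-pass (0.5-8 Hz), Z-score standardization, then removal of a
least-squares fourth-degree polynomial baseline.  The result is the
``xFILT`` view on which segmentation, enhancement and most features operate.
The ABP channel is low-passed (order-10 Yule-Walker recursive design, 8 Hz
cutoff) before slope-sum segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "WaveformRecord",
    "Chunk",
    "align_by_xcorr",
    "chunk",
    "bandpass_ppg",
    "zscore",
    "baseline_correct",
    "lowpass_abp",
    "yulewalker_design",
    "preprocess_record",
]


@dataclass
class WaveformRecord:
    """Paired single-channel PPG and ABP waveforms at a common sampling rate.

    ``ppg`` is in arbitrary (photodetector) units, ``abp`` in mmHg.
    """

    ppg: np.ndarray
    abp: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppg = np.asarray(self.ppg, dtype=float)
        self.abp = np.asarray(self.abp, dtype=float)
        if self.ppg.size == 0 or self.abp.size == 0:
            raise ValueError("ppg and abp must be non-empty")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def duration(self) -> float:
        return self.ppg.size / self.fs


@dataclass
class Chunk:
    """One fixed-length block of an aligned record.

    ``ppg_filt`` holds the xFILT view; ``raw_mean``/``raw_std`` are the chunk
    statistics of the denoised PPG *before* Z-scoring (they are feature
    inputs, not bookkeeping).  ``quality`` is attached by the quality gates.
    """

    ppg_filt: np.ndarray
    abp: np.ndarray
    abp_lp: np.ndarray
    start_index: int
    fs: float
    raw_mean: float = np.nan
    raw_std: float = np.nan
    degenerate: bool = False
    quality: object | None = None

    @property
    def n(self) -> int:
        return self.ppg_filt.size


class AlignmentError(ValueError):
    """Raised when the cross-correlation argmax is undefined."""


def align_by_xcorr(ppg: np.ndarray, abp: np.ndarray, max_lag: int,
                   standardize: bool = True):
    """Estimate the PPG-vs-ABP lag and return the aligned overlap.

    The lag is the argmax over ``dt`` in ``[-max_lag, max_lag]`` of
    ``sum_t ABP(t) * PPG(t + dt)``; a positive lag means the PPG trails the
    ABP.  Both signals are standardized first by default (the correlation
    objective is otherwise dominated by the ABP's mmHg offset).  Ties are
    broken toward the smallest ``|lag|``.  Returns
    ``(lag, ppg_aligned, abp_aligned)`` where the outputs are the
    equal-length overlapping portions after advancing the PPG by ``lag``.
    """
    ppg = np.asarray(ppg, dtype=float)
    abp = np.asarray(abp, dtype=float)
    max_lag = int(max_lag)
    if ppg.size <= 2 * max_lag or abp.size <= 2 * max_lag:
        raise AlignmentError("signals must be longer than twice max_lag")
    if np.ptp(ppg) == 0 or np.ptp(abp) == 0:
        raise AlignmentError("constant input: correlation argmax undefined")

    a = (abp - abp.mean()) / abp.std() if standardize else abp
    p = (ppg - ppg.mean()) / ppg.std() if standardize else ppg
    # full cross-correlation sum_t a(t) p(t+dt); scipy.correlate(p, a) gives
    # sum_t p(t + k) a(t) at index offset k = i - (len(a) - 1)
    cc = signal.correlate(p, a, mode="full")
    lags = np.arange(-(a.size - 1), p.size)
    sel = (lags >= -max_lag) & (lags <= max_lag)
    cc_w = cc[sel]
    lags_w = lags[sel]
    best = np.max(cc_w)
    ties = lags_w[cc_w >= best - 1e-12 * max(1.0, abs(best))]
    lag = int(ties[np.argmin(np.abs(ties))])

    if lag >= 0:
        ppg_al, abp_al = ppg[lag:], abp
    else:
        ppg_al, abp_al = ppg, abp[-lag:]
    m = min(ppg_al.size, abp_al.size)
    return lag, ppg_al[:m], abp_al[:m]


def chunk(record: WaveformRecord, length_s: float = 30.0) -> list[Chunk]:
    """Cut an aligned record into consecutive fixed-length blocks.

    The trailing remainder shorter than ``length_s`` is discarded; a record
    shorter than one block yields an empty list.  The returned chunks carry
    the raw (unfiltered) signals; run :func:`preprocess_record` to fill the
    xFILT and low-passed ABP views.
    """
    n_chunk = int(round(length_s * record.fs))
    n = min(record.ppg.size, record.abp.size)
    out = []
    for k in range(n // n_chunk):
        lo = k * n_chunk
        hi = lo + n_chunk
        out.append(
            Chunk(ppg_filt=record.ppg[lo:hi].copy(), abp=record.abp[lo:hi].copy(),
                  abp_lp=np.array([]), start_index=lo, fs=record.fs)
        )
    return out


def bandpass_ppg(x: np.ndarray, fs: float, low: float = 0.5, high: float = 8.0,
                 order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-pass (default 0.5-8 Hz, second order).

    Applied forward-backward so fiducial timings are not biased by group
    delay; the effective magnitude response is the squared design response.
    """
    if fs <= 2 * high:
        raise ValueError(f"fs={fs} too low for a {high} Hz band edge")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def zscore(x: np.ndarray) -> np.ndarray:
    """Standardize to zero mean, unit (sample) standard deviation.

    A constant input is returned as zeros; callers flag it degenerate via
    :func:`is_degenerate` rather than receiving an exception.
    """
    x = np.asarray(x, dtype=float)
    s = x.std(ddof=1) if x.size > 1 else 0.0
    if s == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / s


def is_degenerate(x: np.ndarray) -> bool:
    return np.ptp(np.asarray(x, dtype=float)) == 0


def baseline_correct(x: np.ndarray, degree: int = 4) -> np.ndarray:
    """Remove the least-squares polynomial baseline (degree 4 by default).

    This is a linear projection: applying it twice equals applying it once.
    """
    x = np.asarray(x, dtype=float)
    if x.size <= degree + 1:
        raise ValueError("chunk too short for baseline fit")
    t = np.linspace(-1.0, 1.0, x.size)  # scaled axis keeps the fit well-conditioned
    coeffs = np.polynomial.polynomial.polyfit(t, x, degree)
    return x - np.polynomial.polynomial.polyval(t, coeffs)


def yulewalker_design(order: int, freqs, mags, npt: int = 512, n_iter: int = 8):
    """Least-squares recursive (IIR) filter fit to a magnitude specification.

    ``freqs`` are breakpoints normalized to Nyquist=1 and ``mags`` the
    desired magnitudes at those breakpoints.  The magnitude spec is first
    turned into a minimum-phase complex frequency response through the real
    cepstrum; an order-``order`` rational transfer function is then fit to
    that target by weighted complex least squares with Sanathanan-Koerner
    iteration (the weight ``1/|A|`` de-biases the linearized equation
    error).  Poles falling outside the unit circle are reflected inside,
    preserving the magnitude; the result is normalized to unit gain at DC.
    Returns ``(b, a)``.
    """
    freqs = np.asarray(freqs, dtype=float)
    mags = np.asarray(mags, dtype=float)
    grid = np.linspace(0.0, 1.0, npt)
    hd = np.interp(grid, freqs, mags)

    # minimum-phase complex target via the real cepstrum of log |H|
    tiny = 1e-8 * max(hd.max(), 1.0)
    log_mag = np.log(np.maximum(hd, tiny))
    log_full = np.concatenate([log_mag, log_mag[-2:0:-1]])
    cep = np.fft.ifft(log_full).real
    m = log_full.size
    fold = np.zeros(m)
    fold[0] = cep[0]
    fold[1 : m // 2] = 2.0 * cep[1 : m // 2]
    fold[m // 2] = cep[m // 2]
    target = np.exp(np.fft.fft(fold))[:npt]

    w = np.pi * grid
    basis = np.exp(-1j * np.outer(w, np.arange(order + 1)))
    b = np.zeros(order + 1)
    a = np.ones(order + 1)
    a_prev = np.ones(npt, dtype=complex)
    for _ in range(n_iter):
        wt = 1.0 / np.maximum(np.abs(a_prev), 1e-6)
        lhs = np.concatenate(
            [basis * wt[:, None], -(target * wt)[:, None] * basis[:, 1:]], axis=1
        )
        rhs = target * wt
        lhs_ri = np.concatenate([lhs.real, lhs.imag])
        rhs_ri = np.concatenate([rhs.real, rhs.imag])
        sol, *_ = np.linalg.lstsq(lhs_ri, rhs_ri, rcond=None)
        b = sol[: order + 1]
        a = np.concatenate([[1.0], sol[order + 1 :]])
        poles = np.roots(a)
        poles = np.where(np.abs(poles) >= 1.0, 1.0 / np.conj(poles), poles)
        a = np.real(np.poly(poles))
        a_prev = basis @ a

    if np.any(np.abs(np.roots(a)) >= 1.0):
        raise ValueError("unstable recursive design for this spec")
    dc = np.sum(b) / np.sum(a)
    if dc != 0:
        b = b / dc
    return b, a


def lowpass_abp(abp: np.ndarray, fs: float, cutoff: float = 8.0,
                order: int = 10) -> np.ndarray:
    """Low-pass the ABP with the order-10 Yule-Walker recursive design.

    The magnitude spec is a unit-gain passband up to ``cutoff`` with a short
    transition band; application is zero-phase.  Passband ripple of the
    design is below about 0.5 dB (single pass) for the default spec.
    """
    if fs <= 2 * cutoff:
        raise ValueError(f"fs={fs} too low for a {cutoff} Hz cutoff")
    nyq = fs / 2.0
    fc = cutoff / nyq
    ft = min(1.0, fc + 0.1)
    b, a = yulewalker_design(order, [0.0, fc, ft, 1.0], [1.0, 1.0, 0.0, 0.0])
    return signal.filtfilt(b, a, np.asarray(abp, dtype=float))


def preprocess_record(record: WaveformRecord, length_s: float = 30.0,
                      band=(0.5, 8.0), butter_order: int = 2,
                      baseline_degree: int = 4) -> list[Chunk]:
    """Chunk a record and fill the xFILT and low-passed ABP views per chunk.

    Per chunk: band-pass the PPG, record the denoised mean/std (pre-Z-score
    chunk statistics used later as features), Z-score, remove the polynomial
    baseline.  The ABP view is the zero-phase Yule-Walker low-pass.
    """
    chunks = chunk(record, length_s=length_s)
    for c in chunks:
        denoised = bandpass_ppg(c.ppg_filt, record.fs, band[0], band[1], butter_order)
        c.raw_mean = float(denoised.mean())
        c.raw_std = float(denoised.std(ddof=1))
        c.degenerate = is_degenerate(denoised)
        z = zscore(denoised)
        c.ppg_filt = baseline_correct(z, degree=baseline_degree) if not c.degenerate else z
        c.abp_lp = lowpass_abp(c.abp, record.fs)
    return chunks
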