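"""Slope-sum pulse onset detection, pulse segmentation and BP labeling.

The slope sum function (SSF) at sample ``i`` is the sum of the positive
sample-to-sample increments inside the trailing window of ``w`` samples; it
is large on pulse upslopes and zero on monotone decays, which makes its
upstroke start a robust pulse-onset marker.  The window defaults to 0.128 s
(16 samples at 125 Hz), the typical duration of a pulse upslope.

Onset picking uses an adaptive threshold: a running median of recently
accepted SSF peak heights, scaled by a fixed fraction, with a refractory
period between onsets.  Detection is therefore invariant to amplitude
rescaling of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import skew

__all__ = [
    "SlopeSumParams",
    "PulseSegment",
    "PulseLabel",
    "slope_sum",
    "detect_onsets",
    "segment_ppg",
    "label_pulses",
]


@dataclass
class SlopeSumParams:
    """Slope-sum analysis settings.

    ``threshold_frac`` scales the running-median SSF peak height into the
    acceptance threshold; ``refractory_s`` is the minimum inter-onset
    spacing; ``init_window_s`` seeds the running median from the first
    seconds of the chunk.
    """

    fs: float
    window_s: float = 0.128
    threshold_frac: float = 0.6
    refractory_s: float = 0.3
    init_window_s: float = 3.0
    median_window: int = 8

    @property
    def window(self) -> int:
        w = int(round(self.window_s * self.fs))
        if w < 1:
            raise ValueError("slope-sum window must span at least one sample")
        return w


@dataclass
class PulseSegment:
    """One PPG pulse in the half-open interval ``[onset, next_onset)``.

    Carries the three per-pulse signal views: ``view_filt`` (xFILT slice),
    ``view_norm`` (per-pulse min-max normalization to [0, 1]) and
    ``view_modwt`` (filled by the wavelet-enhancement stage).
    """

    onset: int
    end: int
    view_filt: np.ndarray
    view_norm: np.ndarray = field(default=None)
    view_modwt: np.ndarray | None = None
    chunk_ref: object | None = None
    skewness: float = np.nan
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.view_filt = np.asarray(self.view_filt, dtype=float)
        if self.n < 2:
            raise ValueError("pulse must span at least 2 samples")
        if self.view_norm is None:
            lo, hi = self.view_filt.min(), self.view_filt.max()
            if hi - lo == 0:
                self.view_norm = np.zeros_like(self.view_filt)
                self.degenerate = True
            else:
                self.view_norm = (self.view_filt - lo) / (hi - lo)
        if np.isnan(self.skewness):
            self.skewness = float(skew(self.view_filt, bias=True)) if not self.degenerate else np.nan

    @property
    def n(self) -> int:
        return int(self.view_filt.size)


@dataclass
class PulseLabel:
    """Per-pulse systolic/diastolic pressure label with validity flag."""

    sbp: float
    dbp: float
    valid: bool
    reason: str = ""


def slope_sum(x: np.ndarray, params: SlopeSumParams) -> np.ndarray:
    """Trailing-window sum of positive increments (the SSF).

    Output has the input length; the first ``w`` samples are warm-up (the
    window is truncated there).  Non-negative everywhere and exactly zero
    over monotonically non-increasing stretches longer than the window.
    """
    x = np.asarray(x, dtype=float)
    w = params.window
    if x.size <= w:
        raise ValueError("signal must be longer than the slope-sum window")
    inc = np.diff(x, prepend=x[0])
    inc[inc < 0] = 0.0
    c = np.concatenate([[0.0], np.cumsum(inc)])
    ssf = np.empty(x.size)
    idx = np.arange(x.size) + 1
    lo = np.maximum(idx - w, 0)
    ssf = c[idx] - c[lo]
    return ssf


def detect_onsets(ssf: np.ndarray, params: SlopeSumParams,
                  signal: np.ndarray | None = None) -> np.ndarray:
    """Pick pulse onsets from an SSF trace.

    SSF peaks are accepted when they exceed ``threshold_frac`` times the
    running median of recently accepted peak heights (seeded from the median
    SSF peak height of the first ``init_window_s`` seconds); each accepted
    peak is localized by walking backward to the start of the SSF upstroke
    (nearest local minimum or near-zero sample).  When the segmentation
    ``signal`` itself is supplied, the onset is refined to the signal
    minimum in a half-window around that point (the pulse foot).  Peaks in
    the warm-up region (first ``w`` samples) are ignored.  Returns strictly
    increasing onset indices spaced by at least the refractory period; an
    empty array when nothing is found.
    """
    ssf = np.asarray(ssf, dtype=float)
    w = params.window
    refractory = max(1, int(round(params.refractory_s * params.fs)))
    if ssf.size == 0 or np.ptp(ssf) == 0:
        return np.array([], dtype=int)

    peaks, _ = find_peaks(ssf, distance=refractory)
    peaks = peaks[peaks >= w]
    if peaks.size == 0:
        return np.array([], dtype=int)

    heights = ssf[peaks]
    top_half = np.sort(heights)[heights.size // 2 :]
    global_ref = float(np.median(top_half))
    init_hi = w + int(round(params.init_window_s * params.fs))
    init_peaks = peaks[peaks < init_hi]
    seed_height = float(np.median(ssf[init_peaks])) if init_peaks.size else global_ref
    seed_height = max(seed_height, global_ref)
    recent = [seed_height]

    accepted = []
    for p in peaks:
        # floor keeps a run of small spurious peaks from dragging the
        # adaptive threshold into the noise
        ref = max(float(np.median(recent[-params.median_window:])), 0.6 * global_ref)
        thr = params.threshold_frac * ref
        if ssf[p] >= thr:
            accepted.append(int(p))
            recent.append(float(ssf[p]))

    onsets = []
    floor_eps = 1e-3
    for p in accepted:
        lo = max(0, p - 3 * w)
        k = p
        found = None
        while k > lo:
            k -= 1
            if ssf[k] <= floor_eps * ssf[p]:
                found = k
                break
            if 0 < k < ssf.size - 1 and ssf[k] <= ssf[k - 1] and ssf[k] <= ssf[k + 1]:
                found = k
                break
        if found is None:
            found = lo + int(np.argmin(ssf[lo:p])) if p > lo else p
        if signal is not None:
            half = max(2, w // 2)
            s_lo = max(0, found - half)
            s_hi = min(len(signal), found + half + 1)
            found = s_lo + int(np.argmin(signal[s_lo:s_hi]))
        onsets.append(found)

    out = []
    for o in sorted(set(onsets)):
        if out and o - out[-1] < refractory:
            continue
        out.append(o)
    return np.array(out, dtype=int)


def segment_ppg(chunk, onsets, drop_first: bool = True) -> list[PulseSegment]:
    """Cut a chunk's xFILT into pulses at consecutive onset pairs.

    The first segment is dropped (it may contain a partial pulse); each
    remaining segment gets its [0, 1] min-max normalized view and skewness.
    Fewer than two onsets yield an empty list.
    """
    onsets = np.asarray(onsets, dtype=int)
    if onsets.size < 2:
        return []
    segments = []
    pairs = list(zip(onsets[:-1], onsets[1:]))
    if drop_first:
        pairs = pairs[1:]
    for lo, hi in pairs:
        if hi - lo < 2:
            continue
        segments.append(
            PulseSegment(onset=int(lo), end=int(hi),
                         view_filt=chunk.ppg_filt[lo:hi], chunk_ref=chunk)
        )
    return segments


def label_pulses(abp: np.ndarray, ppg_bounds, sbp_max: float = 300.0,
                 dbp_min: float = 20.0) -> list[PulseLabel]:
    """Measure SBP/DBP on ABP intervals re-segmented by PPG pulse bounds.

    Per half-open interval, SBP is the ABP maximum and DBP the minimum
    *following* the systolic peak within the same interval.  Labels are
    invalid when the interval is empty, when the peak is the last sample
    (no following minimum), or on non-physiological values
    (``SBP > sbp_max`` or ``DBP < dbp_min``).
    """
    abp = np.asarray(abp, dtype=float)
    labels = []
    for lo, hi in ppg_bounds:
        lo, hi = int(lo), int(hi)
        if hi - lo < 2 or lo < 0 or hi > abp.size:
            labels.append(PulseLabel(np.nan, np.nan, False, "empty interval"))
            continue
        seg = abp[lo:hi]
        i_sbp = int(np.argmax(seg))
        sbp = float(seg[i_sbp])
        if i_sbp >= seg.size - 1:
            labels.append(PulseLabel(sbp, np.nan, False, "peak at interval end"))
            continue
        dbp = float(np.min(seg[i_sbp + 1 :]))
        if sbp > sbp_max:
            labels.append(PulseLabel(sbp, dbp, False, f"SBP>{sbp_max:g}"))
        elif dbp < dbp_min:
            labels.append(PulseLabel(sbp, dbp, False, f"DBP<{dbp_min:g}"))
        elif not sbp > dbp:
            labels.append(PulseLabel(sbp, dbp, False, "SBP<=DBP"))
        else:
            labels.append(PulseLabel(sbp, dbp, True))
    return labels
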