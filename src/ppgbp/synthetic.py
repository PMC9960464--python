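"""Synthetic paired PPG/ABP waveform generator with exact ground truth.

Each beat is a smooth kernel built from Gaussian lobes (systolic lobe,
diastolic lobe, slow baseline run-off) so that every extremum of the
noiseless waveform is known analytically up to sample rounding.  The ABP
channel uses a morphologically similar kernel affinely rescaled per beat to
the configured ``[DBP, SBP]`` range in mmHg.  The generator supports a
configurable PPG-vs-ABP acquisition lag, additive white noise, sinusoidal
baseline wander and beat-to-beat heart-rate jitter, and reports ground-truth
pulse onsets, fiducial locations and per-beat pressure labels so every
downstream stage can be tested without external recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
__all__ = ["SynthConfig", "GroundTruth", "BeatTruth", "generate_pulse_pair", "generate_record"]

# Pulse-kernel morphology, in fractions of the beat period (center, width)
# and fractions of the systolic amplitude.  The diastolic lobe amplitude has
# a "visible" value (a distinct local maximum appears after the notch) and a
# "hidden" value (only an inflection shoulder remains, as in many adult
# fingertip recordings).  The exponential run-off models diastolic decay and
# gives the waveform a well-defined foot minimum before every upstroke.
_SYS = dict(amp=1.00, c=0.20, s=0.075)
_DIA_VIS = dict(amp=0.32, c=0.47, s=0.11)
_DIA_HID = dict(amp=0.14, c=0.47, s=0.11)
_TAIL = dict(amp=0.50, tau=0.60, gate_c=0.30, gate_s=0.04)

# ABP morphology: the arterial pulse always shows a marked dicrotic notch.
# Lobe timing matches the PPG kernel (the two channels are synchronous at
# the generator level; any offset is imposed explicitly via ``lag``), only
# the amplitude mix differs.
_ABP_SYS = dict(amp=1.00, c=0.20, s=0.075)
_ABP_DIA = dict(amp=0.38, c=0.47, s=0.11)
_ABP_TAIL = dict(amp=0.55, tau=0.60, gate_c=0.30, gate_s=0.04)

_OVERSAMPLE = 8  # oversampling factor used when locating true extrema


@dataclass
class SynthConfig:
    """Generator settings; defaults emulate a bedside-monitor recording.

    ``lag`` is the number of samples by which the PPG channel trails the ABP
    channel (positive: PPG later).  ``noise_sd`` is relative to the systolic
    pulse amplitude.  ``dp_visibility`` is the fraction of beats drawn with a
    distinct diastolic peak.
    """

    fs: float = 125.0
    duration: float = 60.0
    heart_rate: float = 75.0
    lag: int = 0
    sbp: float = 120.0
    dbp: float = 80.0
    dp_visibility: float = 1.0
    noise_sd: float = 0.02
    drift_amp: float = 0.15
    drift_freq: float = 0.10
    hr_jitter: float = 0.03
    amp_jitter: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 20.0 <= self.dbp < self.sbp <= 300.0:
            raise ValueError("need 20 <= dbp < sbp <= 300 mmHg")
        if not 0.0 <= self.dp_visibility <= 1.0:
            raise ValueError("dp_visibility must be in [0, 1]")
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")
        if self.noise_sd < 0 or self.hr_jitter < 0 or self.amp_jitter < 0:
            raise ValueError("noise/jitter magnitudes must be non-negative")


@dataclass
class BeatTruth:
    """Ground-truth description of one generated beat (indices in samples)."""

    onset: int
    msp: int | None
    sp: int | None
    dn: int | None
    ip: int | None
    dp: int | None
    dp_present: bool
    sbp: float
    dbp: float


@dataclass
class GroundTruth:
    """Record-level ground truth: onsets, fiducials, labels, imposed lag."""

    beats: list[BeatTruth]
    lag: int
    fs: float

    @property
    def onsets(self) -> np.ndarray:
        return np.array([b.onset for b in self.beats], dtype=int)

    @property
    def labels(self) -> np.ndarray:
        return np.array([(b.sbp, b.dbp) for b in self.beats], dtype=float)

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, b in enumerate(self.beats):
            rows.append(
                dict(beat=i, onset=b.onset, msp=b.msp, sp=b.sp, dn=b.dn, ip=b.ip,
                     dp=b.dp, dp_present=b.dp_present, sbp=b.sbp, dbp=b.dbp)
            )
        return pd.DataFrame(rows)


def _gauss(u: np.ndarray, amp: float, c: float, s: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((u - c) / s) ** 2)


def _kernel(u: np.ndarray, dp_visible: bool, kind: str = "ppg") -> np.ndarray:
    """Evaluate one beat kernel at phase ``u`` (fraction of the beat period).

    Support is effectively ``u`` in ``[-0.5, 2)``: the run-off tail of a beat
    reaches into the next beat, which is what creates the foot minimum when
    consecutive kernels are summed.
    """
    if kind == "ppg":
        sys_, tail = _SYS, _TAIL
        dia = _DIA_VIS if dp_visible else _DIA_HID
    else:
        sys_, dia, tail = _ABP_SYS, _ABP_DIA, _ABP_TAIL
    y = _gauss(u, **sys_) + _gauss(u, **dia)
    gate = 1.0 / (1.0 + np.exp(-(u - tail["gate_c"]) / tail["gate_s"]))
    # closing gate tapers the run-off smoothly to zero well inside the
    # kernel support so truncation leaves no step
    close = 1.0 / (1.0 + np.exp((u - 1.35) / 0.06))
    y = y + tail["amp"] * np.exp(-np.clip(u, 0.0, None) / tail["tau"]) * gate * close
    return y


def _beat_layout(cfg: SynthConfig, rng: np.random.Generator, n_samples: int):
    """Draw beat start times, periods, amplitudes and DP visibility flags."""
    period0 = cfg.fs * 60.0 / cfg.heart_rate
    starts, periods, amps, visible = [], [], [], []
    t = 0.0
    # one extra leading/trailing beat so edge beats still see their neighbors
    while t < n_samples + 2 * period0:
        eps = rng.normal(0.0, cfg.hr_jitter) if cfg.hr_jitter > 0 else 0.0
        period = period0 * float(np.clip(1.0 + eps, 0.6, 1.6))
        amp = 1.0 + (rng.normal(0.0, cfg.amp_jitter) if cfg.amp_jitter > 0 else 0.0)
        starts.append(t)
        periods.append(period)
        amps.append(max(amp, 0.2))
        visible.append(bool(rng.random() < cfg.dp_visibility))
        t += period
    return np.array(starts), np.array(periods), np.array(amps), visible


def _render(starts, periods, amps, visible, n, kind: str, oversample: int = 1) -> np.ndarray:
    """Sum beat kernels onto a sample grid of ``n * oversample`` points."""
    out = np.zeros(n * oversample)
    grid = np.arange(n * oversample) / oversample
    for t0, per, amp, vis in zip(starts, periods, amps, visible):
        lo = int(np.floor((t0 - 0.5 * per) * oversample))
        hi = int(np.ceil((t0 + 2.0 * per) * oversample))
        lo = max(lo, 0)
        hi = min(hi, n * oversample)
        if hi <= lo:
            continue
        u = (grid[lo:hi] - t0) / per
        out[lo:hi] += amp * _kernel(u, vis, kind=kind)
    return out


def _prominent_extrema(x: np.ndarray, prominence_frac: float = 1e-3) -> np.ndarray:
    """Strict local maxima of ``x`` with prominence above a small fraction of
    the range; filters out numerical micro-ripples of the kernel model."""
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(x, prominence=prominence_frac * np.ptp(x))
    return peaks


def _truth_from_clean(clean_os: np.ndarray, starts, periods, visible, n: int,
                      oversample: int, fs: float) -> list[BeatTruth]:
    """Locate extrema of the oversampled noiseless PPG and assign per beat.

    The onset is the foot minimum just before the systolic upstroke; SP is
    the following maximum; DN the next minimum (when the diastolic lobe is
    distinct); DP the maximum after DN.  MSP is the steepest point of the
    upstroke; IP the inflection between DN and DP.  Indices are on the
    output sample grid (oversampled locations rounded down-scaled).
    """
    minima = _prominent_extrema(-clean_os)
    maxima = _prominent_extrema(clean_os)
    d1 = np.gradient(clean_os)
    d2 = np.gradient(d1)
    beats: list[BeatTruth] = []
    for t0, per, vis in zip(starts, periods, visible):
        # foot minimum expected shortly before the nominal beat start
        win_lo = int((t0 - 0.35 * per) * oversample)
        win_hi = int((t0 + 0.12 * per) * oversample)
        cand = minima[(minima >= win_lo) & (minima <= win_hi)]
        if cand.size == 0:
            continue
        onset_os = int(cand[np.argmin(clean_os[cand])])
        nxt_lo = int((t0 + per - 0.35 * per) * oversample)
        nxt_hi = int((t0 + per + 0.12 * per) * oversample)
        nxt = minima[(minima >= nxt_lo) & (minima <= nxt_hi)]
        end_os = int(nxt[np.argmin(clean_os[nxt])]) if nxt.size else int((t0 + per) * oversample)

        in_beat = lambda a: a[(a > onset_os) & (a < end_os)]  # noqa: E731
        maxs = in_beat(maxima)
        mins = in_beat(minima)
        if maxs.size == 0:
            continue
        sp_os = int(maxs[0])
        dn_os = None
        dp_os = None
        after_sp_min = mins[mins > sp_os]
        if after_sp_min.size:
            dn_os = int(after_sp_min[0])
            after_dn_max = maxs[maxs > dn_os]
            if after_dn_max.size:
                dp_os = int(after_dn_max[0])
        msp_seg = d1[onset_os:sp_os]
        msp_os = onset_os + int(np.argmax(msp_seg)) if msp_seg.size else None
        ip_os = None
        if dn_os is not None and dp_os is not None:
            seg = d2[dn_os:dp_os + 1]
            sign_change = np.nonzero(np.diff(np.signbit(seg)))[0]
            if sign_change.size:
                ip_os = dn_os + int(sign_change[0])
        dp_present = dp_os is not None

        def scale(i):
            return None if i is None else int(round(i / oversample))

        onset = scale(onset_os)
        if onset is None or not 0 <= onset < n:
            continue
        beats.append(
            BeatTruth(onset=onset, msp=scale(msp_os), sp=scale(sp_os), dn=scale(dn_os),
                      ip=scale(ip_os), dp=scale(dp_os), dp_present=dp_present,
                      sbp=np.nan, dbp=np.nan)
        )
    beats.sort(key=lambda b: b.onset)
    # drop duplicates/partial edge beats with missing SP
    dedup: list[BeatTruth] = []
    for b in beats:
        if b.sp is None or b.sp >= n:
            continue
        if dedup and b.onset <= dedup[-1].onset:
            continue
        dedup.append(b)
    return dedup


def generate_pulse_pair(config: SynthConfig, beat_index: int = 0):
    """Generate one isolated PPG/ABP pulse pair plus its truth fragment.

    The beat's DP visibility is a Bernoulli(``dp_visibility``) draw from a
    stream seeded by ``config.seed`` and advanced to ``beat_index``.
    Returns ``(ppg, abp, truth)`` where
    ``truth`` is a :class:`BeatTruth` with indices relative to the pulse
    start and ABP rescaled to ``[dbp, sbp]`` mmHg.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    vis_draws = rng.random(beat_index + 1)
    vis = bool(vis_draws[beat_index] < config.dp_visibility)

    n = int(round(config.fs * 60.0 / config.heart_rate))
    u = np.arange(n) / n
    ppg = _kernel(u, vis, kind="ppg")
    abp_shape = _kernel(u, True, kind="abp")
    lo, hi = abp_shape.min(), abp_shape.max()
    abp = config.dbp + (config.sbp - config.dbp) * (abp_shape - lo) / (hi - lo)

    u_os = np.arange(n * _OVERSAMPLE) / (n * _OVERSAMPLE)
    clean_os = _kernel(u_os, vis, kind="ppg")
    truth = _isolated_truth(clean_os, n, _OVERSAMPLE)
    truth.dp_present = vis and truth.dp is not None
    if not truth.dp_present:
        truth.dp = None
        truth.ip = None
    truth.sbp, truth.dbp = config.sbp, config.dbp
    return ppg, abp, truth


def _isolated_truth(clean_os: np.ndarray, n: int, oversample: int) -> BeatTruth:
    maxima = _prominent_extrema(clean_os)
    minima = _prominent_extrema(-clean_os)
    d1 = np.gradient(clean_os)
    d2 = np.gradient(d1)
    sp_os = int(maxima[0]) if maxima.size else None
    dn_os = dp_os = msp_os = ip_os = None
    if sp_os is not None:
        after = minima[minima > sp_os]
        if after.size:
            dn_os = int(after[0])
            after_max = maxima[maxima > dn_os]
            if after_max.size:
                dp_os = int(after_max[0])
        msp_os = int(np.argmax(d1[:sp_os])) if sp_os > 0 else None
        if dn_os is not None and dp_os is not None:
            seg = d2[dn_os:dp_os + 1]
            ch = np.nonzero(np.diff(np.signbit(seg)))[0]
            if ch.size:
                ip_os = dn_os + int(ch[0])

    def scale(i):
        return None if i is None else int(round(i / oversample))

    return BeatTruth(onset=0, msp=scale(msp_os), sp=scale(sp_os), dn=scale(dn_os),
                     ip=scale(ip_os), dp=scale(dp_os), dp_present=dp_os is not None,
                     sbp=np.nan, dbp=np.nan)


def generate_record(config: SynthConfig):
    """Generate a full paired record and its ground truth.

    Returns ``(record, truth)`` where ``record`` is a
    :class:`~ppgbp.preprocessing.WaveformRecord`.  The PPG channel is delayed
    by ``config.lag`` samples with leading zero-padding (acquisition offset);
    ground-truth indices refer to the delivered, already-delayed PPG.
    Baseline drift is added to the PPG only, so ABP labels stay exact up to
    the configured additive noise.
    """
    from .preprocessing import WaveformRecord

    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(round(config.fs * config.duration))

    starts, periods, amps, visible = _beat_layout(config, rng, n)
    n_beats = len(starts)

    clean_ppg_os = _render(starts, periods, amps, visible, n, "ppg", oversample=_OVERSAMPLE)
    # baseline wander is deterministic, so it belongs to the ground-truth
    # waveform: true extrema are those of the drifted, noise-free signal
    t_os = np.arange(n * _OVERSAMPLE) / (_OVERSAMPLE * config.fs)
    clean_ppg_os = clean_ppg_os + config.drift_amp * np.sin(2 * np.pi * config.drift_freq * t_os)
    clean_ppg = clean_ppg_os[::_OVERSAMPLE].copy()
    clean_abp = _render(starts, periods, amps, [True] * n_beats, n, "abp")

    # per-beat affine rescale of ABP to [dbp, sbp] mmHg between foot minima
    truth_beats = _truth_from_clean(clean_ppg_os, starts, periods, visible, n,
                                    _OVERSAMPLE, config.fs)
    onsets = [b.onset for b in truth_beats]
    abp_mmhg = np.full(n, (config.sbp + config.dbp) / 2.0)
    bounds = [0] + onsets + [n]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi - lo < 2:
            continue
        seg = clean_abp[lo:hi]
        smin, smax = seg.min(), seg.max()
        if smax - smin < 1e-12:
            abp_mmhg[lo:hi] = config.dbp
            continue
        abp_mmhg[lo:hi] = config.dbp + (config.sbp - config.dbp) * (seg - smin) / (smax - smin)
    for b in truth_beats:
        b.sbp, b.dbp = config.sbp, config.dbp

    # additive white noise on both channels (drift already in clean_ppg)
    ppg = clean_ppg
    if config.noise_sd > 0:
        ppg = ppg + rng.normal(0.0, config.noise_sd, n)
        abp_noise_sd = config.noise_sd * (config.sbp - config.dbp)
        abp_mmhg = abp_mmhg + rng.normal(0.0, abp_noise_sd, n)

    # acquisition lag: PPG trails ABP by `lag` samples (zero-padded at the edge)
    lag = int(config.lag)
    if lag > 0:
        ppg = np.concatenate([np.zeros(lag), ppg[:-lag]])
    elif lag < 0:
        ppg = np.concatenate([ppg[-lag:], np.zeros(-lag)])
    for b in truth_beats:
        for attr in ("onset", "msp", "sp", "dn", "ip", "dp"):
            v = getattr(b, attr)
            if v is not None:
                setattr(b, attr, v + lag)
    truth_beats = [b for b in truth_beats if 0 <= b.onset < n and (b.sp is None or b.sp < n)]

    record = WaveformRecord(ppg=ppg, abp=abp_mmhg, fs=config.fs,
                            meta={"source": "ppgbp.synthetic", "seed": str(config.seed)})
    truth = GroundTruth(beats=truth_beats, lag=lag, fs=config.fs)
    return record, truth
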