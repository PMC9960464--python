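"""Per-pulse, per-couple and per-chunk feature catalog.

Features are computed on three pulse views — ``xFILT`` (band-passed,
standardized, baseline-corrected), ``xNORM`` (per-pulse min-max to [0, 1])
and ``xMODWT`` (detail-level 4-5 reconstruction) — plus the raw chunk.
Scopes:

* ``pulse``   — one value per pulse (fiducial timings/amplitudes, areas,
  widths, derivative extremes, time- and frequency-domain statistics);
* ``couple``  — computed on consecutive pulse pairs, averaged over all the
  couples of a chunk and broadcast to every pulse of that chunk;
* ``chunk``   — computed once per chunk (FFT spectrum features, pre-Z-score
  statistics) and broadcast to every pulse.

Feature names carry a view suffix (``T1_xMODWT``); the registry of
:class:`FeatureDescriptor` rows documents each feature's view, scope and
whether it is an established quantity or one proposed for the enhanced
signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import trapezoid
from scipy.signal import find_peaks, periodogram
from scipy.stats import kurtosis, skew

__all__ = [
    "FeatureDescriptor",
    "feature_catalog",
    "pulse_point_features",
    "derivative_features",
    "waveform_stat_features",
    "width_features",
    "couple_features",
    "chunk_fft_features",
    "chunk_raw_stats",
    "build_feature_table",
]

WIDTH_FRACTIONS = (0.10, 0.25, 0.33, 0.50, 0.66, 0.75)


@dataclass(frozen=True)
class FeatureDescriptor:
    """Registry entry for one feature column."""

    name: str
    view: str  # xFILT | xNORM | xMODWT | raw-chunk
    scope: str  # pulse | couple | chunk
    novelty: str  # known | proposed
    definition: str


def _point_names() -> list[str]:
    return [
        "TSP", "TDN", "TDP", "TMSP", "TIP", "TP", "T1", "T2",
        "ASP", "ADN", "ADP", "rise_time", "decay_time",
        "area_total", "area_sys", "area_dia", "area_dp_end",
    ]


def _deriv_names() -> list[str]:
    return [
        "d1max", "d1min", "t_d1max", "t_d1min",
        "d2max", "d2min", "t_d2max", "t_d2min",
        "d1max_ratio", "d2max_ratio",
    ]


def _stat_names() -> list[str]:
    return [
        "SF", "CF", "IF", "ClF", "peak", "RMS", "mean", "std",
        "skewness", "kurtosis",
        "SNR", "SINAD", "THD", "PSA", "SPL",
        "MeaF", "MedF", "OB", "HB", "band_power",
    ]


_CHUNK_FFT_NAMES = [
    "Peak1", "Peak2", "Peak3", "Peak4",
    "Freq1", "Freq2", "Freq3", "Freq4",
    "Area_0_2", "Area_2_5", "Area_5_8", "Area_0_8",
    "ChunkMeaF", "ChunkMedF", "ChunkSpecArea", "ChunkSpecMax",
]

_COUPLE_NAMES = [
    "mean_p2pi", "mean_tb1", "mean_tb2", "mean_TP_over_p2pi", "mean_TDN_over_p2pi",
]

_POINT_DEFS = {
    "TSP": "time of systolic peak from pulse onset (s)",
    "TDN": "time of dicrotic notch (s)",
    "TDP": "time of diastolic peak (s)",
    "TMSP": "time of max slope point (s)",
    "TIP": "time of inflection point (s)",
    "TP": "pulse duration (s)",
    "T1": "SP-to-DN interval (s)",
    "T2": "DN-to-DP interval (s)",
    "ASP": "amplitude at SP",
    "ADN": "amplitude at DN",
    "ADP": "amplitude at DP",
    "rise_time": "onset-to-SP time (s)",
    "decay_time": "SP-to-end time (s)",
    "area_total": "trapezoidal area of the pulse",
    "area_sys": "area onset-to-DN",
    "area_dia": "area DN-to-end",
    "area_dp_end": "area DP-to-end",
}


def feature_catalog() -> pd.DataFrame:
    """Full registry of feature descriptors as a DataFrame."""
    rows: list[FeatureDescriptor] = []
    for view in ("xFILT", "xMODWT"):
        proposed_view = view == "xMODWT"
        for nm in _point_names():
            novelty = "proposed" if proposed_view else "known"
            rows.append(FeatureDescriptor(f"{nm}_{view}", view, "pulse", novelty,
                                          _POINT_DEFS.get(nm, nm)))
        for nm in _deriv_names():
            rows.append(FeatureDescriptor(f"{nm}_{view}", view, "pulse",
                                          "proposed" if proposed_view else "known",
                                          "first/second finite-difference derivative extremum"))
        for nm in _stat_names():
            rows.append(FeatureDescriptor(f"{nm}_{view}", view, "pulse", "proposed",
                                          "time/frequency-domain pulse statistic"))
    for f in WIDTH_FRACTIONS:
        rows.append(FeatureDescriptor(f"width{int(round(f * 100))}_xNORM", "xNORM",
                                      "pulse", "known",
                                      f"pulse width at {f:.0%} of normalized amplitude (s)"))
    for nm in _COUPLE_NAMES:
        rows.append(FeatureDescriptor(nm, "xFILT", "couple", "known",
                                      "chunk-averaged consecutive-pulse interval feature"))
    for nm in _CHUNK_FFT_NAMES:
        rows.append(FeatureDescriptor(nm, "xFILT", "chunk", "known",
                                      "chunk magnitude-spectrum feature"))
    rows.append(FeatureDescriptor("raw_mean", "raw-chunk", "chunk", "known",
                                  "chunk mean after denoising, before Z-score"))
    rows.append(FeatureDescriptor("raw_std", "raw-chunk", "chunk", "known",
                                  "chunk std after denoising, before Z-score"))
    df = pd.DataFrame([r.__dict__ for r in rows])
    assert df["name"].is_unique
    return df


def pulse_point_features(view: np.ndarray, fiducials, fs: float, suffix: str) -> dict:
    """Fiducial-anchored timings, amplitudes and areas for one pulse view.

    Times are seconds from pulse onset; areas use the trapezoidal rule with
    ``dt = 1/fs``.  Features depending on a missing fiducial are NaN.
    """
    x = np.asarray(view, dtype=float)
    n = x.size
    dt = 1.0 / fs
    out = {f"{nm}_{suffix}": np.nan for nm in _point_names()}
    out[f"TP_{suffix}"] = n * dt
    out[f"area_total_{suffix}"] = trapezoid(x, dx=dt)

    def t(pt):
        return pt.time if pt is not None else np.nan

    sp, dn, dp = fiducials.sp, fiducials.dn, fiducials.dp
    out[f"TSP_{suffix}"] = t(sp)
    out[f"TDN_{suffix}"] = t(dn)
    out[f"TDP_{suffix}"] = t(dp)
    out[f"TMSP_{suffix}"] = t(fiducials.msp)
    out[f"TIP_{suffix}"] = t(fiducials.ip)
    if sp is not None:
        out[f"ASP_{suffix}"] = sp.amplitude
        out[f"rise_time_{suffix}"] = sp.time
        out[f"decay_time_{suffix}"] = (n - 1) * dt - sp.time
    if dn is not None:
        out[f"ADN_{suffix}"] = dn.amplitude
        out[f"area_sys_{suffix}"] = trapezoid(x[: dn.index + 1], dx=dt)
        out[f"area_dia_{suffix}"] = trapezoid(x[dn.index :], dx=dt)
        if sp is not None:
            out[f"T1_{suffix}"] = dn.time - sp.time
    if dp is not None:
        out[f"ADP_{suffix}"] = dp.amplitude
        out[f"area_dp_end_{suffix}"] = trapezoid(x[dp.index :], dx=dt)
        if dn is not None:
            out[f"T2_{suffix}"] = dp.time - dn.time
    return out


def derivative_features(view: np.ndarray, fs: float, suffix: str) -> dict:
    """Extremes of the first and second finite-difference derivatives."""
    x = np.asarray(view, dtype=float)
    d1 = np.gradient(x) * fs
    d2 = np.gradient(d1) * fs
    amp = np.ptp(x)
    out = {
        f"d1max_{suffix}": d1.max(),
        f"d1min_{suffix}": d1.min(),
        f"t_d1max_{suffix}": np.argmax(d1) / fs,
        f"t_d1min_{suffix}": np.argmin(d1) / fs,
        f"d2max_{suffix}": d2.max(),
        f"d2min_{suffix}": d2.min(),
        f"t_d2max_{suffix}": np.argmax(d2) / fs,
        f"t_d2min_{suffix}": np.argmin(d2) / fs,
        f"d1max_ratio_{suffix}": d1.max() / amp if amp > 0 else np.nan,
        f"d2max_ratio_{suffix}": d2.max() / amp if amp > 0 else np.nan,
    }
    return out


def _spectral_features(x: np.ndarray, fs: float) -> dict:
    """Periodogram-based single-pulse frequency features (flat window)."""
    freqs, pxx = periodogram(x, fs=fs, window="boxcar", detrend=False)
    out = dict.fromkeys(
        ("SNR", "SINAD", "THD", "PSA", "SPL", "MeaF", "MedF", "OB", "HB", "band_power"),
        np.nan,
    )
    if pxx[1:].sum() <= 0:
        return out
    df = freqs[1] - freqs[0]
    p = pxx.copy()
    k0 = 1 + int(np.argmax(p[1:]))  # fundamental bin (DC excluded)
    out["PSA"] = p[k0]
    out["SPL"] = freqs[k0]
    psum = p[1:].sum()
    out["MeaF"] = float((freqs[1:] * p[1:]).sum() / psum)
    cum = np.cumsum(p[1:])
    out["MedF"] = float(freqs[1 + int(np.searchsorted(cum, 0.5 * cum[-1]))])
    # occupied bandwidth: central 99% of non-DC power
    lo_i = int(np.searchsorted(cum, 0.005 * cum[-1]))
    hi_i = int(np.searchsorted(cum, 0.995 * cum[-1]))
    out["OB"] = float(freqs[1 + hi_i] - freqs[1 + lo_i])
    # half-power bandwidth around the fundamental
    half = p[k0] / 2.0
    lo = k0
    while lo > 1 and p[lo] > half:
        lo -= 1
    hi = k0
    while hi < p.size - 1 and p[hi] > half:
        hi += 1
    out["HB"] = float((hi - lo) * df)
    out["band_power"] = float(psum * df)

    # harmonic bookkeeping: fundamental and harmonics occupy +/-1 bin
    def bins_around(k):
        return [j for j in (k - 1, k, k + 1) if 1 <= j < p.size]

    fund_bins = bins_around(k0)
    p_fund = p[fund_bins].sum()
    harm_bins: list[int] = []
    for h in range(2, 7):
        kh = k0 * h
        if kh >= p.size - 1:
            break
        harm_bins.extend(bins_around(kh))
    harm_bins = [b for b in harm_bins if b not in fund_bins]
    p_harm = p[harm_bins].sum()
    p_rest = psum - p_fund - p_harm
    with np.errstate(divide="ignore"):
        out["SINAD"] = float(10 * np.log10(p_fund / (psum - p_fund))) if psum > p_fund else np.inf
        out["SNR"] = float(10 * np.log10(p_fund / p_rest)) if p_rest > 0 else np.inf
        out["THD"] = float(10 * np.log10(p_harm / p_fund)) if p_harm > 0 else -np.inf
    return out


def waveform_stat_features(view: np.ndarray, fs: float, suffix: str) -> dict:
    """Time-domain shape statistics plus periodogram frequency features.

    The shape factor ``SF = RMS / mean(|x|)`` is the headline statistic: a
    pulse with a pronounced diastolic oscillation has a larger SF than a
    smooth decay, which is why SF on the enhanced view tracks waveform
    morphology so well.  Crest factor ``CF = peak / RMS``, impulse factor
    ``IF = peak / mean(|x|)`` and clearance factor
    ``ClF = peak / mean(sqrt(|x|))**2`` follow the standard definitions with
    ``peak = max(|x|)``.
    """
    x = np.asarray(view, dtype=float)
    out = {f"{nm}_{suffix}": np.nan for nm in _stat_names()}
    if x.size < 3 or not np.any(x != 0):
        return out
    absx = np.abs(x)
    rms = float(np.sqrt(np.mean(x**2)))
    mabs = float(absx.mean())
    peak = float(absx.max())
    msqrt = float(np.mean(np.sqrt(absx)))
    out[f"SF_{suffix}"] = rms / mabs if mabs > 0 else np.nan
    out[f"CF_{suffix}"] = peak / rms if rms > 0 else np.nan
    out[f"IF_{suffix}"] = peak / mabs if mabs > 0 else np.nan
    out[f"ClF_{suffix}"] = peak / msqrt**2 if msqrt > 0 else np.nan
    out[f"peak_{suffix}"] = peak
    out[f"RMS_{suffix}"] = rms
    out[f"mean_{suffix}"] = float(x.mean())
    out[f"std_{suffix}"] = float(x.std(ddof=1))
    out[f"skewness_{suffix}"] = float(skew(x, bias=True))
    out[f"kurtosis_{suffix}"] = float(kurtosis(x, bias=True))
    for k, v in _spectral_features(x, fs).items():
        out[f"{k}_{suffix}"] = v
    return out


def width_features(view_norm: np.ndarray, fs: float,
                   fractions=WIDTH_FRACTIONS) -> dict:
    """Pulse widths at fixed height fractions of the normalized pulse.

    Width at height ``h`` is the time between the first and last crossings
    of level ``h``, linearly interpolated between samples.
    """
    x = np.asarray(view_norm, dtype=float)
    out = {}
    for f in fractions:
        name = f"width{int(round(f * 100))}_xNORM"
        above = x >= f
        if not above.any():
            out[name] = np.nan
            continue
        first = int(np.argmax(above))
        last = int(x.size - 1 - np.argmax(above[::-1]))
        t_first = float(first)
        if first > 0:
            t_first = first - 1 + (f - x[first - 1]) / (x[first] - x[first - 1])
        t_last = float(last)
        if last < x.size - 1 and x[last + 1] != x[last]:
            t_last = last + (x[last] - f) / (x[last] - x[last + 1])
        out[name] = (t_last - t_first) / fs
    return out


def couple_features(pulses, fiducials_filt, fs: float) -> dict:
    """Consecutive-pulse interval features, averaged over a chunk's couples.

    ``p2pi`` is the SP-to-SP interval of a couple; ``tb1`` the onset-to-onset
    interval and ``tb2`` the SP-to-next-onset interval (both documented
    reconstructions); ``TP/p2pi`` and ``TDN/p2pi`` are the pulse-duration and
    notch-time fractions of the beat interval.  Couples with a missing SP (or
    DN for the notch ratio) are skipped; a single-pulse chunk gives NaNs.
    """
    out = dict.fromkeys(_COUPLE_NAMES, np.nan)
    if len(pulses) < 2:
        return out
    p2pi, tb1, tb2, tp_r, tdn_r = [], [], [], [], []
    for i in range(len(pulses) - 1):
        f0, f1 = fiducials_filt[i], fiducials_filt[i + 1]
        tb1.append((pulses[i + 1].onset - pulses[i].onset) / fs)
        if f0.sp is not None:
            tb2.append((pulses[i + 1].onset - (pulses[i].onset + f0.sp.index)) / fs)
        if f0.sp is None or f1.sp is None:
            continue
        interval = (pulses[i + 1].onset + f1.sp.index) - (pulses[i].onset + f0.sp.index)
        interval /= fs
        if interval <= 0:
            continue
        p2pi.append(interval)
        tp_r.append(pulses[i].n / fs / interval)
        if f0.dn is not None:
            tdn_r.append(f0.dn.time / interval)
    if p2pi:
        out["mean_p2pi"] = float(np.mean(p2pi))
        out["mean_TP_over_p2pi"] = float(np.mean(tp_r))
        if tdn_r:
            out["mean_TDN_over_p2pi"] = float(np.mean(tdn_r))
    if tb1:
        out["mean_tb1"] = float(np.mean(tb1))
    if tb2:
        out["mean_tb2"] = float(np.mean(tb2))
    return out


def chunk_fft_features(chunk_ppg_filt: np.ndarray, fs: float,
                       n_peaks: int = 4) -> dict:
    """Sixteen magnitude-spectrum features of a whole chunk's xFILT.

    The chunk spectrum is the unwindowed FFT magnitude.  ``PeakK``/``FreqK``
    are the amplitudes and frequencies of the first ``n_peaks`` spectral
    peaks in decreasing amplitude order; band areas integrate the magnitude
    spectrum over 0-2, 2-5 ("Area from 2 to 5"), 5-8 and 0-8 Hz; the rest
    are the spectral centroid, median frequency, total area and maximum of
    the magnitude spectrum.
    """
    x = np.asarray(chunk_ppg_filt, dtype=float)
    out = dict.fromkeys(_CHUNK_FFT_NAMES, np.nan)
    if x.size < 8 or np.ptp(x) == 0:
        return out
    mag = np.abs(np.fft.rfft(x)) / x.size
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    df = freqs[1] - freqs[0]
    m = mag.copy()
    m[0] = 0.0  # DC excluded from peak search
    pk, props = find_peaks(m, prominence=0.02 * m.max())
    order = np.argsort(m[pk])[::-1][:n_peaks]
    sel = pk[order]
    for i, k in enumerate(sel, start=1):
        out[f"Peak{i}"] = float(m[k])
        out[f"Freq{i}"] = float(freqs[k])
    for lo, hi, name in ((0, 2, "Area_0_2"), (2, 5, "Area_2_5"),
                         (5, 8, "Area_5_8"), (0, 8, "Area_0_8")):
        band = (freqs >= lo) & (freqs <= hi)
        out[name] = float(trapezoid(mag[band], dx=df)) if band.sum() > 1 else np.nan
    tot = m[1:].sum()
    if tot > 0:
        out["ChunkMeaF"] = float((freqs[1:] * m[1:]).sum() / tot)
        cum = np.cumsum(m[1:])
        out["ChunkMedF"] = float(freqs[1 + int(np.searchsorted(cum, 0.5 * cum[-1]))])
    out["ChunkSpecArea"] = float(trapezoid(mag, dx=df))
    out["ChunkSpecMax"] = float(m.max())
    return out


def chunk_raw_stats(chunk) -> dict:
    """Pre-Z-score chunk statistics recorded during preprocessing."""
    return {"raw_mean": chunk.raw_mean, "raw_std": chunk.raw_std}


def build_feature_table(chunk_results, catalog: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assemble the pulses-by-features table with SBP/DBP labels.

    ``chunk_results`` is an iterable of dicts with keys ``chunk_id``,
    ``pulses`` (list of PulseSegment), ``labels`` (list of PulseLabel),
    ``fiducials_filt``/``fiducials_modwt`` (per-pulse FiducialSet),
    ``chunk`` (the Chunk) and optionally ``record_id``.  One row per valid
    labeled pulse; chunk- and couple-scope features are broadcast within a
    chunk.  Label columns are never NaN (invalid labels are excluded
    upstream).
    """
    rows = []
    for res in chunk_results:
        chunk_obj = res["chunk"]
        fs = chunk_obj.fs
        pulses = res["pulses"]
        labels = res["labels"]
        ffilt = res["fiducials_filt"]
        fmodwt = res["fiducials_modwt"]
        shared = {}
        shared.update(couple_features(pulses, ffilt, fs))
        shared.update(chunk_fft_features(chunk_obj.ppg_filt, fs))
        shared.update(chunk_raw_stats(chunk_obj))
        for i, (p, lab) in enumerate(zip(pulses, labels)):
            if not lab.valid:
                continue
            row = {
                "record_id": res.get("record_id", 0),
                "chunk_id": res["chunk_id"],
                "pulse_id": i,
                "onset": p.onset,
                "sbp": lab.sbp,
                "dbp": lab.dbp,
            }
            row.update(pulse_point_features(p.view_filt, ffilt[i], fs, "xFILT"))
            row.update(derivative_features(p.view_filt, fs, "xFILT"))
            row.update(waveform_stat_features(p.view_filt, fs, "xFILT"))
            row.update(width_features(p.view_norm, fs))
            if p.view_modwt is not None and fmodwt[i] is not None:
                row.update(pulse_point_features(p.view_modwt, fmodwt[i], fs, "xMODWT"))
                row.update(derivative_features(p.view_modwt, fs, "xMODWT"))
                row.update(waveform_stat_features(p.view_modwt, fs, "xMODWT"))
            else:
                for nm in _point_names() + _deriv_names() + _stat_names():
                    row[f"{nm}_xMODWT"] = np.nan
            row.update(shared)
            rows.append(row)
    if not rows:
        cat = catalog if catalog is not None else feature_catalog()
        cols = ["record_id", "chunk_id", "pulse_id", "onset", "sbp", "dbp"] + list(cat["name"])
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)
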