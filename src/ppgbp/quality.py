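"""Chunk- and pulse-level quality gates.

Three gates protect the feature table from corrupt monitor data:

* an ABP beat-abnormality gate based on physiological-plausibility criteria
  (pressure ranges, pulse pressure, beat-to-beat jumps, inter-beat
  interval); the chunk is discarded when the abnormal-beat fraction exceeds
  a threshold (default 0.4);
* a regression-similarity gate: the chunk-mean coefficient of determination
  of three linear regressions (PPG pulse on its ABP pulse, PPG pulse on the
  previous PPG pulse, ABP pulse on the previous ABP pulse) must each reach a
  threshold (default 0.8);
* a per-pulse skewness signal-quality index: pulses whose xFILT skewness is
  negative are discarded (a healthy pulse has a fast upstroke and a long
  decay, hence non-negative skewness).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import skew

__all__ = [
    "AbnormalityCriteria",
    "QualityReport",
    "rsq",
    "linear_fit",
    "similarity_gate",
    "abnormality_gate",
    "skewness_sqi",
]


@dataclass
class AbnormalityCriteria:
    """Plausibility bounds for ABP beats (units: mmHg, seconds).

    A beat is abnormal when it violates any criterion; the chunk abnormality
    index is the abnormal-beat fraction.
    """

    sbp_max: float = 300.0
    dbp_min: float = 20.0
    map_range: tuple = (30.0, 200.0)
    pulse_pressure_min: float = 20.0
    ibi_range: tuple = (0.3, 2.4)
    sbp_jump_max: float = 20.0
    dbp_jump_max: float = 20.0


@dataclass
class QualityReport:
    """Gate outcomes for one chunk."""

    abnormality_index: float = np.nan
    pass_abnormality: bool = False
    rsq_ppg_abp: float = np.nan
    rsq_ppg_prev: float = np.nan
    rsq_abp_prev: float = np.nan
    pass_similarity: bool = False
    pulse_skewness: list = field(default_factory=list)
    per_pulse_pass_skewness: list = field(default_factory=list)
    reasons: list = field(default_factory=list)


def rsq(x: np.ndarray, yfit: np.ndarray) -> float:
    """Coefficient of determination of ``yfit`` against the pulse ``x``.

    ``rsq = 1 - SSresid / SStotal`` with ``SSresid = sum((x - yfit)**2)`` and
    ``SStotal = (N - 1) * var(x)`` (sample variance).  Undefined (NaN) for a
    constant ``x``; gates treat that as a failure.
    """
    x = np.asarray(x, dtype=float)
    yfit = np.asarray(yfit, dtype=float)
    if x.size != yfit.size or x.size < 2:
        raise ValueError("x and yfit must share a length of at least 2")
    ss_total = (x.size - 1) * float(np.var(x, ddof=1))
    if ss_total == 0:
        return np.nan
    ss_resid = float(np.sum((x - yfit) ** 2))
    return 1.0 - ss_resid / ss_total


def linear_fit(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Least-squares affine fit of pulse ``x`` on reference ``ref``.

    The reference is linearly resampled to the pulse length first (pulses
    are rarely the same length).  Returns the fitted samples.
    """
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if ref.size != x.size:
        ref = np.interp(np.linspace(0, 1, x.size), np.linspace(0, 1, ref.size), ref)
    if np.ptp(ref) == 0:
        return np.full_like(x, x.mean())
    slope, intercept = np.polyfit(ref, x, 1)
    return slope * ref + intercept


def _mean_rsq(pulses, refs) -> float:
    vals = []
    for x, ref in zip(pulses, refs):
        if x is None or ref is None or len(x) < 2:
            continue
        vals.append(rsq(x, linear_fit(x, ref)))
    if not vals:
        return np.nan
    return float(np.nanmean(vals))


def similarity_gate(ppg_pulses, abp_pulses, threshold: float = 0.8,
                    report: QualityReport | None = None):
    """Chunk-level regression-similarity test.

    ``ppg_pulses`` and ``abp_pulses`` are corresponding per-beat sample
    arrays (PPG cut at the ABP pulse bounds).  Computes the chunk means of
    the coefficient of determination for the three regressions and fails the
    chunk if any mean is below ``threshold`` (or if fewer than two beats are
    available).  Returns ``(passed, report)``.
    """
    report = report or QualityReport()
    if len(ppg_pulses) < 2 or len(abp_pulses) < 2:
        report.pass_similarity = False
        report.reasons.append("similarity: fewer than 2 pulses")
        return False, report
    report.rsq_ppg_abp = _mean_rsq(ppg_pulses, abp_pulses)
    report.rsq_ppg_prev = _mean_rsq(ppg_pulses[1:], ppg_pulses[:-1])
    report.rsq_abp_prev = _mean_rsq(abp_pulses[1:], abp_pulses[:-1])
    means = (report.rsq_ppg_abp, report.rsq_ppg_prev, report.rsq_abp_prev)
    passed = all(np.isfinite(m) and m >= threshold for m in means)
    if not passed:
        report.reasons.append(
            "similarity: mean rsq "
            f"(ppg~abp {means[0]:.3f}, ppg~prev {means[1]:.3f}, abp~prev {means[2]:.3f})"
            f" below {threshold:g}"
        )
    report.pass_similarity = passed
    return passed, report


def abnormality_gate(abp: np.ndarray, onsets, fs: float, threshold: float = 0.4,
                     criteria: AbnormalityCriteria | None = None,
                     report: QualityReport | None = None):
    """ABP beat-abnormality gate for one chunk.

    Beats are the half-open intervals between consecutive ``onsets``.  Per
    beat, SBP, DBP, mean pressure, pulse pressure, inter-beat interval and
    beat-to-beat SBP/DBP jumps are checked against ``criteria``; the
    abnormality index is the fraction of beats violating at least one
    criterion.  The chunk fails when the index exceeds ``threshold`` (or has
    no beats).  Returns ``(passed, index, report)``.
    """
    criteria = criteria or AbnormalityCriteria()
    report = report or QualityReport()
    abp = np.asarray(abp, dtype=float)
    onsets = np.asarray(onsets, dtype=int)
    if onsets.size < 2:
        report.pass_abnormality = False
        report.abnormality_index = 1.0
        report.reasons.append("abnormality: no beats")
        return False, 1.0, report

    sbps, dbps, maps_, pps, ibis = [], [], [], [], []
    for lo, hi in zip(onsets[:-1], onsets[1:]):
        seg = abp[lo:hi]
        sbps.append(seg.max())
        dbps.append(seg.min())
        maps_.append(seg.mean())
        pps.append(seg.max() - seg.min())
        ibis.append((hi - lo) / fs)

    abnormal = 0
    nb = len(sbps)
    for i in range(nb):
        bad = (
            sbps[i] > criteria.sbp_max
            or dbps[i] < criteria.dbp_min
            or not criteria.map_range[0] <= maps_[i] <= criteria.map_range[1]
            or pps[i] < criteria.pulse_pressure_min
            or not criteria.ibi_range[0] <= ibis[i] <= criteria.ibi_range[1]
        )
        if i > 0:
            bad = bad or abs(sbps[i] - sbps[i - 1]) > criteria.sbp_jump_max
            bad = bad or abs(dbps[i] - dbps[i - 1]) > criteria.dbp_jump_max
        abnormal += bool(bad)

    index = abnormal / nb
    passed = index <= threshold
    report.abnormality_index = index
    report.pass_abnormality = passed
    if not passed:
        report.reasons.append(f"abnormality index {index:.3f} > {threshold:g}")
    return passed, index, report


def skewness_sqi(pulse) -> tuple[float, bool]:
    """Per-pulse skewness signal-quality index on the xFILT view.

    Uses the bias-uncorrected sample third standardized moment; the pulse
    passes iff skewness is non-negative (an exactly symmetric amplitude
    distribution is a boundary pass, so the comparison carries a small
    numerical tolerance).  Zero-variance pulses fail.
    """
    x = np.asarray(getattr(pulse, "view_filt", pulse), dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return np.nan, False
    s = float(skew(x, bias=True))
    return s, s >= -1e-12
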