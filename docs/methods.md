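# Methods

This note documents the models, parameter choices and numerical decisions
behind `ppgbp`, and what the synthetic-data tests do and do not establish
about real recordings.

## Signal model and the synthetic generator

Each synthetic beat is a smooth kernel in beat-phase `u ∈ [0, 2)` (fraction
of the beat period): a systolic Gaussian lobe (center 0.20, width 0.075,
unit amplitude), a diastolic Gaussian lobe (center 0.47, width 0.11;
amplitude 0.32 when the diastolic peak is "visible", 0.14 when it is only
an inflection shoulder), and an exponential diastolic run-off
(amplitude 0.50, time constant 0.60 of the period) gated on after the
systolic rise and tapered smoothly to zero well inside the kernel support
so kernel truncation leaves no step. Overlapping kernels of consecutive
beats sum to a quasi-periodic waveform whose foot minimum before each
upstroke is well defined — the run-off gives the late diastole a realistic
negative slope, which is what keeps that minimum in place under baseline
wander. The ABP kernel shares the PPG kernel's lobe timing (so the
channels' cross-correlation peak sits at zero offset and the configured
`lag` is the only inter-channel delay) with a stronger dicrotic wave, and
is affinely rescaled per beat to `[DBP, SBP]` mmHg.

Generator defaults (chosen once as a realistic bedside operating point):
125 Hz sampling, 75 bpm with 3 % beat-period jitter and 5 % amplitude
jitter, additive white noise at 2 % of pulse amplitude, and sinusoidal
baseline wander at 0.1 Hz with amplitude 0.15 of the pulse (Mayer-wave /
respiration scale). The beat-period jitter matters beyond realism: it
breaks the periodicity that would otherwise make the cross-correlation lag
ambiguous modulo one beat.

**Ground truth** is defined on the *deterministic* waveform — kernels plus
drift, before stochastic noise — by locating its extrema on an 8×
oversampled grid (with a 0.1 %-of-range prominence floor to ignore
numerical micro-ripple) and rounding to the sample grid. Drift is part of
the truth because it is deterministic and genuinely moves the foot minima;
"noise-free" tests mean `noise_sd = 0`, not drift-free.

What the generator does **not** emulate: motion artifacts, sensor
saturation or disconnection, arrhythmic beats, pulse-shape drift within a
record, venous oscillations, and device-specific transfer functions.
Passing tests therefore establish the correctness of the algorithms under
clean-to-moderately-noisy quasi-periodic conditions, not clinical-grade
robustness.

## Preprocessing

The PPG conditioning chain is band-pass → Z-score → polynomial baseline
removal, in that order. Both filters are applied forward–backward
(zero-phase): fiducial *timing* is the object of study downstream, and a
causal application would bias every location by the group delay. The
band-pass is a second-order Butterworth, 0.5–8 Hz; the baseline fit is an
ordinary least-squares degree-4 polynomial on a [−1, 1]-scaled time axis
(conditioning of the Vandermonde system).

The ABP low-pass is an order-10 recursive filter fit to a magnitude
specification (unit gain to 8 Hz, stop-band above ≈14 Hz at fs = 125 Hz).
The design converts the magnitude spec to a minimum-phase complex target
via the real cepstrum and fits a rational transfer function by weighted
complex least squares with Sanathanan–Koerner iteration; poles are
reflected into the unit circle if needed and the gain is normalized to
unity at DC. The resulting response has ≈0.4 dB passband ripple and
≈−48 dB at 30 Hz.

Alignment standardizes both channels, evaluates the cross-correlation over
lags up to ±5 s, and breaks ties toward the smallest |lag|; positive lag
means the PPG trails the ABP, and the aligned outputs are the overlapping
portions after advancing the PPG.

## Onset detection

The slope sum function uses a trailing window of 0.128 s (16 samples at
125 Hz — the typical systolic upslope duration). Onset picking is
deliberately amplitude-scale-free: SSF peaks (minimum spacing = the 0.3-s
refractory period) are accepted when they exceed 0.6 × a running median of
recently accepted peak heights, seeded from the first 3 s and floored at
0.6 × the median of the upper half of all peak heights in the chunk (the
floor prevents a run of spurious small peaks from dragging the threshold
into the noise). Each accepted peak is walked back to the SSF upstroke
start and refined to the signal minimum in a ±8-sample window.

For the **ABP** the SSF runs on the recursive low-pass view. For the
**PPG** it runs on a gentle second-order 8-Hz zero-phase low-pass of the
raw channel rather than on `xFILT`: the 0.5-Hz high-pass edge of the
band-pass reshapes the slow inter-beat valley and can move the foot
minimum by up to ~10 samples at 40 bpm, while the low-pass view preserves
the baseline and hence the foot. The resulting onset bounds are then
applied to `xFILT` to cut the pulses. The first segment of every chunk is
discarded (possible partial pulse).

## Quality gates

* **Abnormality**: per ABP beat, seven plausibility criteria (SBP ≤ 300,
  DBP ≥ 20, mean pressure in [30, 200] mmHg, pulse pressure ≥ 20 mmHg,
  inter-beat interval in [0.3, 2.4] s, beat-to-beat SBP and DBP jumps
  ≤ 20 mmHg). A beat violating any criterion is abnormal; the chunk index
  is the abnormal-beat fraction and the chunk is discarded above 0.4.
* **Similarity**: PPG pulses are cut at the ABP beat bounds; each pulse is
  regressed (ordinary least squares, affine) on its ABP partner and on the
  previous pulse of its own channel, references linearly resampled to the
  pulse length. The coefficient of determination is
  `1 − SSresid/((N−1)·var)`; a chunk is discarded if any of the three
  chunk means falls below 0.8.
* **Skewness**: per-pulse biased sample skewness of `xFILT`; a pulse is
  discarded when negative (tolerance −1e−12 so an exactly symmetric
  amplitude distribution is a boundary pass). A healthy pulse — fast
  upstroke, long decay — spends most samples near its baseline and is
  right-skewed.
* **Physiological filter**: labels with SBP > 300 mmHg or DBP < 20 mmHg are
  dropped (SBP = interval maximum of the ABP re-segmented at PPG bounds,
  DBP = minimum after that peak within the interval).

## MODWT enhancement

The maximal overlap DWT is computed entirely in the Fourier domain: the
level-j transfer function is the base `sym4` filter DFT (rescaled by
`2^(−1/2)` per stage) sampled at `2^(j−1)·f mod N`, which is exactly
circular convolution with the à-trous upsampled filter. Boundary handling
is therefore periodic; coefficients are time-aligned with the input; the
transform is linear, shift-equivariant and energy-conserving, and
inversion runs the pyramid backwards with conjugate transfer functions.
Decomposition depth is `⌊log2 N⌋` (floor: the ceiling would exceed the
maximal meaningful level for non-powers of two).

The enhanced pulse keeps detail levels {4, 5} only — at 125 Hz, the
≈2–7.8 Hz band, which concentrates the pulse's oscillatory energy while
discarding the fundamental envelope. Pulses shorter than 32 samples
(level 5 undefined) are flagged not-enhanceable and excluded from
MODWT-view features rather than zero-padded, since padding distorts
fiducial timing.

One systematic of this view is worth stating plainly: dropping the
fundamental retards the diastolic bump, so the `xMODWT` diastolic peak
sits a stable ≈10 samples (≈80 ms) later than the raw-waveform DP on the
synthetic corpus, with small scatter. The notch and systolic peak are not
affected (≤ 2–3 samples). This is why the inter-detector DP error
statistics are dominated by a mean offset rather than noise, and it is the
price of making the DP visible at all in pulses where the plain waveform
shows no second maximum (0 % visibility on `xFILT` vs 100 % on `xMODWT`
for generator pulses with a hidden diastolic lobe).

## Fiducial detectors

*Derivative detector* (on `xFILT`): MSP = first-derivative argmax; SP =
first downward zero-crossing of the first derivative after MSP; DN = first
signal minimum after SP, or, when the notch is not a minimum, the first
prominent second-derivative maximum after SP; DP = first signal maximum
after DN, or the second-derivative downward zero-crossing after DN when no
maximum exists; IP = first second-derivative sign change between DN and
DP. Derivatives are central finite differences; no additional smoothing.

*Wavelet detector* (on `xMODWT`): SP = first local maximum with prominence
≥ 5 % of the signal range (the floor ignores small ringing near the
circular boundary); DN = first strict minimum after SP; DP = first strict
maximum after DN, deliberately without a prominence filter — the
enhancement's purpose is that these are plain extrema, however small.

Detector comparison reports signed differences (derivative minus wavelet)
in seconds on the sample grid (8-ms resolution at 125 Hz), with mean and
SD per point. Local extrema use strict comparisons with plateau ties
resolved leftward. DP-visibility rates use a 1 %-of-range prominence
floor, which cleanly separates shoulder-only pulses from true double
peaks on both clean and mildly noisy data.

## Features

All areas use the trapezoidal rule with `dt = 1/fs`; times are measured
from the pulse onset. Widths at 10/25/33/50/66/75 % height are computed on
the per-pulse [0, 1]-normalized view with linear interpolation between
samples, making them invariant to affine amplitude transforms of `xFILT`.
Per-pulse spectra use an unwindowed periodogram (pulses are short; a taper
would cost more resolution than it buys leakage suppression); chunk
spectra use the unwindowed FFT magnitude. SNR/SINAD/THD attribute ±1 bin
around the fundamental and its harmonics. The couple features `tb1`
(onset-to-onset) and `tb2` (SP-to-next-onset) are documented
reconstructions of consecutive-pulse interval definitions; `p2pi` is the
SP-to-SP interval, and couple values are averaged over a chunk's couples
and broadcast to its pulses, as are all chunk-scope features. The chunk
`raw_mean`/`raw_std` are recorded after denoising and before Z-scoring.

The catalog (~120 named features) covers every feature class the pipeline
motivates — fiducial-anchored, derivative, statistical, spectral, couple
and chunk scope, on both `xFILT` and `xMODWT` — without claiming any
particular total; the registry (`feature_catalog()`) carries each
feature's view, scope and novelty tag.

## Feature ranking

* **CFS**: greedy forward search on the merit
  `k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)` (mean absolute Pearson correlations);
  the search stops when no candidate improves the merit, and unselected
  features are ranked by the merit they would add to the final set. Note
  an arithmetic property: a second, perfectly redundant copy of an
  already-selected feature leaves the merit unchanged (and a noisy copy
  changes it only marginally) — the redundancy penalty appears relative
  to an equally-relevant *uncorrelated* candidate, whose merit would be
  `2·r̄_cf/√2`.
* **RReliefF**: regression variant with range-normalized features and
  label, all instances visited in order by default (fully deterministic;
  seeded subsampling optional), 10 nearest neighbors by Manhattan
  distance, influence decaying as `exp(−(rank/σ)²)` with `σ = k/3`.
  Labels are used as-is (mmHg); no label binning.
* **MRMR**: relevance = mutual information between equal-frequency
  10-bin discretized feature and label (F-statistic variant available),
  redundancy = mean pairwise MI with the selected set, difference
  objective by default.

All three are invariant to affine feature rescaling (correlation, range
normalization, quantile binning respectively); ties break
lexicographically by feature name for determinism.

## Problem sizes

The test suite and the acceptance script size their corpora for a
single-CPU run: 30–150 s records, a 1000-pulse fiducial corpus, 50
random-lag alignment trials, seven heart rates spanning 40–160 bpm for
onset detection, and 100 seeded 500×50 tables for ranking recovery. These
sizes give binomial noise well below the margins being asserted (e.g. a
≥95 % recovery criterion checked at 100 % over 100 runs).

## Known limitations

* The derivative detector's DN/IP rules are documented reconstructions of
  derivative-based detection practice; the detector interface accepts
  replacements.
* The wavelet-view DP offset (above) means DP *timing* features from
  `xMODWT` carry a view-specific bias; they remain informative as
  features but are not interchangeable with `xFILT` DP timings.
* The abnormality criteria bounds are configurable defaults from the
  beat-quality literature, not patient-calibrated limits.
* Ranking scores are comparable within a method, not across methods.
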