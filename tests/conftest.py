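"""Shared fixtures: synthetic records and segmented pulse corpora.

Everything is generated at test time from seeded configurations; the
session-scoped corpora are reused across test modules to keep the suite
fast.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.signal import butter, sosfiltfilt

from ppgbp import SynthConfig, generate_record
from ppgbp.modwt import enhance_pulse, is_enhanceable
from ppgbp.preprocessing import preprocess_record
from ppgbp import segmentation as seg


def clean_config(**kw) -> SynthConfig:
    """Noise-free generator settings (drift and jitter stay at defaults)."""
    base = dict(noise_sd=0.0)
    base.update(kw)
    return SynthConfig(**base)


def segmentation_view(x: np.ndarray, fs: float) -> np.ndarray:
    sos = butter(2, 8.0, btype="lowpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def segmented_pulses(record, truth, match_tol: int = 3):
    """Segment a record chunk-wise and pair each pulse with its truth beat.

    Returns a list of dicts with the pulse, its truth beat, the absolute
    onset offset and the enhanced view (None when not enhanceable).
    """
    chunks = preprocess_record(record)
    params = seg.SlopeSumParams(fs=record.fs)
    out = []
    for c in chunks:
        raw = record.ppg[c.start_index : c.start_index + c.n]
        view = segmentation_view(raw, record.fs)
        onsets = seg.detect_onsets(seg.slope_sum(view, params), params, signal=raw)
        for p in seg.segment_ppg(c, onsets):
            d = np.abs(truth.onsets - (p.onset + c.start_index))
            i = int(np.argmin(d))
            if d[i] > match_tol:
                continue
            xm = enhance_pulse(p.view_filt) if is_enhanceable(p.n) else None
            out.append(dict(pulse=p, beat=truth.beats[i], offset=c.start_index, xmodwt=xm))
    return out


@pytest.fixture(scope="session")
def visible_corpus():
    """Noise-free corpus with every diastolic peak distinct (~140 pulses)."""
    rec, tr = generate_record(clean_config(duration=120.0, dp_visibility=1.0, seed=11))
    return rec, tr, segmented_pulses(rec, tr)


@pytest.fixture(scope="session")
def hidden_corpus():
    """Noise-free corpus in which no pulse shows a distinct diastolic peak."""
    rec, tr = generate_record(clean_config(duration=120.0, dp_visibility=0.0, seed=12))
    return rec, tr, segmented_pulses(rec, tr)


@pytest.fixture(scope="session")
def default_record():
    """Default (mildly noisy) one-minute record."""
    return generate_record(SynthConfig(duration=60.0, seed=2))
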