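"""Feature catalog coverage and closed-form checks for the extractors."""

import numpy as np
import pytest

from ppgbp.features import (
    WIDTH_FRACTIONS,
    build_feature_table,
    chunk_fft_features,
    chunk_raw_stats,
    couple_features,
    derivative_features,
    feature_catalog,
    pulse_point_features,
    waveform_stat_features,
    width_features,
)
from ppgbp.fiducials import FiducialPoint, FiducialSet

FS = 125.0


def _fidset(sp=None, dn=None, dp=None, msp=None, ip=None):
    def mk(i, amp=1.0):
        return None if i is None else FiducialPoint(i, i / FS, amp)

    return FiducialSet(sp=mk(sp), dn=mk(dn), dp=mk(dp), msp=mk(msp), ip=mk(ip), fs=FS)


class TestCatalog:
    def test_every_named_feature_of_the_catalog_is_registered(self):
        cat = feature_catalog()
        base = set(cat["name"])
        for required in ["TDN", "TDP", "TP", "T1", "T2", "ADP", "ADN", "SF", "ClF",
                        "SINAD", "SPL", "PSA", "OB", "MeaF", "MedF", "HB"]:
            assert any(n.startswith(required + "_") for n in base), required
        for literal in ["Peak1", "Freq1", "Freq2", "Area_2_5", "mean_tb1", "mean_tb2",
                        "mean_TP_over_p2pi", "mean_TDN_over_p2pi", "raw_mean", "raw_std"]:
            assert literal in base, literal
        assert any(n.startswith("area_dp_end_") for n in base)

    def test_names_unique_and_scopes_valid(self):
        cat = feature_catalog()
        assert cat["name"].is_unique
        assert set(cat["scope"]) == {"pulse", "couple", "chunk"}
        assert set(cat["view"]) <= {"xFILT", "xNORM", "xMODWT", "raw-chunk"}
        assert {"known", "proposed"} == set(cat["novelty"])


class TestPointFeatures:
    def test_times_match_fiducial_differences(self):
        # SP at 0.2 s, DN at 0.4 s, DP at 0.5 s, pulse 1.0 s
        n = int(FS)
        x = np.zeros(n)
        f = _fidset(sp=int(0.2 * FS), dn=int(0.4 * FS), dp=int(0.5 * FS))
        out = pulse_point_features(x, f, FS, "xFILT")
        assert out["T1_xFILT"] == pytest.approx(0.2)
        assert out["T2_xFILT"] == pytest.approx(0.1, abs=1.01 / FS)
        assert out["TP_xFILT"] == pytest.approx(1.0)
        assert out["rise_time_xFILT"] == pytest.approx(0.2)

    def test_areas_match_brute_force_riemann_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        f = _fidset(sp=20, dn=40, dp=55)
        out = pulse_point_features(x, f, FS, "xFILT")
        dt = 1 / FS
        brute_total = np.sum((x[:-1] + x[1:]) / 2) * dt
        assert out["area_total_xFILT"] == pytest.approx(brute_total, abs=1e-9)
        brute_dp_end = np.sum((x[55:-1] + x[56:]) / 2) * dt
        assert out["area_dp_end_xFILT"] == pytest.approx(brute_dp_end, abs=1e-9)
        assert out["area_sys_xFILT"] + out["area_dia_xFILT"] == \
            pytest.approx(brute_total, abs=1e-9)

    def test_missing_fiducials_mask_dependent_features(self):
        out = pulse_point_features(np.ones(50), _fidset(), FS, "xFILT")
        for nm in ("TSP", "TDN", "T1", "T2", "ASP", "area_sys"):
            assert np.isnan(out[f"{nm}_xFILT"])
        assert np.isfinite(out["TP_xFILT"])


class TestDerivativeFeatures:
    def test_ramp_has_constant_first_derivative(self):
        a = 3.0
        t = np.arange(200) / FS
        out = derivative_features(a * t, FS, "xFILT")
        assert out["d1max_xFILT"] == pytest.approx(a, rel=1e-6)
        assert abs(out["d2max_xFILT"]) < 1e-6

    def test_sinusoid_first_derivative_maximum_is_omega(self):
        f0 = 2.0
        t = np.arange(int(4 * FS)) / FS
        out = derivative_features(np.sin(2 * np.pi * f0 * t), FS, "xFILT")
        assert out["d1max_xFILT"] == pytest.approx(2 * np.pi * f0, rel=5e-3)

    def test_time_reversal_swaps_and_negates_first_derivative_extremes(self):
        x = np.random.default_rng(1).normal(size=300).cumsum()
        fwd = derivative_features(x, FS, "v")
        rev = derivative_features(x[::-1], FS, "v")
        assert fwd["d1max_v"] == pytest.approx(-rev["d1min_v"], rel=1e-9)
        assert fwd["d1min_v"] == pytest.approx(-rev["d1max_v"], rel=1e-9)


class TestWaveformStats:
    def test_constant_magnitude_signal_has_unit_shape_and_crest_factor(self):
        x = 3.0 * np.array([1.0, -1.0] * 100)
        out = waveform_stat_features(x, FS, "v")
        assert out["SF_v"] == pytest.approx(1.0)
        assert out["CF_v"] == pytest.approx(1.0)
        assert out["IF_v"] == pytest.approx(1.0)

    def test_unit_sinusoid_shape_factor_closed_form(self):
        """SF of a sinusoid = (1/sqrt(2)) / (2/pi) = pi / (2 sqrt(2))."""
        t = np.arange(int(8 * FS)) / FS
        x = np.sin(2 * np.pi * 2.5 * t)
        out = waveform_stat_features(x, FS, "v")
        assert out["SF_v"] == pytest.approx(np.pi / (2 * np.sqrt(2)), rel=2e-3)

    def test_pure_tone_spectral_features(self):
        f0 = 5.0
        t = np.arange(int(8 * FS)) / FS
        out = waveform_stat_features(np.sin(2 * np.pi * f0 * t), FS, "v")
        df = 1 / 8.0  # spectral bin width for an 8 s pulse
        assert abs(out["SPL_v"] - f0) <= df
        assert abs(out["MeaF_v"] - f0) <= 2 * df
        assert abs(out["MedF_v"] - f0) <= df
        assert out["SINAD_v"] > 20.0

    def test_amplitude_scaling_moves_amplitude_features_linearly(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=120)
        a, b = waveform_stat_features(x, FS, "v"), waveform_stat_features(4 * x, FS, "v")
        assert b["RMS_v"] == pytest.approx(4 * a["RMS_v"])
        assert b["peak_v"] == pytest.approx(4 * a["peak_v"])
        # shape statistics are scale-invariant
        for nm in ("SF_v", "CF_v", "ClF_v", "skewness_v"):
            assert b[nm] == pytest.approx(a[nm], rel=1e-9)


class TestWidths:
    def test_triangle_width_at_half_height_is_half_base(self):
        n = 101
        x = np.concatenate([np.linspace(0, 1, 51), np.linspace(1, 0, 51)[1:]])
        out = width_features(x, FS)
        assert out["width50_xNORM"] == pytest.approx(0.5 * (n - 1) / FS, rel=0.02)

    def test_widths_decrease_with_height(self):
        x = np.sin(np.linspace(0, np.pi, 80)) ** 2
        out = width_features(x, FS)
        ws = [out[f"width{int(round(f*100))}_xNORM"] for f in WIDTH_FRACTIONS]
        assert all(a >= b for a, b in zip(ws[:-1], ws[1:]))

    def test_width_invariant_under_affine_amplitude_transform_of_xfilt(self):
        # widths are computed on the min-max normalized view, which is
        # unchanged by affine transforms of the underlying pulse
        x = np.sin(np.linspace(0, np.pi, 60)) ** 2
        y = -3.0 * x + 7.0
        ynorm = (y - y.min()) / np.ptp(y)
        out_x = width_features(x, FS)
        out_y = width_features(ynorm, FS)
        assert out_y["width50_xNORM"] == pytest.approx(
            width_features(1 - x, FS)["width50_xNORM"])
        assert out_x.keys() == out_y.keys()


class _StubPulse:
    def __init__(self, onset, n):
        self.onset, self.end, self.n = onset, onset + n, n


class TestCoupleFeatures:
    def test_periodic_chunk_intervals(self):
        """60 bpm gapless segmentation: p2pi = tb1 = 1 s, TP/p2pi = 1."""
        period = int(FS)
        pulses = [_StubPulse(k * period, period) for k in range(10)]
        fids = [_fidset(sp=25, dn=45) for _ in pulses]
        out = couple_features(pulses, fids, FS)
        assert out["mean_p2pi"] == pytest.approx(1.0)
        assert out["mean_tb1"] == pytest.approx(1.0)
        assert out["mean_TP_over_p2pi"] == pytest.approx(1.0)
        assert out["mean_tb2"] == pytest.approx(1.0 - 25 / FS)
        assert out["mean_TDN_over_p2pi"] == pytest.approx(45 / FS / 1.0)

    def test_averaging_matches_brute_force_mean(self):
        rng = np.random.default_rng(3)
        onsets = np.cumsum(rng.integers(90, 140, size=8))
        pulses = [_StubPulse(int(o), int(n)) for o, n in zip(onsets[:-1], np.diff(onsets))]
        fids = [_fidset(sp=20, dn=40) for _ in pulses]
        out = couple_features(pulses, fids, FS)
        brute = np.mean([(pulses[i + 1].onset + 20 - pulses[i].onset - 20) / FS
                         for i in range(len(pulses) - 1)])
        assert out["mean_p2pi"] == pytest.approx(brute)

    def test_single_pulse_chunk_masked(self):
        out = couple_features([_StubPulse(0, 100)], [_fidset(sp=20)], FS)
        assert all(np.isnan(v) for v in out.values())


class TestChunkFft:
    def test_pure_tone_frequency_within_one_bin(self):
        n = int(30 * FS)
        t = np.arange(n) / FS
        out = chunk_fft_features(np.sin(2 * np.pi * 1.2 * t), FS)
        assert abs(out["Freq1"] - 1.2) <= FS / n

    def test_two_tone_peak_ordering(self):
        n = int(30 * FS)
        t = np.arange(n) / FS
        x = np.sin(2 * np.pi * 1.2 * t) + 0.5 * np.sin(2 * np.pi * 2.4 * t)
        out = chunk_fft_features(x, FS)
        assert abs(out["Freq1"] - 1.2) <= FS / n
        assert abs(out["Freq2"] - 2.4) <= FS / n
        assert out["Peak1"] > out["Peak2"]

    def test_band_areas_decompose_and_match_quadrature_oracle(self):
        from scipy.integrate import trapezoid

        rng = np.random.default_rng(4)
        x = rng.normal(size=int(30 * FS))
        out = chunk_fft_features(x, FS)
        mag = np.abs(np.fft.rfft(x)) / x.size
        freqs = np.fft.rfftfreq(x.size, 1 / FS)
        sel = (freqs >= 2) & (freqs <= 5)
        oracle = trapezoid(mag[sel], dx=freqs[1] - freqs[0])
        assert out["Area_2_5"] == pytest.approx(oracle, rel=1e-9)
        assert out["Area_0_8"] == pytest.approx(
            out["Area_0_2"] + out["Area_2_5"] + out["Area_5_8"], rel=0.02)

    def test_short_chunk_masked(self):
        out = chunk_fft_features(np.zeros(4), FS)
        assert all(np.isnan(v) for v in out.values())


class TestRawStats:
    def test_stats_are_read_back_and_shift_behaves(self):
        class C:
            raw_mean, raw_std = 1.5, 0.7

        out = chunk_raw_stats(C())
        assert out == {"raw_mean": 1.5, "raw_std": 0.7}

    def test_mean_shift_and_std_invariance_at_the_source(self):
        from ppgbp.preprocessing import zscore

        x = np.random.default_rng(5).normal(size=1000)
        assert (x + 10).mean() == pytest.approx(x.mean() + 10)
        assert (x + 10).std(ddof=1) == pytest.approx(x.std(ddof=1))
        assert np.allclose(zscore(x + 10), zscore(x))


class TestBuildTable:
    def test_row_count_equals_valid_pulses_and_chunk_columns_are_constant(self, default_record):
        from ppgbp import run_pipeline

        rec, _ = default_record
        res = run_pipeline(rec)
        n_valid = sum(len(cr["pulses"]) for cr in res.chunk_results)
        assert len(res.feature_table) == n_valid
        assert not res.feature_table["sbp"].isna().any()
        assert not res.feature_table["dbp"].isna().any()
        for col in ("Peak1", "raw_mean", "mean_p2pi"):
            grp = res.feature_table.groupby("chunk_id")[col].nunique(dropna=False)
            assert (grp <= 1).all()

    def test_empty_input_gives_headered_empty_table(self):
        t = build_feature_table([])
        assert len(t) == 0
        assert "sbp" in t.columns and "dbp" in t.columns
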