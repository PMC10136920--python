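import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import apneaflow as af
from apneaflow.preprocess import FilterDesignError, _odd_window

from oracles import naive_running_median


def _rec(x, fs=100.0):
    return af.PPGRecord(np.asarray(x, dtype=float), fs)


class TestBaselineRemoval:
    def test_constant_signal_maps_to_zero(self):
        out = af.remove_baseline(_rec(np.full(1000, 3.7)))
        assert np.allclose(out.samples, 0.0)

    def test_slow_ramp_is_removed_from_pulse_train(self):
        fs = 100.0
        t = np.arange(6000) / fs
        ramp = 0.5 * t
        pulses = np.zeros(t.size)
        for tb in np.arange(0.5, 60.0, 1.0):
            pulses += np.exp(-0.5 * ((t - tb) / 0.08) ** 2)
        out = af.remove_baseline(_rec(ramp + pulses, fs))
        corr = np.corrcoef(out.samples, ramp)[0, 1]
        assert abs(corr) < 0.1

    def test_sine_matches_naive_oracle_exactly(self):
        fs = 100.0
        x = np.sin(2 * np.pi * 1.0 * np.arange(800) / fs)
        out = af.remove_baseline(_rec(x, fs), window_s=2.5)
        size = _odd_window(2.5, fs)
        expected = x - naive_running_median(x, size)
        assert np.array_equal(out.samples, expected)

    def test_too_short_input_raises(self):
        with pytest.raises(ValueError):
            af.remove_baseline(_rec(np.zeros(100)))  # < 2.5 s at 100 Hz


class TestMedianDenoise:
    def test_isolated_impulse_is_removed(self):
        x = np.full(600, 1.0)
        x[300] = 50.0
        out = af.median_denoise(_rec(x), window_s=0.05)
        assert np.allclose(out.samples, 1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000),
           st.integers(min_value=50, max_value=500))
    def test_matches_naive_sort_oracle(self, seed, length):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(length)
        fs = 20.0  # window 2N = 40 samples -> odd-adjusted 41
        out = af.median_denoise(_rec(x, fs), window_s=2.0)
        expected = naive_running_median(x, _odd_window(2.0, fs))
        assert np.array_equal(out.samples, expected)

    def test_monotone_input_stays_monotone(self):
        x = np.linspace(0, 1, 500)
        out = af.median_denoise(_rec(x), window_s=0.5)
        assert np.all(np.diff(out.samples) >= 0)

    def test_too_short_input_raises(self):
        with pytest.raises(ValueError):
            af.median_denoise(_rec(np.zeros(100)), window_s=2.0)


class TestLowpassDesign:
    def test_design_is_deterministic(self):
        d1 = af.design_lowpass(100.0)
        d2 = af.design_lowpass(100.0)
        assert np.array_equal(d1.sos, d2.sos)
        assert d1.stopband_edge_hz == d2.stopband_edge_hz

    def test_infeasible_spec_raises(self):
        with pytest.raises(FilterDesignError):
            af.design_lowpass(100.0, order=0)

    def test_cutoff_must_be_below_nyquist(self):
        with pytest.raises(FilterDesignError):
            af.design_lowpass(8.0, cutoff_hz=4.8)


class TestApplyLowpass:
    def test_output_shorter_by_half_order(self):
        design = af.design_lowpass(100.0)
        rec = _rec(np.random.default_rng(0).standard_normal(1000))
        out = af.apply_lowpass(rec, design)
        assert out.n_samples == 1000 - design.order // 2

    def test_dc_preserved_within_passband_ripple(self):
        design = af.design_lowpass(100.0)
        out = af.apply_lowpass(_rec(np.full(2000, 2.0)), design)
        ripple_lin = 10 ** (design.passband_ripple_db / 20.0)
        assert abs(out.samples[-1] - 2.0) <= 2.0 * (ripple_lin - 1) + 1e-6

    def test_20hz_tone_attenuated_to_stopband_spec(self):
        fs = 100.0
        design = af.design_lowpass(fs)
        t = np.arange(8000) / fs
        out = af.apply_lowpass(_rec(np.sin(2 * np.pi * 20.0 * t), fs), design)
        residual = np.abs(out.samples[4000:]).max()
        assert residual <= 10 ** (-design.stopband_atten_db / 20.0)

    def test_sampling_rate_mismatch_raises(self):
        design = af.design_lowpass(100.0)
        with pytest.raises(ValueError):
            af.apply_lowpass(_rec(np.zeros(500), fs=200.0), design)


class TestSnr:
    @pytest.mark.parametrize("ps, pn, expected", [
        (1.0, 1.0, 0.0),
        (100.0, 1.0, 20.0),
        (10 ** 6.149, 1.0, 61.49),
    ])
    def test_log_ratio(self, ps, pn, expected):
        assert af.compute_snr(ps, pn) == pytest.approx(expected)

    def test_nonpositive_power_raises(self):
        with pytest.raises(ValueError):
            af.compute_snr(0.0, 1.0)


class TestWindowing:
    def test_120s_record_gives_61_windows(self):
        rec = _rec(np.zeros(12000))
        assert len(af.segment_windows(rec)) == 61

    def test_60s_record_gives_one_window(self):
        assert len(af.segment_windows(_rec(np.zeros(6000)))) == 1

    def test_59s_record_raises(self):
        with pytest.raises(ValueError):
            af.segment_windows(_rec(np.zeros(5900)))

    def test_window_takes_label_of_majority_minute(self):
        rec = _rec(np.zeros(12000))
        windows = af.segment_windows(rec, labels=[False, True])
        by_start = {w.start_s: w.label for w in windows}
        assert by_start[0.0] is False
        assert by_start[29.0] is False   # 31 s in minute 0
        assert by_start[30.0] is False   # tie -> earlier minute
        assert by_start[31.0] is True    # 31 s in minute 1
        assert by_start[60.0] is True

    def test_windowing_commutes_with_filtering(self):
        rng = np.random.default_rng(1)
        rec = _rec(rng.standard_normal(13000))
        design = af.design_lowpass(100.0)
        filtered = af.apply_lowpass(rec, design)
        windows = af.segment_windows(filtered, step_s=10.0)
        for w in windows:
            start = int(w.start_s * 100)
            assert np.array_equal(w.samples,
                                  filtered.samples[start:start + 6000])
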