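import numpy as np
import pytest

import apneaflow as af
from apneaflow.peaks import REFRACTORY_S, ThresholdPair, adaptive_thresholds

from conftest import match_peaks


def _pulse_record(duration_s=60.0, hr=60, sd_ms=0, seed=0, **noise):
    cfg = af.SynthConfig(duration_s=duration_s, base_heart_rate_bpm=hr,
                         hr_variability_sd_ms=sd_ms, seed=seed, **noise)
    return af.generate_ppg(cfg)


class TestWaveletScale3:
    def test_constant_input_gives_zero_coefficients(self):
        rec = af.PPGRecord(np.full(500, 4.2), 100.0)
        dec = af.wavelet_scale3(rec)
        assert np.allclose(dec.coefficients, 0.0, atol=1e-12)
        assert dec.coefficients.size == 500

    def test_slow_ramp_gives_small_constant_response(self):
        rec = af.PPGRecord(np.linspace(0, 1, 2000), 100.0)
        dec = af.wavelet_scale3(rec)
        interior = dec.coefficients[100:-100]
        assert np.ptp(interior) < 1e-6

    def test_single_pulse_yields_straddling_maxima_pair(self):
        t = np.arange(600) / 100.0
        x = np.exp(-0.5 * ((t - 3.0) / 0.08) ** 2)
        dec = af.wavelet_scale3(af.PPGRecord(x, 100.0))
        w = dec.coefficients
        peak = 300
        p = int(np.argmax(w))
        n = int(np.argmin(w))
        assert p < peak < n
        # zero-crossing between the pair sits on the pulse peak
        seg = w[p:n + 1]
        k = p + int(np.nonzero((seg[:-1] >= 0) & (seg[1:] < 0))[0][0])
        assert abs(k - peak) <= 2

    def test_too_short_input_raises(self):
        with pytest.raises(ValueError):
            af.wavelet_scale3(af.PPGRecord(np.zeros(10), 100.0))


class TestMaximaPairs:
    def test_single_above_threshold_pair_found(self):
        w = np.array([0, 1, 3, 1, 0, -1, -3, -1, 0], dtype=float)
        dec = af.WaveletDecomposition(w, 8, 0, 100.0)
        pairs = af.find_maxima_pairs(dec, ThresholdPair(2.0, -2.0))
        assert pairs == [(2, 6)]

    def test_sub_threshold_extrema_ignored(self):
        w = np.array([0, 1, 0, -1, 0], dtype=float)
        dec = af.WaveletDecomposition(w, 8, 0, 100.0)
        assert af.find_maxima_pairs(dec, ThresholdPair(2.0, -2.0)) == []

    def test_positive_orphan_removed(self):
        w = np.array([0, 3, 0, 0.5, 0], dtype=float)
        dec = af.WaveletDecomposition(w, 8, 0, 100.0)
        assert af.find_maxima_pairs(dec, ThresholdPair(2.0, -2.0)) == []

    def test_non_monotone_path_rejected(self):
        w = np.array([0, 3, -0.5, 2, 0, -3, 0], dtype=float)
        dec = af.WaveletDecomposition(w, 8, 0, 100.0)
        assert af.find_maxima_pairs(dec, ThresholdPair(2.0, -2.0)) == []

    def test_lowering_thresholds_never_loses_pairs(self):
        rng = np.random.default_rng(0)
        rec, _ = _pulse_record(duration_s=30, sd_ms=30, seed=2,
                               noise_emg_amp=0.1)
        dec = af.wavelet_scale3(rec)
        w = dec.coefficients
        scale = float(np.abs(w).max())
        counts = []
        for frac in (0.5, 0.4, 0.3, 0.2, 0.1):
            thr = ThresholdPair(frac * scale, -frac * scale)
            counts.append(len(af.find_maxima_pairs(dec, thr)))
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestLocatePeaks:
    def test_crossing_bracketed_between_samples(self):
        w = np.array([0.0, 3.0, 1.0, -1.0, -3.0, 0.0])
        dec = af.WaveletDecomposition(w, 8, 0, 100.0)
        out = af.locate_peaks([(1, 4)], dec)
        # linear interpolation between samples 2 (+1) and 3 (-1) -> 2.5
        assert out.tolist() in ([2], [3])

    def test_symmetric_pair_crosses_at_midpoint(self):
        w = np.array([0.0, 4.0, 2.0, 0.0, -2.0, -4.0, 0.0])
        dec = af.WaveletDecomposition(w, 8, 0, 100.0)
        assert af.locate_peaks([(1, 5)], dec).tolist() == [3]

    def test_pair_without_sign_change_skipped(self):
        w = np.array([0.0, 3.0, 1.0, 0.5, 0.2, 0.1, 0.0])
        dec = af.WaveletDecomposition(w, 8, 0, 100.0)
        assert af.locate_peaks([(1, 5)], dec).size == 0


class TestRefractory:
    def test_candidate_within_200ms_suppressed(self):
        fs = 1000.0
        train = af.apply_refractory([0, 150, 900], fs)
        assert train.peak_indices.tolist() == [0, 900]

    def test_spacing_at_least_200ms_unchanged(self):
        fs = 1000.0
        cands = [0, 200, 450, 700]
        train = af.apply_refractory(cands, fs)
        assert train.peak_indices.tolist() == cands

    def test_empty_candidates_give_empty_train(self):
        train = af.apply_refractory([], 100.0)
        assert train.n_peaks == 0


class TestRecovery:
    def _detection(self):
        rec, truth = _pulse_record(duration_s=60)
        dec = af.wavelet_scale3(rec)
        w = dec.coefficients
        thp, thn = adaptive_thresholds(w, 100.0)
        thr = ThresholdPair(float(thp[0]), float(thn[0]))
        return rec, truth, dec, thr

    def test_deleted_peak_is_recovered(self):
        rec, truth, dec, thr = self._detection()
        full = af.detect_peaks(rec)
        victim = full.peak_indices[30]
        gapped = af.PeakTrain(np.delete(full.peak_indices, 30),
                              np.delete(full.peak_amplitudes, 30), 100.0)
        recovered = af.recover_missed(gapped, dec, thr, samples=rec.samples)
        assert recovered.n_peaks == full.n_peaks
        assert np.min(np.abs(recovered.peak_indices - victim)) <= 5

    def test_regular_train_unchanged(self):
        rec, truth, dec, thr = self._detection()
        full = af.detect_peaks(rec)
        out = af.recover_missed(full, dec, thr, samples=rec.samples)
        assert np.array_equal(out.peak_indices, full.peak_indices)

    def test_gap_without_subthreshold_pair_left_alone(self):
        fs = 100.0
        idx = np.array([0, 100, 200, 600, 700], dtype=int)
        w = np.zeros(800)
        dec = af.WaveletDecomposition(w, 8, 0, fs)
        train = af.PeakTrain(idx, np.ones(idx.size), fs)
        out = af.recover_missed(train, dec, ThresholdPair(1.0, -1.0))
        assert np.array_equal(out.peak_indices, idx)


class TestDetectPeaks:
    def test_clean_minute_at_60bpm_finds_60_peaks(self):
        rec, truth = _pulse_record(duration_s=60, hr=60)
        train = af.detect_peaks(rec)
        assert abs(train.n_peaks - 60) <= 1
        tp, fp, fn = match_peaks(train.peak_indices, truth.peak_indices, 5)
        assert tp / truth.peak_indices.size >= 0.99

    def test_constant_signal_gives_empty_train(self):
        train = af.detect_peaks(af.PPGRecord(np.full(6000, 1.0), 100.0))
        assert train.n_peaks == 0

    def test_refractory_invariant_holds_on_output(self):
        rec, _ = _pulse_record(duration_s=120, sd_ms=40, seed=9,
                               noise_emg_amp=0.15)
        train = af.detect_peaks(rec)
        if train.n_peaks > 1:
            min_gap_s = np.min(np.diff(train.peak_indices)) / 100.0
            assert min_gap_s >= REFRACTORY_S

    def test_translation_equivariance_on_shared_interior(self):
        rec, _ = _pulse_record(duration_s=90, sd_ms=30, seed=4)
        x = rec.samples
        k = 137
        a = af.detect_peaks(af.PPGRecord(x[:-k], 100.0))
        b = af.detect_peaks(af.PPGRecord(x[k:], 100.0))
        lo, hi = 2000, 6000  # interior samples present in both crops
        pa = a.peak_indices[(a.peak_indices >= lo + k)
                            & (a.peak_indices < hi)]
        pb = b.peak_indices[(b.peak_indices >= lo)
                            & (b.peak_indices < hi - k)] + k
        assert np.array_equal(pa, pb)
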