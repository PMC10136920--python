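import warnings

import numpy as np
import pytest

import apneaflow as af
from apneaflow.mse import SampEnParams, ScaleEntropyVector
from apneaflow.prv import PRV_COLUMNS, impute_columns


def _train(indices, amplitudes=None, fs=100.0):
    indices = np.asarray(indices, dtype=int)
    amps = np.ones(indices.size) if amplitudes is None else amplitudes
    return af.PeakTrain(indices, amps, fs)


def _entropy_vec(values):
    values = np.asarray(values, dtype=float)
    return ScaleEntropyVector(np.arange(1, values.size + 1), values,
                              SampEnParams(scale_max=values.size), "improved")


class TestComputePrv:
    def test_regular_minute_at_60bpm(self):
        idx = np.arange(60) * 100  # exactly 1 s apart at 100 Hz
        out = af.compute_prv(_train(idx), 60.0)
        assert out.pr == 60.0
        assert out.sdnn_pp_ms == 0.0
        assert out.nn50 == 0
        assert out.pnn50 == 0.0
        assert out.pp_mean_ms == 1000.0

    def test_nn50_boundary_counts_only_strict_excess(self):
        # intervals 1000, 1060, 1000 ms -> both successive diffs are 60 ms
        out = af.compute_prv(_train([0, 100, 206, 306]), 60.0)
        assert out.nn50 == 2
        assert out.pnn50 == 1.0
        # exactly 50 ms differences do NOT count ("exceeds 50 ms")
        out50 = af.compute_prv(_train([0, 100, 205, 305]), 60.0)
        assert out50.nn50 == 0

    def test_amplitude_statistics(self):
        out = af.compute_prv(_train([0, 100, 200],
                                    amplitudes=np.array([1.0, 2.0, 3.0])),
                             60.0)
        assert out.aa_mean == 2.0
        assert out.aa_median == 2.0

    def test_fewer_than_three_peaks_is_degenerate(self):
        out = af.compute_prv(_train([0, 100]), 60.0)
        assert out.degenerate
        assert out.pr == 2.0
        assert np.isnan(out.sdnn_pp_ms)

    def test_invariant_to_uniform_time_shift(self):
        a = af.compute_prv(_train([0, 100, 205, 320]), 60.0)
        b = af.compute_prv(_train([500, 600, 705, 820]), 60.0)
        assert a.to_array()[1:].tolist() == b.to_array()[1:].tolist()

    def test_amplitude_features_scale_with_signal(self):
        amps = np.array([1.0, 2.0, 3.0, 2.0])
        a = af.compute_prv(_train([0, 100, 200, 300], amps), 60.0)
        b = af.compute_prv(_train([0, 100, 200, 300], 2.0 * amps), 60.0)
        assert b.aa_mean == 2.0 * a.aa_mean
        assert b.sdnn_aa == 2.0 * a.sdnn_aa


class TestAssembleFeatures:
    def test_shape_is_windows_by_scale_max_plus_nine(self):
        evs = [_entropy_vec(np.linspace(0, 1, 15)) for _ in range(10)]
        prvs = [af.compute_prv(_train([0, 100, 200, 300]), 60.0)
                for _ in range(10)]
        fm = af.assemble_features(evs, prvs)
        assert fm.values.shape == (10, 24)
        assert fm.columns[:2] == ["mse_s1", "mse_s2"]
        assert list(fm.columns[-9:]) == list(PRV_COLUMNS)

    def test_degenerate_window_imputed_and_masked(self):
        evs = [_entropy_vec(np.full(15, np.nan)),
               _entropy_vec(np.linspace(0, 1, 15))]
        prvs = [af.compute_prv(_train([0, 100]), 60.0),
                af.compute_prv(_train([0, 100, 200, 300]), 60.0)]
        fm = af.assemble_features(evs, prvs)
        assert np.all(np.isfinite(fm.values))
        assert fm.mask[0].sum() > 0
        assert fm.mask[1].sum() == 0

    def test_empty_input_gives_empty_matrix(self):
        fm = af.assemble_features([], [])
        assert fm.values.shape[0] == 0

    def test_misaligned_lengths_raise(self):
        with pytest.raises(ValueError):
            af.assemble_features([_entropy_vec(np.zeros(15))], [])

    def test_column_order_stable_across_runs(self):
        evs = [_entropy_vec(np.linspace(0, 1, 15))]
        prvs = [af.compute_prv(_train([0, 100, 200, 300]), 60.0)]
        a = af.assemble_features(evs, prvs)
        b = af.assemble_features(evs, prvs)
        assert a.columns == b.columns
        assert np.array_equal(a.values, b.values)

    def test_prediction_time_imputation_uses_training_medians(self):
        raw = np.array([[1.0, np.nan], [3.0, 4.0]])
        _, _, medians = impute_columns(raw)
        values, mask, _ = impute_columns(np.array([[np.nan, np.nan]]),
                                         medians)
        assert values.tolist() == [[2.0, 4.0]]
        assert mask.all()


class TestSelectFeatures:
    def test_discriminative_column_is_selected(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        X = rng.standard_normal((200, 6))
        X[:, 3] = y  # perfectly informative column
        mask = af.select_features(X, y, seed=0)
        assert mask[3]

    def test_zero_threshold_keeps_everything(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 100)
        X = rng.standard_normal((100, 4))
        mask = af.select_features(X, y, importance_threshold=0.0, seed=0)
        assert mask.all()

    def test_all_constant_columns_warn_and_select_nothing(self):
        X = np.ones((40, 3))
        y = np.array([0, 1] * 20)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            mask = af.select_features(X, y, seed=0)
        assert not mask.any()
        assert caught

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            af.select_features(np.random.default_rng(0).random((10, 3)),
                               np.zeros(10), seed=0)
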