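"""Signal conditioning: filters, windowing, label filtering, z-scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from sksformer import preprocess as pp


class TestLowpass:
    def test_dc_passthrough(self):
        x = np.full((300, 3), 2.5)
        np.testing.assert_allclose(pp.lowpass_filter(x, fs=20.0), x, atol=1e-9)

    def test_stopband_attenuation_of_high_frequency_sinusoid(self):
        fs, cutoff, f = 20.0, 2.5, 9.0
        t = np.arange(4000) / fs
        x = np.sin(2 * np.pi * f * t)
        y = pp.lowpass_filter(x, fs=fs, cutoff=cutoff)
        ratio = np.sqrt(np.mean(y**2)) / np.sqrt(np.mean(x**2))
        assert ratio < 0.05
        # steady state (edge transients excluded): two zero-phase passes
        # square the one-pass magnitude response, which is ~3e-10 here
        steady = np.sqrt(np.mean(y[500:-500] ** 2))
        w, h = sps.freqz(*sps.butter(4, cutoff, fs=fs), worN=[f], fs=fs)
        assert abs(h[0]) ** 2 < 1e-6
        assert steady / np.sqrt(np.mean(x**2)) < 1e-6

    def test_zero_phase_symmetry(self):
        # exact away from the ends; the finite odd-reflection padding
        # (length 15) leaves small asymmetric transients at the edges
        rng = np.random.default_rng(0)
        x = rng.normal(size=(500, 2))
        fwd = pp.lowpass_filter(x, fs=20.0)
        rev = pp.lowpass_filter(x[::-1], fs=20.0)[::-1]
        np.testing.assert_allclose(fwd[50:-50], rev[50:-50], atol=1e-8)
        np.testing.assert_allclose(fwd, rev, atol=0.05)

    def test_invalid_cutoff_and_short_series(self):
        with pytest.raises(ValueError):
            pp.lowpass_filter(np.zeros((100, 1)), fs=20.0, cutoff=10.0)
        with pytest.raises(ValueError):
            pp.lowpass_filter(np.zeros((10, 1)), fs=20.0)


class TestSavgol:
    def test_cubic_polynomial_reproduced_exactly(self):
        t = np.linspace(-1, 1, 200)
        x = 0.3 * t**3 - 1.2 * t**2 + t - 0.5
        y = pp.savgol_smooth(x)
        np.testing.assert_allclose(y, x, atol=1e-9)

    def test_constant_unchanged(self):
        x = np.full((50, 2), 7.0)
        np.testing.assert_allclose(pp.savgol_smooth(x), x, atol=1e-12)

    def test_noise_variance_reduced_and_matches_kernel_convolution(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=1000)
        y = pp.savgol_smooth(x)
        assert y.var() < x.var()
        kernel = sps.savgol_coeffs(11, 3)
        interior = np.convolve(x, kernel, mode="valid")
        np.testing.assert_allclose(y[5:-5], interior, atol=1e-10)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            pp.savgol_smooth(np.zeros(50), window=10)
        with pytest.raises(ValueError):
            pp.savgol_smooth(np.zeros(50), window=11, polyorder=11)

    def test_denoise_shape_conservative(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(333, 3))
        assert pp.denoise(x, fs=20.0).shape == x.shape


class TestSegmentation:
    @pytest.mark.parametrize("length,t,stride,expected",
                             [(400, 200, 100, 3), (199, 200, 100, 0),
                              (1000, 200, 100, 9), (200, 200, 100, 1)])
    def test_window_count_formula(self, length, t, stride, expected):
        series = pp.LabeledSeries(np.zeros((length, 3)),
                                  np.array(["a"] * length), fs=20.0)
        wins = pp.segment_windows(series, t=t, stride=stride)
        assert len(wins) == expected
        starts = [w[2] for w in wins]
        assert starts == list(range(0, expected * stride, stride))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(length=st.integers(1, 600), t=st.integers(1, 250),
           stride=st.integers(1, 120))
    def test_window_count_matches_brute_force(self, length, t, stride):
        series = pp.LabeledSeries(np.zeros((length, 2)),
                                  np.array(["a"] * length), fs=20.0)
        wins = pp.segment_windows(series, t=t, stride=stride)
        brute = [s for s in range(0, length, stride) if s + t <= length
                 and s % stride == 0]
        assert len(wins) == len(brute)

    def test_windows_are_half_open_views_of_source(self):
        x = np.arange(40, dtype=float).reshape(40, 1)
        series = pp.LabeledSeries(x, np.array(["a"] * 40), fs=20.0)
        wins = pp.segment_windows(series, t=10, stride=5)
        for values, _, start in wins:
            np.testing.assert_array_equal(values[:, 0],
                                          np.arange(start, start + 10))


class TestLabelConsistency:
    def test_uniform_labels_all_retained(self):
        series = pp.LabeledSeries(np.zeros((400, 3)),
                                  np.array(["walk"] * 400), fs=20.0)
        wins = pp.segment_windows(series, t=100, stride=50)
        kept = pp.enforce_label_consistency(wins)
        assert len(kept) == len(wins)
        assert all(w.label == "walk" for w in kept)

    def test_transition_windows_dropped_matches_brute_force(self):
        labels = np.array(["walk"] * 230 + ["run"] * 270)
        series = pp.LabeledSeries(np.zeros((500, 3)), labels, fs=20.0)
        wins = pp.segment_windows(series, t=100, stride=50)
        kept = pp.enforce_label_consistency(wins)
        expected = sum(1 for _, lab, _ in wins if len(set(lab)) == 1)
        assert len(kept) == expected
        assert 0 < len(kept) < len(wins)

    def test_per_record_label_trivially_passes(self):
        series = pp.LabeledSeries(np.zeros((400, 3)), "swing", fs=20.0)
        wins = pp.segment_windows(series, t=100, stride=100)
        assert len(pp.enforce_label_consistency(wins)) == len(wins)


class TestNormalizer:
    def _windows(self, x):
        return [pp.SampleWindow(values=w, label=0, source=("s", i))
                for i, w in enumerate(x)]

    def test_hand_computed_stats_on_small_fixture(self):
        w1 = np.array([[1.0, 10.0], [3.0, 30.0]])
        w2 = np.array([[5.0, 50.0], [7.0, 70.0]])
        w3 = np.array([[9.0, 90.0], [11.0, 110.0]])
        stats = pp.fit_normalizer(self._windows([w1, w2, w3]))
        np.testing.assert_allclose(stats.mean, [6.0, 60.0])
        np.testing.assert_allclose(stats.std,
                                   [np.std([1, 3, 5, 7, 9, 11]),
                                    np.std([10, 30, 50, 70, 90, 110])])

    def test_transformed_training_data_is_standardized(self):
        rng = np.random.default_rng(5)
        x = rng.normal(3.0, 2.5, size=(20, 50, 3))
        stats = pp.fit_normalizer(x)
        z = pp.apply_normalizer(stats, x)
        flat = z.reshape(-1, 3)
        assert np.all(np.abs(flat.mean(axis=0)) < 1e-6)
        np.testing.assert_allclose(flat.std(axis=0), 1.0, atol=1e-6)

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(10, 30, 2))
        x2 = x * 10.0 + 5.0
        z1 = pp.apply_normalizer(pp.fit_normalizer(x), x)
        z2 = pp.apply_normalizer(pp.fit_normalizer(x2), x2)
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_constant_axis_clamped_with_warning(self):
        x = np.zeros((4, 10, 2))
        x[..., 1] = np.random.default_rng(0).normal(size=(4, 10))
        with pytest.warns(UserWarning):
            stats = pp.fit_normalizer(x)
        assert stats.std[0] == pytest.approx(pp.STD_EPS)

    def test_validation_data_never_influences_train_stats(self):
        rng = np.random.default_rng(7)
        train = rng.normal(size=(12, 40, 3))
        stats1 = pp.fit_normalizer(train)
        # mutating would-be validation data must leave the stats unchanged
        _ = rng.normal(size=(5, 40, 3)) * 1e6
        stats2 = pp.fit_normalizer(train)
        np.testing.assert_array_equal(stats1.mean, stats2.mean)
        np.testing.assert_array_equal(stats1.std, stats2.std)


class TestLabels:
    def test_lexicographic_ids(self):
        ids, lm = pp.encode_labels(["walk", "run", "walk"])
        assert lm.names == ["run", "walk"]
        np.testing.assert_array_equal(ids, [1, 0, 1])

    def test_decode_inverse_and_enumeration(self):
        names = ["f", "a", "c", "b", "e", "d"]
        ids, lm = pp.encode_labels(names)
        assert lm.decode(ids) == names
        assert sorted(lm.encode(lm.names)) == list(range(6))

    def test_unseen_label_rejected(self):
        _, lm = pp.encode_labels(["a", "b"])
        with pytest.raises(ValueError):
            lm.encode(["c"])


class TestCropOrPad:
    def test_center_crop_and_edge_pad(self):
        long = pp.LabeledSeries(np.arange(30, dtype=float)[:, None], "x", fs=20.0)
        short = pp.LabeledSeries(np.arange(6, dtype=float)[:, None], "x", fs=20.0)
        c = pp.crop_or_pad(long, 10)
        assert c.shape == (10, 1) and c[0, 0] == 10.0
        p = pp.crop_or_pad(short, 10)
        assert p.shape == (10, 1)
        assert p[0, 0] == 0.0 and p[-1, 0] == 5.0
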