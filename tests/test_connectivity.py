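"""dwPLI estimation: window layout, cross-spectra, estimator properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h
from scipy.signal.windows import hann

from netreconf import (
    InvalidConfigError,
    SlidingWindowDWPLI,
    TrialEnsemble,
    WindowSpec,
    band_average,
    cross_spectra,
    dwpli,
    dwpli_from_imag,
    edge_change,
    window_centers,
    window_tags,
)
from netreconf.exceptions import EstimatorUndefinedError
from oracles import dwpli_bruteforce, naive_dft_cross


class TestWindowCenters:
    def test_reference_layout_51_windows(self):
        centers = window_centers(WindowSpec())
        assert len(centers) == 51
        assert (centers < 0).sum() == 25
        assert (centers > 0).sum() == 25
        assert np.isclose(centers, 0.0).sum() == 1
        # spacing is exactly 5 samples at 128 Hz
        assert np.allclose(np.diff(centers), 5 / 128.0)

    def test_zero_retain_span_single_center(self):
        spec = WindowSpec(retain_span=0.0)
        assert np.array_equal(window_centers(spec), [0.0])

    def test_enumeration_oracle_fs100(self):
        # brute force: multiples of 10 samples = 0.1 s inside [-0.5, 0.5]
        expected = [k * 0.1 for k in range(-5, 6)]
        spec = WindowSpec(fs=100.0, center_spacing_samples=10, retain_span=0.5,
                          freq_max=25.0)
        assert np.allclose(window_centers(spec), expected)

    def test_retain_span_exceeding_epoch_raises(self):
        with pytest.raises(InvalidConfigError):
            WindowSpec(epoch_span=(-1.0, 1.0), retain_span=0.9)

    def test_tags(self):
        tags = window_tags(np.array([-0.1, 0.0, 0.1]))
        assert list(tags) == ["pre", "pulse", "post"]


def _toy_ensemble(data, fs=128.0):
    data = np.asarray(data, dtype=float)
    return TrialEnsemble(data=data, fs=fs, pulse_index=data.shape[1] // 2)


class TestCrossSpectra:
    def test_sinusoid_power_at_its_frequency(self):
        fs = 128.0
        t = np.arange(int(3 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        data = np.stack([x, x])[:, :, None] * np.ones((1, 1, 3))
        ens = _toy_ensemble(data)
        spec = WindowSpec(epoch_span=(-1.5, 1.5), retain_span=0.5)
        cs = cross_spectra(ens, spec)
        x00 = cs.trial_cross(0)[:, :, 0, 0].real.mean(axis=0)
        assert np.isclose(cs.freqs[np.argmax(x00)], 10.0)

    def test_identical_channels_real_cross(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1, 384, 3))
        data = np.concatenate([x, x], axis=0)
        ens = _toy_ensemble(data)
        cs = cross_spectra(ens, WindowSpec(epoch_span=(-1.5, 1.5), retain_span=0.5))
        cross = cs.trial_cross(2)
        assert np.allclose(cross[:, :, 0, 1].imag, 0.0, atol=1e-12)
        assert np.allclose(cross[:, :, 0, 1], cross[:, :, 0, 0])

    def test_matches_naive_dft_oracle(self):
        rng = np.random.default_rng(42)
        data = rng.standard_normal((2, 384, 3))
        ens = _toy_ensemble(data)
        spec = WindowSpec(epoch_span=(-1.5, 1.5), retain_span=0.25)
        cs = cross_spectra(ens, spec)
        w = 3  # arbitrary window
        center_sample = int(round(cs.centers[w] * spec.fs)) + ens.pulse_index
        nwin = spec.n_window_samples
        s0 = center_sample - nwin // 2
        taper = hann(nwin, sym=False)
        keep = (np.fft.rfftfreq(spec.nfft, 1 / spec.fs) >= spec.freq_min - 1e-9) & (
            np.fft.rfftfreq(spec.nfft, 1 / spec.fs) <= spec.freq_max + 1e-9
        )
        for trial in range(3):
            ref = naive_dft_cross(
                data[0, s0 : s0 + nwin, trial],
                data[1, s0 : s0 + nwin, trial],
                taper,
                spec.nfft,
            )[keep]
            got = cs.trial_cross(w)[trial, :, 0, 1]
            assert np.allclose(got, ref, atol=1e-9)

    def test_window_past_epoch_raises(self):
        # 80 samples at 128 Hz: the outermost retained window would need
        # samples beyond the recording, which must never be zero-filled
        data = np.zeros((2, 80, 3))
        ens = _toy_ensemble(data)
        with pytest.raises(InvalidConfigError):
            cross_spectra(ens, WindowSpec(epoch_span=(-0.3125, 0.3125),
                                          retain_span=0.1))

    def test_single_trial_raises(self):
        ens = _toy_ensemble(np.zeros((2, 384, 1)))
        with pytest.raises(EstimatorUndefinedError):
            cross_spectra(ens, WindowSpec(epoch_span=(-1.5, 1.5), retain_span=0.5))


class TestDwpliEstimator:
    def test_three_trial_sign_flip_example(self):
        # I = (+1, +1, -1): ordered pairs give -2/6 = -1/3
        vals, deg = dwpli_from_imag(np.array([1.0, 1.0, -1.0]))
        assert np.isclose(vals, -1.0 / 3.0)
        assert not deg

    def test_all_zero_imag_degenerate(self):
        vals, deg = dwpli_from_imag(np.zeros(5))
        assert vals == 0.0
        assert deg

    def test_constant_sign_gives_one(self):
        vals, _ = dwpli_from_imag(np.array([0.3, 1.2, 0.01, 2.0]))
        assert np.isclose(vals, 1.0)

    @settings(derandomize=True, max_examples=40)
    @given(
        st_h.lists(
            # zero or magnitudes within a few decades: the closed-form and
            # pairwise summations only agree to 1e-12 away from underflow
            st_h.one_of(
                st_h.just(0.0),
                st_h.floats(1e-3, 5.0),
                st_h.floats(-5.0, -1e-3),
            ),
            min_size=2,
            max_size=6,
        )
    )
    def test_bruteforce_pair_oracle(self, imag_list):
        imag = np.array(imag_list)
        vals, deg = dwpli_from_imag(imag)
        ref = dwpli_bruteforce(imag)
        assert abs(vals - ref) < 1e-12
        assert -1.0 - 1e-12 <= vals <= 1.0 + 1e-12

    @settings(derandomize=True, max_examples=20)
    @given(st_h.integers(0, 2**31 - 1))
    def test_trial_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        imag = rng.standard_normal(6)
        a, _ = dwpli_from_imag(imag)
        b, _ = dwpli_from_imag(rng.permutation(imag))
        assert np.isclose(a, b)


@pytest.fixture(scope="module")
def coupled():
    from netreconf import BandPlan, SimulationConfig, generate_trials

    plan = BandPlan(
        band=(8.0, 12.0), pre_partition=(1, 1), post_partition=(1, 1),
        coupling=1.0, lag_cycles=(0.0, 0.25),
    )
    cfg = SimulationConfig(
        n_regions=2, fs=128.0, epoch_span=(-1.5, 1.5), n_trials=200,
        bands=(plan,), noise_sd=0.05, seed=7, n_subjects=1,
    )
    ens = generate_trials(cfg)
    spec = WindowSpec(epoch_span=(-1.5, 1.5))
    return ens, spec, dwpli(cross_spectra(ens, spec))


class TestDwpliFullPath:
    def test_constant_lag_near_one(self, coupled):
        _, _, result = coupled
        alpha = band_average(result, (8.0, 12.0))
        pre = alpha.layers[alpha.tags == "pre"]
        assert pre[:, 0, 1].mean() > 0.9

    def test_scaling_invariance(self, coupled):
        ens, spec, result = coupled
        scaled = TrialEnsemble(
            data=ens.data * np.array([3.7, 0.2])[:, None, None],
            fs=ens.fs, pulse_index=ens.pulse_index,
        )
        result2 = dwpli(cross_spectra(scaled, spec))
        assert np.allclose(result.values, result2.values, atol=1e-9)

    def test_independent_channels_near_zero(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((2, 384, 200))
        ens = _toy_ensemble(data)
        result = dwpli(cross_spectra(ens, WindowSpec(epoch_span=(-1.5, 1.5),
                                                     retain_span=0.25)))
        assert np.max(np.abs(result.values[:, :, 0, 1])) < 0.15

    def test_diagonal_degenerate(self, coupled):
        _, _, result = coupled
        assert np.all(result.degenerate[:, :, 0, 0])
        assert np.all(result.values[:, :, 0, 0] == 0.0)


class TestBandAverage:
    def _result(self, freqs, values):
        from netreconf.connectivity import DwpliResult

        w, f = values.shape[:2]
        centers = np.array([-0.1, 0.0, 0.1])[:w]
        return DwpliResult(
            values=values, degenerate=np.zeros_like(values, dtype=bool),
            freqs=np.asarray(freqs), centers=centers,
            tags=window_tags(centers),
        )

    def test_single_bin_identity(self):
        vals = np.random.default_rng(0).uniform(size=(3, 1, 2, 2))
        res = self._result([10.0], vals)
        conn = band_average(res, (10.0, 10.0))
        assert np.allclose(conn.layers, 0.5 * (vals[:, 0] + vals[:, 0].swapaxes(1, 2)))

    def test_arithmetic_mean(self):
        vals = np.zeros((3, 3, 2, 2))
        vals[:, 0], vals[:, 1], vals[:, 2] = 0.2, 0.4, 0.6
        res = self._result([9.0, 10.0, 11.0], vals)
        conn = band_average(res, (9.0, 11.0))
        assert np.allclose(conn.layers, 0.4)

    def test_alpha_band_uses_nine_bins(self):
        freqs = np.arange(2.0, 25.5, 0.5)
        in_alpha = (freqs >= 8.0) & (freqs <= 12.0)
        assert in_alpha.sum() == 9  # 8.0 ... 12.0 inclusive
        rng = np.random.default_rng(1)
        vals = rng.uniform(size=(3, len(freqs), 2, 2))
        res = self._result(freqs, vals)
        conn = band_average(res, (8.0, 12.0))
        expected = vals[:, in_alpha].mean(axis=1)
        expected = 0.5 * (expected + expected.swapaxes(1, 2))
        assert np.allclose(conn.layers, expected)

    def test_empty_band_raises(self):
        res = self._result([10.0], np.zeros((3, 1, 2, 2)))
        with pytest.raises(InvalidConfigError):
            band_average(res, (13.0, 14.0))

    def test_half_band_boundary_excluded(self):
        # 12.5 Hz belongs to neither default band (closed intervals)
        freqs = np.arange(2.0, 25.5, 0.5)
        alpha = (freqs >= 8.0) & (freqs <= 12.0)
        beta = (freqs >= 13.0) & (freqs <= 20.0)
        assert not alpha[freqs == 12.5] and not beta[freqs == 12.5]


class TestEdgeChange:
    def _series(self, layers):
        from netreconf import ConnectivitySeries

        n_layer = len(layers)
        centers = np.linspace(-0.2, 0.2, n_layer)
        centers[n_layer // 2] = 0.0
        return ConnectivitySeries(
            band=(8.0, 12.0), layers=np.asarray(layers, float),
            centers=centers, tags=window_tags(centers),
        )

    def test_post_equals_pre_gives_zero(self):
        layer = np.random.default_rng(0).uniform(size=(3, 3))
        series = self._series([layer, layer, np.zeros((3, 3)), layer, layer])
        assert np.allclose(edge_change(series), 0.0)

    def test_constant_offset_recovered(self):
        layer = np.random.default_rng(1).uniform(size=(3, 3))
        series = self._series(
            [layer, layer, np.zeros((3, 3)), layer + 0.3, layer + 0.3]
        )
        assert np.allclose(edge_change(series), 0.3)

    def test_random_series_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        layers = rng.uniform(size=(5, 4, 4))
        series = self._series(list(layers))
        got = edge_change(series)
        pre_idx = [0, 1]
        post_idx = [3, 4]
        for i in range(4):
            for j in range(4):
                expected = np.mean([layers[s][i, j] for s in post_idx]) - np.mean(
                    [layers[s][i, j] for s in pre_idx]
                )
                assert np.isclose(got[i, j], expected)

    def test_mismatched_counts_raise(self):
        layer = np.zeros((3, 3))
        from netreconf import ConnectivitySeries

        centers = np.array([-0.2, -0.1, 0.0, 0.1])
        series = ConnectivitySeries(
            band=(8.0, 12.0), layers=np.zeros((4, 3, 3)), centers=centers,
            tags=window_tags(centers),
        )
        with pytest.raises(InvalidConfigError):
            edge_change(series)


def test_transformer_api(two_node_coupled_cfg):
    from netreconf import generate_trials

    ens = generate_trials(two_node_coupled_cfg)
    est = SlidingWindowDWPLI(band=(8.0, 12.0), retain_span=1.0)
    conn = est.fit(ens).transform(ens)
    assert est.n_windows_ == 51
    assert conn.n_layers == 51
    assert (conn.tags == "pre").sum() == 25
    params = est.get_params()
    assert params["band"] == (8.0, 12.0)
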