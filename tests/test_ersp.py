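"""Unit and property tests for the Morlet CWT and ERSP computation."""

import numpy as np
import pytest
import pywt

from reachnet.ersp import (
    ALPHA_BAND,
    ERSPMap,
    ScaleGrid,
    WaveletParams,
    band_average,
    coi_exclusion_samples,
    compute_ersp,
    cwt_power,
    mean_power_by_target,
    morlet_cwt,
    scale_for_frequency,
    window_average,
)
from conftest import make_epochs


PARAMS = WaveletParams(fs=512.0)


class TestScaleMapping:
    @pytest.mark.parametrize("freq, scale", [(8.0, 64.0), (512.0, 1.0), (16.0, 32.0)])
    def test_stated_mapping(self, freq, scale):
        # fs=512 Hz with normalized center frequency 1.0 => effective
        # mother-wavelet center frequency 512 Hz, so scale = 512 / freq
        params = WaveletParams(bandwidth=1.5, center_freq_norm=1.0, fs=512.0)
        assert scale_for_frequency(freq, params) == pytest.approx(scale)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            scale_for_frequency(0.0, PARAMS)
        with pytest.raises(ValueError):
            scale_for_frequency(1000.0, PARAMS)  # would need scale < 1

    def test_grid_matches_pywt_center_frequencies(self):
        grid = ScaleGrid.default(PARAMS)
        f_pywt = pywt.scale2frequency("cmor1.5-1.0", grid.scales) * PARAMS.fs
        assert np.allclose(f_pywt, grid.freqs)


class TestMorletCwt:
    def test_agrees_with_pywt_reference(self, rng):
        x = rng.standard_normal((3, 600))
        scales = np.array([64.0, 40.0, 20.0])
        ref, _ = pywt.cwt(x, scales, "cmor1.5-1.0", method="fft", axis=-1)
        mine = morlet_cwt(x, scales)
        assert np.abs(ref - mine).max() < 1e-10

    def test_tone_localizes_at_its_own_scale(self):
        fs = 512.0
        t = np.arange(2048) / fs
        x = np.sin(2 * np.pi * 10 * t)
        grid = ScaleGrid.default(PARAMS)
        power = np.abs(morlet_cwt(x, grid.scales)) ** 2
        core = power[:, 512:-512]
        peak_scale = core.mean(axis=1).argmax()
        assert grid.freqs[peak_scale] == pytest.approx(10.0, abs=1.0)
        # approximately constant along time at the tone's scale
        tone_row = core[peak_scale]
        assert tone_row.std() / tone_row.mean() < 0.01

    def test_zero_signal_zero_power(self):
        out = morlet_cwt(np.zeros(1024), [64.0, 32.0])
        assert np.all(np.abs(out) == 0)

    def test_amplitude_step_gives_power_ratio_four(self):
        fs = 512.0
        t = np.arange(4096) / fs
        amp = np.where(t < 4.0, 1.0, 2.0)
        x = amp * np.sin(2 * np.pi * 10 * t)
        power = np.abs(morlet_cwt(x, [scale_for_frequency(10.0, PARAMS)])[0]) ** 2
        early = power[1024:1536].mean()   # away from edges and the step
        late = power[2560:3072].mean()
        assert late / early == pytest.approx(4.0, rel=0.02)

    def test_short_epoch_warns_but_runs(self):
        with pytest.warns(UserWarning, match="wavelet support"):
            morlet_cwt(np.zeros(100), [128.0])


class TestComputeErsp:
    def test_stationary_process_near_zero(self, rng):
        ep = make_epochs(rng.standard_normal((40, 2, 2048)))
        grid = ScaleGrid.default(PARAMS)
        ersp = compute_ersp(cwt_power(ep, grid), targets=ep.targets)
        post = ersp.values[..., ersp.time_mask((1.0, 2.0))].mean()
        assert abs(post) < 10.0  # percent; pure sampling error

    def test_halved_amplitude_gives_minus_75_percent(self, sinusoid_epochs):
        # power scales with amplitude squared: 100 * (0.5**2 - 1) = -75 %
        grid = ScaleGrid.default(PARAMS)
        power = cwt_power(sinusoid_epochs, grid)
        excl = coi_exclusion_samples(grid, PARAMS)
        ersp = compute_ersp(power, targets=sinusoid_epochs.targets,
                            baseline_exclude=excl)
        val = window_average(band_average(ersp.values, ersp.freqs, ALPHA_BAND),
                             ersp.times, (1.0, 2.0))
        assert val[0] == pytest.approx(-75.0, abs=2.0)   # gain 0.5 channel
        assert val[1] == pytest.approx(0.0, abs=1.0)     # stationary channel

    def test_edge_unmasked_baseline_biases_null_channel_positive(self, sinusoid_epochs):
        # without cone-of-influence handling, zero padding deflates the
        # baseline power estimate and shifts a truly-null channel upward
        grid = ScaleGrid.default(PARAMS)
        ersp = compute_ersp(cwt_power(sinusoid_epochs, grid),
                            targets=sinusoid_epochs.targets)
        val = window_average(band_average(ersp.values, ersp.freqs, ALPHA_BAND),
                             ersp.times, (1.0, 2.0))
        assert val[0] == pytest.approx(-75.0, abs=3.0)
        assert 0.5 < val[1] < 5.0

    def test_baseline_window_mean_is_exactly_zero(self, rng):
        ep = make_epochs(rng.standard_normal((12, 2, 2048)),
                         targets=rng.integers(1, 4, size=12))
        ersp = compute_ersp(cwt_power(ep, ScaleGrid.default(PARAMS)),
                            targets=ep.targets)
        mask = ersp.time_mask((-1.0, 0.0))
        base_mean = ersp.per_target[..., mask].mean(axis=-1)
        assert np.abs(base_mean).max() < 1e-9

    def test_invariant_to_global_rescaling(self, rng):
        data = rng.standard_normal((10, 2, 2048))
        grid = ScaleGrid.default(PARAMS)
        e1 = compute_ersp(cwt_power(make_epochs(data), grid),
                          targets=np.ones(10, int))
        e2 = compute_ersp(cwt_power(make_epochs(3.7 * data), grid),
                          targets=np.ones(10, int))
        assert np.allclose(e1.values, e2.values, atol=1e-6)

    def test_zero_baseline_power_names_frequency(self):
        ep = make_epochs(np.zeros((2, 1, 2048)))
        power = cwt_power(ep, ScaleGrid.default(PARAMS))
        with pytest.raises(ValueError, match="frequency"):
            compute_ersp(power, targets=ep.targets)

    def test_streamed_target_means_match_cwt_power(self, rng):
        ep = make_epochs(rng.standard_normal((8, 2, 512)),
                         targets=np.array([1, 1, 2, 2, 1, 2, 1, 2]))
        grid = ScaleGrid.from_frequencies([8.0, 10.0, 20.0], PARAMS)
        tids, streamed = mean_power_by_target(ep, grid, PARAMS, single=False)
        per_trial = cwt_power(ep, grid, PARAMS).values
        for k, t in enumerate(tids):
            direct = per_trial[ep.targets == t].mean(axis=0)
            assert np.allclose(streamed[k], direct, rtol=1e-10)


class TestBandAndWindowReductions:
    freqs = np.arange(4.0, 33.0)

    def test_constant_field_preserved(self):
        vals = np.full((2, self.freqs.size, 10), -20.0)
        out = band_average(vals, self.freqs, ALPHA_BAND)
        assert np.allclose(out, -20.0)

    def test_two_point_arithmetic_mean(self):
        vals = np.zeros((1, self.freqs.size, 1))
        vals[0, self.freqs == 10.0, 0] = -10.0
        vals[0, self.freqs == 11.0, 0] = -30.0
        sub = np.isin(self.freqs, (10.0, 11.0))
        out = band_average(vals[:, sub, :], self.freqs[sub], ALPHA_BAND)
        assert out[0, 0] == pytest.approx(-20.0)

    def test_alpha_beta_partition_has_no_overlap(self):
        alpha = (self.freqs >= 8) & (self.freqs < 13)
        ones = np.ones((1, self.freqs.size, 1))
        a = band_average(ones * np.arange(self.freqs.size)[None, :, None],
                         self.freqs, (8, 13))
        assert a[0, 0] == pytest.approx(np.arange(self.freqs.size)[alpha].mean())
        # beta includes its 30 Hz upper edge
        beta_idx = np.flatnonzero((self.freqs >= 13) & (self.freqs <= 30))
        b = band_average(ones * np.arange(self.freqs.size)[None, :, None],
                         self.freqs, (13, 30))
        assert b[0, 0] == pytest.approx(beta_idx.mean())

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="intersect"):
            band_average(np.ones((1, self.freqs.size, 1)), self.freqs, (100, 120))

    def test_window_average_constant_and_ramp(self):
        times = -1.0 + np.arange(2048) / 512.0
        const = np.full((3, 2048), -15.0)
        assert np.allclose(window_average(const, times, (1.0, 2.0)), -15.0)
        ramp = np.where((times >= 1.0) & (times < 2.0),
                        -30.0 * (times - 1.0), 0.0)[None, :]
        out = window_average(ramp, times, (1.0, 2.0))
        assert out[0] == pytest.approx(-15.0, abs=0.05)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            window_average(np.ones((1, 10)), np.arange(10.0), (50.0, 60.0))
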