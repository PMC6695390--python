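"""F1 amplitudes, DoG area-summation fits, and reverse-correlation filters."""

import numpy as np
import pytest
from scipy.signal import fftconvolve

from midgetkit import synthetic
from midgetkit.receptive_field import (
    AreaSummationCurve,
    DoGParams,
    FilterConfig,
    LinearFilter,
    classify_filter,
    dog_predict,
    estimate_linear_filter,
    f1_amplitude,
    fit_dog,
)
from midgetkit.spikes import SpikeRate, bin_spike_rate
from midgetkit.stimulus import StimulusTrace, gaussian_noise_stimulus


def sampled_rate(fn, bin_rate=360.0, duration=2.0):
    t = (np.arange(round(duration * bin_rate)) + 0.5) / bin_rate
    return SpikeRate(bin_rate, fn(t))


class TestF1:
    def test_pure_sinusoid_amplitude(self):
        rate = sampled_rate(lambda t: 10 + 5 * np.sin(2 * np.pi * 4 * t))
        assert f1_amplitude(rate, 4.0) == pytest.approx(5.0, rel=1e-9)

    def test_constant_rate_is_zero(self):
        rate = sampled_rate(lambda t: np.full_like(t, 7.0))
        assert f1_amplitude(rate, 4.0) == pytest.approx(0.0, abs=1e-12)

    def test_half_wave_rectified_sinusoid(self):
        """F1 of max(0, A sin) is A/2 (closed-form Fourier coefficient)."""
        A = 12.0
        rate = sampled_rate(lambda t: np.maximum(0.0, A * np.sin(2 * np.pi * 2 * t)))
        assert f1_amplitude(rate, 2.0) == pytest.approx(A / 2, rel=1e-3)

    def test_offset_invariance_and_linear_scaling(self):
        rate = sampled_rate(lambda t: 10 + 5 * np.sin(2 * np.pi * 4 * t))
        shifted = SpikeRate(rate.bin_rate, rate.rates + 20.0)
        scaled = SpikeRate(rate.bin_rate, rate.rates * 3.0)
        assert f1_amplitude(shifted, 4.0) == pytest.approx(f1_amplitude(rate, 4.0))
        assert f1_amplitude(scaled, 4.0) == pytest.approx(3 * f1_amplitude(rate, 4.0))

    def test_above_nyquist_rejected(self):
        rate = sampled_rate(lambda t: np.ones_like(t), bin_rate=60.0)
        with pytest.raises(ValueError):
            f1_amplitude(rate, 40.0)


class TestDoGPredict:
    def test_hand_computed_value(self):
        # independent evaluation of R0 + Kc pi sc^2 e^{-(pi sc f)^2} - Ks pi ss^2 e^{-(pi ss f)^2}
        # at (2, 0.5, 0.02, 0.05, 0.08), f = 10, frozen from a hand calculation
        p = DoGParams(r0=2.0, kc=0.5, sigma_c=0.02, ks=0.05, sigma_s=0.08)
        assert dog_predict(p, 10.0) == pytest.approx(2.0004215612575, rel=1e-10)

    def test_large_spot_asymptote(self):
        p = DoGParams(5.0, 100.0, 0.02, 50.0, 0.08)
        assert dog_predict(p, 1e4) == pytest.approx(5.0)

    def test_matched_center_surround_cancels_exactly(self):
        p = DoGParams(3.0, 7.0, 0.03, 7.0, 0.03)
        f = np.geomspace(0.1, 1000, 50)
        np.testing.assert_allclose(dog_predict(p, f), 3.0, rtol=1e-12)


class TestFitDoG:
    TRUE = DoGParams(r0=5.0, kc=1.27e5, sigma_c=0.01, ks=4973.0, sigma_s=0.04)
    DIAMS = np.geomspace(2.0, 300.0, 12)

    def test_noiseless_recovery_within_0p1_percent(self):
        curve = AreaSummationCurve(self.DIAMS, dog_predict(self.TRUE, self.DIAMS))
        fit = fit_dog(curve)
        np.testing.assert_allclose(fit.params.as_array(), self.TRUE.as_array(), rtol=1e-3)
        assert fit.rss < 1e-8
        assert fit.converged

    def test_refit_of_fitted_curve_reproduces_input(self):
        curve = AreaSummationCurve(self.DIAMS, dog_predict(self.TRUE, self.DIAMS))
        fit = fit_dog(curve)
        rss = np.sum((dog_predict(fit.params, self.DIAMS) - curve.f1_amplitudes) ** 2)
        assert rss < 1e-8

    def test_no_surround_generator_yields_negligible_surround(self):
        pure_center = DoGParams(r0=5.0, kc=1.27e5, sigma_c=0.01, ks=0.0, sigma_s=0.04)
        curve = AreaSummationCurve(self.DIAMS, dog_predict(pure_center, self.DIAMS))
        fit = fit_dog(curve)
        center_int = fit.params.kc * np.pi * fit.params.sigma_c**2
        surround_int = fit.params.ks * np.pi * fit.params.sigma_s**2
        assert surround_int <= 0.01 * center_int

    def test_sigma_c_recovered_under_noise(self):
        """Median recovered center size within 10% at 5%-of-peak noise."""
        peak = dog_predict(self.TRUE, self.DIAMS).max()
        recovered = []
        for seed in range(30):
            curve = synthetic.area_summation_ground_truth(
                self.TRUE, self.DIAMS, noise_sd=0.05 * peak, seed=seed
            )
            recovered.append(fit_dog(curve).params.sigma_c)
        assert abs(np.median(recovered) - self.TRUE.sigma_c) / self.TRUE.sigma_c < 0.10

    def test_surround_constraint_enforced(self):
        curve = AreaSummationCurve(self.DIAMS, dog_predict(self.TRUE, self.DIAMS))
        fit = fit_dog(curve)
        assert fit.params.sigma_s >= fit.params.sigma_c

    def test_too_few_diameters_rejected(self):
        with pytest.raises(ValueError):
            fit_dog(AreaSummationCurve([1, 2, 3, 4], [1, 2, 3, 4]))


def white_stimulus(n_frames=1440, frame_rate=360.0, seed=0):
    """Noise whose discrete power spectrum is exactly flat (|S_k|^2 = n)."""
    rng = np.random.default_rng(seed)
    half = n_frames // 2
    mag = np.sqrt(n_frames)
    spec = np.zeros(n_frames, dtype=complex)
    spec[1:half] = mag * np.exp(1j * rng.uniform(0, 2 * np.pi, half - 1))
    spec[half] = mag
    spec[half + 1 :] = np.conj(spec[1:half][::-1])
    s = np.fft.ifft(spec).real
    return StimulusTrace(frame_rate, 0.5, s)


class TestLinearFilter:
    def test_rate_equal_to_stimulus_gives_spike_at_lag_zero(self):
        stim = gaussian_noise_stimulus(epoch_duration=10.0, seed=1)[0]
        # rate = upsampled zero-mean stimulus (offset to stay non-negative)
        n_bins = round(stim.duration * 360)
        idx = np.minimum((np.arange(n_bins) / 360 * 60).astype(int), stim.n_frames - 1)
        r = stim.contrasts[idx]
        rate = SpikeRate(360.0, r - r.min())
        filt = estimate_linear_filter(stim, rate)
        assert np.argmax(np.abs(filt.values)) == 0
        assert filt.values[0] > 0

    def test_convolution_round_trip_correlation(self, off_kernel):
        """A rate made by convolving a known kernel with the stimulus (no
        noise, no rectification) is recovered with correlation >= 0.99."""
        stim = gaussian_noise_stimulus(frame_rate=360.0, epoch_duration=20.0, seed=2)[0]
        kern = off_kernel.resample(1000.0 / 360.0)
        n_bins = stim.n_frames
        drive = fftconvolve(stim.contrasts, kern.values)[:n_bins]
        rate = SpikeRate(360.0, drive - drive.min())
        filt = estimate_linear_filter(stim, rate)
        support = kern.values.size
        c = np.corrcoef(filt.values[:support], kern.values)[0, 1]
        assert c >= 0.99

    def test_linearity_in_rate(self):
        stim = gaussian_noise_stimulus(epoch_duration=5.0, seed=3)[0]
        rng = np.random.default_rng(4)
        n_bins = round(stim.duration * 360)
        r1 = SpikeRate(360.0, rng.uniform(0, 50, n_bins))
        r2 = SpikeRate(360.0, rng.uniform(0, 50, n_bins))
        combo = SpikeRate(360.0, 2.0 * r1.rates + 3.0 * r2.rates)
        f1 = estimate_linear_filter(stim, r1).values
        f2 = estimate_linear_filter(stim, r2).values
        fc = estimate_linear_filter(stim, combo).values
        np.testing.assert_allclose(fc, 2 * f1 + 3 * f2, atol=1e-9)

    def test_power_division_matches_omitted_denominator_on_white_noise(self):
        stim = white_stimulus(seed=5)
        rng = np.random.default_rng(6)
        n_bins = stim.n_frames
        rate = SpikeRate(360.0, rng.uniform(0, 40, n_bins))
        f_omit = estimate_linear_filter(stim, rate, FilterConfig(omit_s=0.0)).values
        f_div = estimate_linear_filter(
            stim, rate, FilterConfig(omit_s=0.0, divide_power_spectrum=True)
        ).values
        rms_diff = np.sqrt(np.mean((f_omit - f_div) ** 2)) / np.sqrt(np.mean(f_omit**2))
        assert rms_diff < 0.02

    def test_lnp_simulation_recovers_trough_latency(self, off_model):
        """Full OFF LNP chain, ten 10-s noise epochs: trough within one
        360 Hz bin of the 25 ms ground truth."""
        stims = gaussian_noise_stimulus(epoch_duration=10.0, n_epochs=10, seed=11)
        rates = [
            bin_spike_rate(
                synthetic.simulate_lnp_spikes(off_model, s, seed=100 + i), 360.0, s.duration
            )
            for i, s in enumerate(stims)
        ]
        filt = estimate_linear_filter(stims, rates)
        cls = classify_filter(filt)
        assert cls.polarity == "OFF"
        assert abs(cls.latency_ms - 25.0) <= 1000.0 / 360.0

    def test_mismatched_durations_rejected(self):
        stim = gaussian_noise_stimulus(epoch_duration=5.0, seed=0)[0]
        rate = SpikeRate(360.0, np.zeros(round(4.0 * 360)))
        with pytest.raises(ValueError):
            estimate_linear_filter(stim, rate)


class TestClassifyFilter:
    def negative_lobe_filter(self, peak_bin=9, sign=-1.0):
        lags = np.arange(180) / 360 * 1e3
        values = sign * np.exp(-0.5 * ((np.arange(180) - peak_bin) / 2.0) ** 2)
        return LinearFilter(lags, values, 360.0)

    def test_single_negative_lobe_at_bin9_is_off_at_25ms(self):
        cls = classify_filter(self.negative_lobe_filter())
        assert cls.polarity == "OFF"
        assert cls.latency_ms == pytest.approx(25.0, abs=1e-9)

    def test_negation_flips_polarity_keeps_latency(self):
        a = classify_filter(self.negative_lobe_filter(sign=-1.0))
        b = classify_filter(self.negative_lobe_filter(sign=+1.0))
        assert (a.polarity, b.polarity) == ("OFF", "ON")
        assert a.latency_ms == pytest.approx(b.latency_ms)

    def test_on_simulation_classified_on(self, off_kernel):
        on_kernel = synthetic.TemporalKernel(off_kernel.time_ms, -off_kernel.values)
        model = synthetic.LNPModel(on_kernel, baseline_rate=20.0, gain=8.0)
        stims = gaussian_noise_stimulus(epoch_duration=10.0, n_epochs=5, seed=12)
        rates = [
            bin_spike_rate(
                synthetic.simulate_lnp_spikes(model, s, seed=200 + i), 360.0, s.duration
            )
            for i, s in enumerate(stims)
        ]
        assert classify_filter(estimate_linear_filter(stims, rates)).polarity == "ON"

    def test_all_zero_filter_rejected(self):
        filt = LinearFilter(np.arange(10.0), np.zeros(10), 360.0)
        with pytest.raises(ValueError):
            classify_filter(filt)
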