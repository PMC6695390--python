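"""Ground-truth generators: LNP simulation, traces, annotations, counts."""

import numpy as np
import pytest

from midgetkit import morphometry, synthetic
from midgetkit.receptive_field import DoGParams, dog_predict, fit_dog
from midgetkit.spikes import bin_spike_rate
from midgetkit.stimulus import StimulusTrace, gaussian_noise_stimulus


def constant_stimulus(duration=10.0, frame_rate=60.0):
    return StimulusTrace(frame_rate, 0.5, np.zeros(round(duration * frame_rate)))


class TestLNP:
    def test_zero_contrast_fires_at_baseline(self, off_model):
        spikes = synthetic.simulate_lnp_spikes(off_model, constant_stimulus(50.0), seed=0)
        expected = off_model.baseline_rate * 50.0
        assert abs(spikes.n_spikes - expected) < 3 * np.sqrt(expected)

    def test_off_model_sta_is_negative_at_trough_lag(self, off_model):
        """The spike-triggered average of an OFF cell's stimulus is negative
        at the kernel trough (25 ms before the spike)."""
        stim = gaussian_noise_stimulus(epoch_duration=100.0, seed=5)[0]
        spikes = synthetic.simulate_lnp_spikes(off_model, stim, seed=6)
        assert spikes.n_spikes > 1000
        frame_of = np.minimum(
            (spikes.spike_times * stim.frame_rate).astype(int), stim.n_frames - 1
        )
        lag_frames = round(0.025 * stim.frame_rate)
        ok = frame_of >= lag_frames
        sta_at_trough = stim.contrasts[frame_of[ok] - lag_frames].mean()
        assert sta_at_trough < -0.01

    def test_gain_scales_modulation_linearly_before_rectification(self, off_kernel):
        """With the rectifier never engaged, doubling the gain exactly
        doubles the rate modulation around baseline."""
        stim = gaussian_noise_stimulus(sd=0.05, epoch_duration=5.0, seed=2)[0]
        m1 = synthetic.LNPModel(off_kernel, baseline_rate=200.0, gain=1.0)
        m2 = synthetic.LNPModel(off_kernel, baseline_rate=200.0, gain=2.0)
        r1 = synthetic.lnp_rate(m1, stim)
        r2 = synthetic.lnp_rate(m2, stim)
        assert np.all(r1 > 0) and np.all(r2 > 0)
        np.testing.assert_allclose(r2 - 200.0, 2.0 * (r1 - 200.0), rtol=1e-6, atol=1e-8)

    def test_empty_stimulus_rejected(self, off_model):
        with pytest.raises(ValueError):
            synthetic.simulate_lnp_spikes(off_model, StimulusTrace(60.0, 0.5, np.array([])))

    def test_bit_reproducible(self, off_model):
        stim = gaussian_noise_stimulus(epoch_duration=5.0, seed=1)[0]
        a = synthetic.simulate_lnp_spikes(off_model, stim, seed=9)
        b = synthetic.simulate_lnp_spikes(off_model, stim, seed=9)
        np.testing.assert_array_equal(a.spike_times, b.spike_times)


class TestAreaSummationGroundTruth:
    TRUE = DoGParams(r0=5.0, kc=1.27e5, sigma_c=0.01, ks=4973.0, sigma_s=0.04)
    DIAMS = np.geomspace(2.0, 300.0, 12)

    def test_noiseless_equals_model(self):
        curve = synthetic.area_summation_ground_truth(self.TRUE, self.DIAMS, noise_sd=0)
        np.testing.assert_array_equal(curve.f1_amplitudes, dog_predict(self.TRUE, self.DIAMS))

    def test_large_spot_asymptote_is_baseline(self):
        curve = synthetic.area_summation_ground_truth(self.TRUE, [1e4, 1e5], noise_sd=0)
        np.testing.assert_allclose(curve.f1_amplitudes, self.TRUE.r0)

    def test_fit_round_trip_recovers_parameters(self):
        curve = synthetic.area_summation_ground_truth(self.TRUE, self.DIAMS, noise_sd=0)
        fit = fit_dog(curve)
        np.testing.assert_allclose(fit.params.as_array(), self.TRUE.as_array(), rtol=1e-3)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            synthetic.area_summation_ground_truth(self.TRUE, self.DIAMS, noise_sd=-1)


class TestExtracellularTrace:
    def test_no_spikes_is_pure_noise(self):
        tr = synthetic.simulate_extracellular_trace([], duration=1.0, noise_sd=1.0, seed=0)
        assert tr.true_spike_times.size == 0
        assert abs(tr.voltage.std() - 1.0) < 0.05

    def test_single_spike_noiseless_places_template_peak(self):
        tr = synthetic.simulate_extracellular_trace([0.05], duration=0.1, noise_sd=0.0, seed=0)
        peak_sample = int(np.argmax(np.abs(tr.voltage)))
        assert peak_sample == round(0.05 * tr.sample_rate)
        assert np.max(np.abs(tr.voltage)) == pytest.approx(1.0)

    def test_spike_outside_duration_rejected(self):
        with pytest.raises(ValueError):
            synthetic.simulate_extracellular_trace([2.0], duration=1.0)


class TestNeuronGenerator:
    def test_soma_diameter_exact(self):
        spec = synthetic.SyntheticAnnotationSpec(soma_diameter_um=9.0)
        n = synthetic.generate_neuron_annotation(spec, seed=0)
        assert morphometry.soma_diameter(n) == 9.0

    def test_constant_dendrite_profile_measured_exactly(self):
        spec = synthetic.SyntheticAnnotationSpec(dendrite_diameter_um=0.45)
        n = synthetic.generate_neuron_annotation(spec, seed=1)
        assert morphometry.primary_dendrite_diameter(n) == pytest.approx(0.45)

    def test_hi_hii_like_neurons_separate_on_dendrite_diameter(self):
        """Neurons built to the two horizontal-cell dendrite calibers
        (0.627 vs 0.450 um) are cleanly split by a mid-way threshold."""
        hi = synthetic.generate_neuron_annotation(
            synthetic.SyntheticAnnotationSpec(soma_diameter_um=9.148, dendrite_diameter_um=0.627),
            seed=2,
        )
        hii = synthetic.generate_neuron_annotation(
            synthetic.SyntheticAnnotationSpec(soma_diameter_um=8.259, dendrite_diameter_um=0.450),
            seed=3,
        )
        d_hi = morphometry.primary_dendrite_diameter(hi)
        d_hii = morphometry.primary_dendrite_diameter(hii)
        assert abs(d_hi - 0.627) / 0.627 < 0.05
        assert abs(d_hii - 0.450) / 0.450 < 0.05
        threshold = 0.54
        assert d_hii < threshold < d_hi

    def test_soma_exceeds_dendrite_for_realistic_specs(self):
        n = synthetic.generate_neuron_annotation(synthetic.SyntheticAnnotationSpec(), seed=4)
        assert morphometry.soma_diameter(n) >= morphometry.primary_dendrite_diameter(n)


class TestPedicleGenerator:
    def test_circle_area_matches_pi_r_squared(self):
        curve = synthetic.generate_pedicle_curve(np.pi * 25.0, 32, irregularity=0.0, seed=0)
        assert morphometry.pedicle_area(curve) == pytest.approx(np.pi * 25.0, rel=0.01)

    def test_area_scales_with_target(self):
        a1 = morphometry.pedicle_area(synthetic.generate_pedicle_curve(20.0, 16, 0.2, seed=5))
        a2 = morphometry.pedicle_area(synthetic.generate_pedicle_curve(60.0, 16, 0.2, seed=5))
        assert a2 / a1 == pytest.approx(3.0, rel=0.01)

    def test_too_few_control_points_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_pedicle_curve(50.0, 3)

    def test_generator_hits_target_within_half_percent(self):
        for seed in range(3):
            c = synthetic.generate_pedicle_curve(67.7, 16, irregularity=0.3, seed=seed)
            assert abs(morphometry.pedicle_area(c) - 67.7) / 67.7 < 0.005


class TestRibbonCounts:
    def test_zero_sd_returns_rounded_means(self):
        counts, labels = synthetic.generate_ribbon_counts([39.67, 51.75], [0, 0], [3, 4], seed=0)
        assert counts.tolist() == [40, 40, 40, 52, 52, 52, 52]
        assert labels.tolist() == [0, 0, 0, 1, 1, 1, 1]

    def test_single_group_for_null_calibration(self):
        counts, labels = synthetic.generate_ribbon_counts([45.0], [6.0], [7], seed=1)
        assert counts.size == 7 and set(labels) == {0}

    def test_determinism(self):
        a = synthetic.generate_ribbon_counts([40, 52], [1, 1], [3, 4], seed=9)
        b = synthetic.generate_ribbon_counts([40, 52], [1, 1], [3, 4], seed=9)
        np.testing.assert_array_equal(a[0], b[0])

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_ribbon_counts([40], [-1], [3])
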