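import numpy as np
import pytest

import meamask as mm
from meamask.errors import InvalidParameterError
from meamask.spikes import analytic_highpass_gain
from meamask.synthetic import biphasic_template

FS = 20000.0


def _sine_gain(freq_hz: float, spec: mm.FilterSpec) -> float:
    """Steady-state amplitude ratio of a single-pass-filtered sinusoid,
    measured by RMS over whole cycles of the transient-free tail (sample
    peaks underestimate the amplitude when few samples hit the crest)."""
    t = np.arange(int(FS)) / FS  # 1 s
    x = np.sin(2 * np.pi * freq_hz * t)
    y = mm.highpass(x, spec, zero_phase=False)
    tail = y[int(FS) // 2:]  # past the transient; whole cycles at 50+ Hz
    return float(np.sqrt(2.0) * np.std(tail))


class TestHighpass:
    def test_dc_input_is_rejected_to_numerical_zero(self):
        out = mm.highpass(np.full(5000, 1000.0), mm.FilterSpec())
        assert np.max(np.abs(out)) < 1e-6 * 1000.0

    @pytest.mark.parametrize("freq", [50.0, 200.0, 2000.0])
    def test_single_pass_matches_analytic_butterworth(self, freq):
        spec = mm.FilterSpec()
        expected = analytic_highpass_gain(freq, spec.cutoff_hz,
                                          spec.order)[0]
        assert _sine_gain(freq, spec) == pytest.approx(expected, rel=0.01)

    def test_cutoff_gain_is_inverse_sqrt2(self):
        assert _sine_gain(200.0, mm.FilterSpec()) == pytest.approx(
            1 / np.sqrt(2), rel=0.01)

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(InvalidParameterError):
            mm.FilterSpec(cutoff_hz=11000.0)

    def test_trace_shorter_than_warmup_rejected(self):
        with pytest.raises(InvalidParameterError):
            mm.highpass(np.zeros(5), mm.FilterSpec())

    def test_zero_phase_preserves_template_peak_position(self):
        tpl = biphasic_template(FS)
        x = np.zeros(4000)
        x[2000:2000 + tpl.size] = tpl
        y = mm.highpass(x, mm.FilterSpec())
        assert abs(int(np.argmin(y)) - (2000 + int(np.argmin(tpl)))) <= 1


class TestSigma:
    def test_gaussian_noise_std_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.0, 5.0, 1_000_000)
        assert mm.estimate_sigma(x, "std") == pytest.approx(5.0, rel=0.01)
        assert mm.estimate_sigma(x, "mad") == pytest.approx(5.0, rel=0.01)

    def test_zero_trace_gives_zero(self):
        assert mm.estimate_sigma(np.zeros(100)) == 0.0

    def test_mad_is_robust_to_rare_large_spikes(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.0, 5.0, 100000)
        x[::500] -= 300.0
        assert mm.estimate_sigma(x, "mad") < mm.estimate_sigma(x, "std")


class TestDetection:
    def test_noise_only_false_positive_rate_low(self):
        rng = np.random.default_rng(2)
        trace = rng.normal(0.0, 10.0, int(60 * FS))
        filtered = mm.highpass(trace, mm.FilterSpec())
        events = mm.detect_spikes(filtered, fs=FS)
        assert len(events) / 60.0 < 0.2

    def test_single_template_detected_once_at_true_time(self):
        rng = np.random.default_rng(3)
        trace = rng.normal(0.0, 10.0, int(2 * FS))
        tpl = biphasic_template(FS, amplitude_uv=100.0)  # SNR 10
        s0 = 20000
        trace[s0:s0 + tpl.size] += tpl
        true_sample = s0 + int(np.argmin(tpl))
        filtered = mm.highpass(trace, mm.FilterSpec())
        events = mm.detect_spikes(filtered, fs=FS)
        assert len(events) == 1
        assert abs(events[0].sample - true_sample) <= 5

    def test_two_templates_3ms_apart_merge_to_one_event(self):
        trace = np.random.default_rng(4).normal(0.0, 1.0, int(FS))
        tpl = biphasic_template(FS, amplitude_uv=100.0)
        for s0 in (10000, 10000 + 60):  # 3 ms apart at 20 kHz
            trace[s0:s0 + tpl.size] += tpl
        filtered = mm.highpass(trace, mm.FilterSpec())
        events = mm.detect_spikes(filtered, fs=FS)
        assert len(events) == 1

    @pytest.mark.parametrize("scale", [0.1, 1.0, 25.0])
    def test_detection_count_invariant_to_scaling(self, scale):
        trace, _ = mm.simulate_spike_trace(5.0, rate_hz=2.0, seed=5)
        filtered = mm.highpass(trace, mm.FilterSpec())
        base = mm.detect_spikes(filtered, fs=FS)
        scaled = mm.detect_spikes(scale * filtered, fs=FS)
        assert [e.sample for e in base] == [e.sample for e in scaled]

    def test_every_event_satisfies_threshold_post_hoc(self):
        trace, _ = mm.simulate_spike_trace(5.0, rate_hz=2.0, seed=6)
        filtered = mm.highpass(trace, mm.FilterSpec())
        sigma = mm.estimate_sigma(filtered)
        for ev in mm.detect_spikes(filtered, fs=FS):
            assert abs(ev.amplitude) >= 5.0 * sigma
            assert abs(filtered[ev.sample] - ev.amplitude) < 1e-12

    def test_negative_polarity_mode(self):
        trace = np.random.default_rng(7).normal(0.0, 1.0, int(FS))
        trace[5000] += 30.0  # positive-only deflection
        params = mm.SpikeDetectionParams(polarity="negative")
        filtered = mm.highpass(trace, mm.FilterSpec())
        events = mm.detect_spikes(filtered, params, fs=FS)
        assert all(ev.amplitude < 0 for ev in events)

    def test_degenerate_zero_trace_rejected(self):
        with pytest.raises(InvalidParameterError):
            mm.detect_spikes(np.zeros(1000), fs=FS)


class TestSta:
    def _events_at(self, samples, electrode=0):
        return [mm.SpikeEvent(electrode=electrode, sample=int(s),
                              time_s=s / FS, amplitude=-100.0)
                for s in samples]

    def test_repeated_identical_template_recovered_exactly(self):
        tpl = biphasic_template(FS, amplitude_uv=100.0)
        trace = np.zeros(20000)
        centers = []
        for s0 in range(1000, 18000, 1000):
            trace[s0:s0 + tpl.size] += tpl
            centers.append(s0 + int(np.argmin(tpl)))
        sta = mm.spike_triggered_average(trace[None, :], np.array([0]),
                                         self._events_at(centers))
        assert sta.waveforms.shape == (1, 151)
        window = trace[centers[0] - 75:centers[0] + 76]
        np.testing.assert_allclose(sta.waveform_of(0), window, atol=1e-12)
        assert sta.counts[0] == len(centers)

    def test_residual_noise_shrinks_like_sqrt_n(self):
        rng = np.random.default_rng(8)
        tpl = biphasic_template(FS, amplitude_uv=100.0)

        def residual_sd(n):
            spacing = 400
            trace = rng.normal(0.0, 5.0, (n + 2) * spacing)
            centers = []
            for i in range(n):
                s0 = (i + 1) * spacing
                trace[s0:s0 + tpl.size] += tpl
                centers.append(s0 + int(np.argmin(tpl)))
            sta = mm.spike_triggered_average(trace[None, :], np.array([0]),
                                             self._events_at(centers))
            ref = np.zeros(151)
            peak = int(np.argmin(tpl))
            ref[75 - peak:75 - peak + tpl.size] = tpl
            return float(np.std(sta.waveform_of(0) - ref))

        ratio = residual_sd(25) / residual_sd(400)
        assert ratio == pytest.approx(4.0, rel=0.5)  # sqrt(400/25)

    def test_boundary_events_dropped_and_counted(self):
        trace = np.zeros((1, 1000))
        events = self._events_at([10, 500, 990])
        sta = mm.spike_triggered_average(trace, np.array([0]), events)
        assert sta.n_boundary_dropped == 2
        assert sta.counts[0] == 1


class TestFrequencyMap:
    def test_sixty_spikes_in_sixty_seconds_is_one_hz(self, grid):
        events = [mm.SpikeEvent(electrode=7, sample=i, time_s=i / FS,
                                amplitude=-50.0) for i in range(60)]
        fmap = mm.frequency_map(events, 60.0, grid)
        assert fmap.rates.ravel()[7] == 1.0

    def test_no_spikes_gives_zero_on_routed_electrodes(self, grid):
        fmap = mm.frequency_map([], 10.0, grid,
                                routed_electrodes=np.array([3, 4]))
        assert fmap.rates.ravel()[3] == 0.0
        assert np.isnan(fmap.rates.ravel()[5])

    def test_channel_electrodes_fire_faster_than_node_electrodes(
            self, grid, rasterized, activity_recording):
        # the amplitude gain in microchannels makes detection there more
        # reliable, reproducing the observed channel-dominated rate map
        _, groups = rasterized
        rec = activity_recording
        filtered = mm.highpass(rec.traces, mm.FilterSpec(fs_hz=rec.fs))
        events = mm.detect_spikes_multi(filtered, rec.routed_electrodes,
                                        fs=rec.fs)
        fmap = mm.frequency_map(events, rec.duration_s, grid,
                                routed_electrodes=rec.routed_electrodes)
        rates = fmap.rates.ravel()
        chan = np.concatenate([np.asarray(c, dtype=np.int64)
                               for c in groups.channel_electrodes])
        node_routed = [e for e in rec.routed_electrodes
                       if e not in set(map(int, chan))]
        assert (np.nanmean(rates[chan])
                >= np.nanmean(rates[np.asarray(node_routed)]))

    def test_nonpositive_duration_rejected(self, grid):
        with pytest.raises(InvalidParameterError):
            mm.frequency_map([], 0.0, grid)
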