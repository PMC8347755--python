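"""Streaming reference derivation, causal filtering and trough detection."""

import numpy as np
import pytest
from scipy.signal import sosfreqz

from sostim.detect import (
    CausalLowpass,
    DetectorConfig,
    FilterDesignError,
    TroughDetector,
    causal_filtered_reference,
    derive_reference,
    design_lowpass,
    detect_minima,
    filter_delay_at,
)
from sostim.io import restream
from sostim.synth import EEGRecord, SynthParams, generate_record


class TestDeriveReference:
    def test_constant_channels(self):
        data = np.vstack([np.full(10, 10.0)] * 2 + [np.full(10, 2.0)] * 2)
        ref = derive_reference(data, ["F3", "F4", "M1", "M2"], DetectorConfig())
        assert np.allclose(ref, 8.0)

    def test_null_mastoids(self):
        data = np.vstack([np.full(5, 6.0), np.full(5, 10.0),
                          np.zeros(5), np.zeros(5)])
        ref = derive_reference(data, ["F3", "F4", "M1", "M2"], DetectorConfig())
        assert np.allclose(ref, 8.0)

    def test_missing_channel_error(self):
        with pytest.raises(KeyError, match="M1"):
            derive_reference(np.zeros((2, 5)), ["F3", "F4"], DetectorConfig())

    def test_common_mode_noise_cancelled(self, noisy_record):
        """Linked-mastoid re-referencing removes the shared noise component,
        leaving a cleaner SO than any single frontal channel."""
        ref = derive_reference(noisy_record.data, noisy_record.channel_labels,
                               DetectorConfig())
        so = 100.0 * np.cos(2 * np.pi * 0.8 * noisy_record.times)
        # noise proxy: residual power around the SO (broad comparison)
        resid_ref = np.std(ref - so)
        resid_f3 = np.std(noisy_record.channel("F3") - so)
        assert resid_ref < resid_f3


class TestCausalLowpass:
    def test_dc_gain_within_ripple(self):
        lp = CausalLowpass(DetectorConfig(), fs=250)
        out = lp.process(np.full(2000, -50.0))
        # odd-order Chebyshev-I passes DC at unity gain (ripple peaks elsewhere)
        assert out[-1] == pytest.approx(-50.0, rel=1e-6)

    @pytest.mark.parametrize("freq", [1.0, 20.0])
    def test_matches_analytic_frequency_response(self, freq):
        fs = 250.0
        cfg = DetectorConfig()
        sos = design_lowpass(cfg, fs)
        _, h = sosfreqz(sos, worN=[freq], fs=fs)
        t = np.arange(int(20 * fs)) / fs
        out = CausalLowpass(cfg, fs).process(np.sin(2 * np.pi * freq * t))
        # steady-state amplitude on the last quarter
        steady = out[-int(5 * fs):]
        assert np.max(np.abs(steady)) == pytest.approx(np.abs(h[0]), rel=0.02, abs=1e-4)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(FilterDesignError, match="Nyquist"):
            design_lowpass(DetectorConfig(cutoff_hz=60.0), fs=100)


class TestTroughDetector:
    def _run(self, samples, fs=1.0, **kw):
        det = TroughDetector(DetectorConfig(**kw), fs)
        return det.process(np.asarray(samples, dtype=float))

    def test_hand_traced_minimum(self):
        events = self._run([-50, -79, -81, -85, -81, -50])
        assert len(events) == 1
        assert events[0].amplitude == -85
        assert events[0].sample_index == 3

    def test_never_below_threshold_no_events(self):
        t = np.arange(0, 10, 1 / 250)
        assert self._run(-79 * np.cos(2 * np.pi * 0.8 * t), fs=250) == []

    def test_flat_bottom_trough_fires_once(self):
        events = self._run([-50, -85, -85, -85, -50])
        assert len(events) == 1
        assert events[0].sample_index == 1

    def test_one_event_per_period_on_sinusoid(self):
        fs = 250.0
        t = np.arange(int(10 * fs)) / fs
        events = self._run(100 * np.cos(2 * np.pi * 0.8 * t), fs=fs)
        times = np.array([e.time_s for e in events])
        troughs = 0.625 + 1.25 * np.arange(len(times))
        assert len(events) == 8
        assert np.allclose(times, troughs, atol=1 / fs)

    def test_rearm_hysteresis_suppresses_double_dip(self):
        wiggle = [-50, -81, -85, -81, -60, -81, -86, -81, -30]
        assert len(self._run(wiggle)) == 1
        assert len(self._run(wiggle, rearm_uV=None)) == 2


class TestStreamingEquivalence:
    def test_chunk_size_equivalence(self, noisy_record):
        by_one = detect_minima(restream(noisy_record, 1))
        by_16 = detect_minima(restream(noisy_record, 16))
        assert [(e.sample_index, e.amplitude) for e in by_one] == \
               [(e.sample_index, e.amplitude) for e in by_16]

    def test_streaming_equals_offline_scan(self, noisy_record):
        cfg = DetectorConfig()
        streamed = detect_minima(noisy_record, cfg)
        filtered = causal_filtered_reference(noisy_record, cfg)
        offline = TroughDetector(cfg, noisy_record.fs).process(filtered)
        assert [(e.sample_index, e.amplitude) for e in streamed] == \
               [(e.sample_index, e.amplitude) for e in offline]


class TestStageGate:
    def test_events_outside_allowed_stages_dropped(self):
        from sostim.detect import DetectionEvent, stage_gate

        events = [DetectionEvent(t, int(t * 250), -90.0) for t in (10.0, 40.0, 70.0)]
        stages = ["W", "N3", "N2"]  # epochs 0-30, 30-60, 60-90 s
        kept = stage_gate(events, stages)
        assert [e.time_s for e in kept] == [40.0, 70.0]
        assert stage_gate(events, stages, allowed=("N3",))[0].time_s == 40.0


class TestDetectionAccuracy:
    def test_detections_match_truth_troughs_monte_carlo(self):
        """Across seeds, >=90% of ground-truth troughs get exactly one
        detection within 0.1 s (after compensating the causal filter's
        analytic phase delay at the SO frequency)."""
        cfg = DetectorConfig()
        delay = filter_delay_at(cfg, 250.0, 0.8)
        hits = total = 0
        for seed in range(20):
            rec = generate_record(SynthParams(duration_s=120, fs=250,
                                              noise_rms=15.0, seed=seed))
            det = np.array([e.time_s for e in detect_minima(rec, cfg)])
            for t in rec.truth_troughs:
                total += 1
                hits += int(np.sum(np.abs(det - (t + delay)) <= 0.1) == 1)
        assert hits / total >= 0.90

    def test_cross_rate_detection_consistency(self):
        """Detections at 100 Hz stay within one slow-wave of those at 1000 Hz
        after decimation of the same record."""
        from sostim.io import resample_record

        rec = generate_record(SynthParams(duration_s=60, fs=1000,
                                          noise_rms=10.0, seed=13))
        t_hi = np.array([e.time_s for e in detect_minima(rec)])
        t_lo = np.array([e.time_s for e in detect_minima(resample_record(rec, 100))])
        assert len(t_lo) == pytest.approx(len(t_hi), abs=2)
        matched = sum(np.min(np.abs(t_hi - t)) < 0.05 for t in t_lo)
        assert matched >= 0.9 * len(t_lo)
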