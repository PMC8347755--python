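"""Epoching, averaged waveform, Hilbert amplitude, ITPC, TF maps."""

import numpy as np
import pytest
from scipy.signal import hilbert

from sostim.effects import (
    EmptyEpochSetError,
    EpochConfig,
    EpochSet,
    amplitude_timecourse,
    averaged_waveform,
    extract_epochs,
    itpc,
    itpc_crit,
    tf_maps,
)
from sostim.synth import EEGRecord, SynthParams, generate_record


def _epochs_from_matrix(data, fs=100.0, pre_s=2.0):
    """Build an EpochSet directly from trials x samples (full 7 s segments)."""
    data = np.asarray(data, dtype=float)
    n = data.shape[1]
    times_full = (np.arange(n) - int(pre_s * fs)) / fs
    trim = slice(int((pre_s - 1.0) * fs), int((pre_s + 3.0) * fs))
    return EpochSet(narrow_full=data, wide=data, fs=fs, times_full=times_full,
                    trim=trim)


class TestExtractEpochs:
    fs = 100.0

    def _record(self, sig):
        return EEGRecord(np.vstack([sig, sig]), self.fs, ["F3", "F4"])

    def test_artifact_rejection_hand_count(self):
        rng = np.random.default_rng(0)
        sig = 30.0 * np.sin(2 * np.pi * 1.0 * np.arange(int(60 * self.fs)) / self.fs)
        sig += rng.normal(0, 2, sig.size)
        # 400 uV movement-artifact bump (~1 s) inside the second epoch
        tt = np.arange(sig.size) / self.fs
        sig += 400.0 * np.exp(-0.5 * ((tt - 20.5) / 0.25) ** 2)
        rec = self._record(sig)
        epochs = extract_epochs(rec, [10.0, 20.0, 40.0])
        assert epochs.n_trials == 2
        assert epochs.n_rejected == 1

    def test_flat_segment_rejected_by_amin(self):
        rng = np.random.default_rng(1)
        sig = 30.0 * np.sin(2 * np.pi * 1.0 * np.arange(int(60 * self.fs)) / self.fs)
        sig[int(18 * self.fs):int(26 * self.fs)] = 0.0  # flat around t=20 epoch
        rec = self._record(sig)
        epochs = extract_epochs(rec, [10.0, 20.0, 40.0])
        assert epochs.n_trials == 2
        assert epochs.n_rejected == 1

    def test_all_clean_keeps_every_event(self):
        sig = 30.0 * np.sin(2 * np.pi * 1.0 * np.arange(int(60 * self.fs)) / self.fs)
        epochs = extract_epochs(self._record(sig), [10.0, 20.0, 40.0])
        assert epochs.n_trials == 3 and epochs.n_rejected == 0

    def test_all_rejected_raises(self):
        sig = np.zeros(int(60 * self.fs))
        with pytest.raises(EmptyEpochSetError):
            extract_epochs(self._record(sig), [10.0, 20.0])

    def test_trim_window_nested(self):
        with pytest.raises(ValueError, match="nested"):
            EpochConfig(trim_post_s=6.0)

    def test_baseline_inside_trimmed_pre(self):
        with pytest.raises(ValueError, match="baseline"):
            EpochConfig(baseline=(-1.5, -1.2))


class TestWaveformAndAmplitude:
    def test_zero_mean_noise_averages_out(self):
        rng = np.random.default_rng(2)
        epochs = _epochs_from_matrix(rng.normal(0, 10, size=(400, 700)))
        wf = averaged_waveform(epochs)
        assert np.abs(wf).max() < 2.5

    def test_identical_trials_average_is_the_trial(self):
        t = np.arange(700) / 100.0 - 2.0
        trial = 50 * np.sin(2 * np.pi * 1.0 * t)
        epochs = _epochs_from_matrix(np.tile(trial, (8, 1)))
        wf = averaged_waveform(epochs)
        base = trial[epochs.trim] - trial[epochs.trim][
            (epochs.times >= -0.5) & (epochs.times <= -0.35)].mean()
        assert np.allclose(wf, base)

    def test_baseline_mean_is_exactly_zero(self):
        rng = np.random.default_rng(3)
        epochs = _epochs_from_matrix(rng.normal(0, 10, size=(20, 700)) + 40.0)
        wf = averaged_waveform(epochs)
        cfg = EpochConfig()
        sel = (epochs.times >= cfg.baseline[0]) & (epochs.times <= cfg.baseline[1])
        assert wf[sel].mean() == pytest.approx(0.0, abs=1e-12)

    def test_amplitude_of_pure_tone(self):
        t = np.arange(700) / 100.0
        trial = 80 * np.sin(2 * np.pi * 1.0 * t)
        epochs = _epochs_from_matrix(np.tile(trial, (4, 1)))
        amp = np.abs(hilbert(epochs.narrow_full, axis=1))[:, epochs.trim]
        assert np.allclose(amp, 80.0, rtol=0.02)

    def test_amplitude_invariant_to_common_phase_shift(self):
        t = np.arange(700) / 100.0
        a = _epochs_from_matrix(np.vstack([60 * np.sin(2 * np.pi * 1.0 * t + p)
                                           for p in (0.0, 0.5, 1.0, 1.5)]))
        b = _epochs_from_matrix(np.vstack([60 * np.sin(2 * np.pi * 1.0 * t + p + 0.7)
                                           for p in (0.0, 0.5, 1.0, 1.5)]))
        assert np.allclose(amplitude_timecourse(a), amplitude_timecourse(b), atol=0.5)

    def test_zero_signal_zero_amplitude(self):
        epochs = _epochs_from_matrix(np.full((3, 700), 1e-30))
        assert np.allclose(amplitude_timecourse(epochs), 0.0)


class TestITPC:
    def test_identical_trials_give_one(self):
        t = np.arange(700) / 100.0
        epochs = _epochs_from_matrix(np.tile(30 * np.sin(2 * np.pi * t), (6, 1)))
        series = itpc(epochs)
        assert np.allclose(series.values, 1.0, atol=1e-9)

    def test_orthogonal_phases_cancel(self):
        t = np.arange(700) / 100.0
        trials = [np.sin(2 * np.pi * 1.0 * t + p)
                  for p in (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)]
        series = itpc(_epochs_from_matrix(np.vstack(trials)))
        interior = (series.times > 0) & (series.times < 2)
        assert np.all(series.values[interior] < 0.05)

    def test_null_level_matches_analytic_expectation(self):
        """Mean ITPC of n independent-noise trials ~ sqrt(pi)/2/sqrt(n)."""
        rng = np.random.default_rng(4)
        series = itpc(_epochs_from_matrix(rng.normal(size=(100, 700))))
        assert series.values.mean() == pytest.approx(np.sqrt(np.pi) / 2 / 10, rel=0.1)

    def test_invariant_to_per_trial_rescaling(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(12, 700))
        scaled = data * rng.uniform(0.1, 10.0, size=(12, 1))
        assert np.allclose(itpc(_epochs_from_matrix(data)).values,
                           itpc(_epochs_from_matrix(scaled)).values)

    def test_bounds(self):
        rng = np.random.default_rng(6)
        v = itpc(_epochs_from_matrix(rng.normal(size=(5, 700)))).values
        assert np.all((v >= 0) & (v <= 1))

    def test_needs_two_trials(self):
        with pytest.raises(ValueError, match="2 trials"):
            itpc(_epochs_from_matrix(np.zeros((1, 700))))


class TestITPCCrit:
    def test_paper_operating_point(self):
        assert itpc_crit(0.01, 50) == pytest.approx(0.3035, abs=5e-4)

    def test_p_to_one_limit(self):
        assert itpc_crit(1 - 1e-12, 50) == pytest.approx(0.0, abs=1e-5)

    def test_direct_formula_value(self):
        assert itpc_crit(0.05, 100) == pytest.approx(0.1731, abs=5e-5)

    def test_monotone_in_n_and_p(self):
        assert itpc_crit(0.01, 50) > itpc_crit(0.01, 100)
        assert itpc_crit(0.01, 50) > itpc_crit(0.05, 50)

    @pytest.mark.parametrize("p", [0.0, 1.0, -1.0, 2.0])
    def test_domain(self, p):
        with pytest.raises(ValueError):
            itpc_crit(p, 50)


class TestTFMaps:
    def test_tone_burst_localized_power_and_itpc(self):
        fs = 100.0
        t = np.arange(700) / fs - 2.0
        rng = np.random.default_rng(7)
        burst = np.where((t >= 0) & (t <= 1), np.sin(2 * np.pi * 10.0 * (t + 2)), 0.0)
        trials = 5.0 * burst + rng.normal(0, 0.3, size=(20, 700))
        epochs = _epochs_from_matrix(trials)
        tf_i, tf_p = tf_maps(epochs)
        fsel = np.abs(tf_i.freqs - 10.0) <= 0.5
        tin = (tf_i.times >= 0.2) & (tf_i.times <= 0.8)
        tout = tf_i.times <= -0.5
        assert tf_p.values[np.ix_(fsel, tin)].mean() > 10.0  # dB above baseline
        assert tf_i.values[np.ix_(fsel, tin)].mean() > 0.9
        assert tf_i.values[np.ix_(fsel, tout)].mean() < 0.5

    def test_noise_trials_itpc_near_null(self):
        rng = np.random.default_rng(8)
        epochs = _epochs_from_matrix(rng.normal(size=(50, 700)))
        tf_i, _ = tf_maps(epochs)
        null = np.sqrt(np.pi) / 2 / np.sqrt(50)
        assert tf_i.values.mean() == pytest.approx(null, rel=0.15)

    def test_stationary_tone_power_is_zero_db(self):
        t = np.arange(700) / 100.0
        trials = np.vstack([20 * np.sin(2 * np.pi * 3.0 * t + p)
                            for p in np.linspace(0, 2 * np.pi, 10, endpoint=False)])
        _, tf_p = tf_maps(_epochs_from_matrix(trials))
        row = np.argmin(np.abs(tf_p.freqs - 3.0))
        assert np.allclose(tf_p.values[row], 0.0, atol=0.2)

    def test_itpc_map_bounded(self):
        rng = np.random.default_rng(9)
        tf_i, _ = tf_maps(_epochs_from_matrix(rng.normal(size=(8, 700))))
        assert tf_i.values.min() >= 0.0 and tf_i.values.max() <= 1.0


class TestOnSyntheticRecord:
    def test_record_pipeline_runs_end_to_end(self):
        rec = generate_record(SynthParams(duration_s=120, fs=100, noise_rms=15.0,
                                          seed=21))
        stim_times = np.arange(10.0, 110.0, 7.0)
        epochs = extract_epochs(rec, stim_times)
        assert epochs.n_trials > 10
        series = itpc(epochs)
        assert series.n_trials == epochs.n_trials
        wf = averaged_waveform(epochs)
        amp = amplitude_timecourse(epochs)
        assert wf.shape == amp.shape == series.values.shape
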