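"""Stimulation-effect quantification.

Quantifies what acoustic stimulation does to slow-wave activity, per
condition (stim vs sham):

* epoch extraction time-locked to the first stimulus (7 s segments,
  2 s pre / 5 s post, trimmed to 1 s pre / 3 s post to avoid boundary
  effects) with amplitude-limit artifact rejection (Amax = 300 uV,
  Amin = 10 uV),
* the averaged waveform (mixes amplitude and phase locking),
* the Hilbert amplitude time course (phase-independent),
* inter-trial phase clustering, ITPC(t) = |mean_trials exp(i*phase)|
  (amplitude-independent), with the Rayleigh-Z minimum-trial criterion
  ITPC_crit = sqrt(-ln(p)/n), and
* time-frequency ITPC and baseline-normalized power (dB) from a
  Hanning-window STFT whose window length shrinks with frequency.

Waveform/amplitude/power are baseline-corrected against the well
phase-locked pre-stimulus interval [-0.5, -0.35] s.  The per-subject time
courses produced here are the inputs to :mod:`sostim.cluster`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import get_window, hilbert

from sostim.synth import EEGRecord

__all__ = [
    "EpochConfig",
    "EpochSet",
    "ITPCSeries",
    "TFMap",
    "EmptyEpochSetError",
    "extract_epochs",
    "averaged_waveform",
    "amplitude_timecourse",
    "itpc",
    "itpc_crit",
    "tf_maps",
]


class EmptyEpochSetError(RuntimeError):
    """All trials were rejected or no stimulus events were provided."""


@dataclass(frozen=True)
class EpochConfig:
    pre_s: float = 2.0
    post_s: float = 5.0
    trim_pre_s: float = 1.0
    trim_post_s: float = 3.0
    amax_uV: float = 300.0
    amin_uV: float = 10.0
    band: tuple[float, float] = (0.25, 4.0)      # zero-phase, time-course metrics
    tf_band: tuple[float, float] = (0.25, 25.0)  # time-frequency path
    baseline: tuple[float, float] = (-0.5, -0.35)
    channel: Optional[str] = None  # default: Fpz if present, else frontal mean
    # time-frequency grid
    tf_freq_step: float = 0.25
    tf_time_step: float = 0.1
    tf_tmin: float = -1.5
    tf_tmax: float = 4.5
    # window length endpoints: 1 s at 0.1 Hz shrinking to 0.1 s at 25 Hz,
    # interpolated linearly in log-frequency
    tf_win_ref: tuple[float, float] = (0.1, 25.0)   # Hz
    tf_win_len: tuple[float, float] = (1.0, 0.1)    # s

    def __post_init__(self):
        if not (-self.pre_s <= -self.trim_pre_s and self.trim_post_s <= self.post_s):
            raise ValueError("trim window must be nested in the extraction window")
        if not (-self.trim_pre_s <= self.baseline[0] < self.baseline[1] <= 0):
            raise ValueError("baseline must lie within the trimmed pre-stimulus interval")


@dataclass
class EpochSet:
    """Trials x time matrices time-locked to the first stimulus (t = 0).

    ``narrow_full`` holds the full 7 s narrow-band (0.25-4 Hz) segments,
    ``wide`` the full 7 s wide-band (0.25-25 Hz) segments used by the
    time-frequency maps; the same artifact-rejection mask was applied to
    both.  Transforms (Hilbert, STFT) run on the full segments; metric
    time courses are then trimmed to ``times`` (the [-1, +3] s window) so
    segment-boundary effects are excluded from the analyzed interval.
    ``data`` is the trimmed narrow-band view.
    """

    narrow_full: np.ndarray
    wide: np.ndarray
    fs: float
    times_full: np.ndarray
    trim: slice
    condition: str = "stim"
    n_rejected: int = 0

    @property
    def data(self) -> np.ndarray:
        return self.narrow_full[:, self.trim]

    @property
    def times(self) -> np.ndarray:
        return self.times_full[self.trim]

    @property
    def n_trials(self) -> int:
        return self.narrow_full.shape[0]


@dataclass
class ITPCSeries:
    times: np.ndarray
    values: np.ndarray  # in [0, 1]
    n_trials: int
    n_zero_excluded: int = 0


@dataclass
class TFMap:
    freqs: np.ndarray
    times: np.ndarray
    values: np.ndarray  # freqs x times; ITPC in [0, 1] or relative power in dB
    kind: str = "itpc"


def _pick_channel(record: EEGRecord, config: EpochConfig) -> np.ndarray:
    if config.channel is not None:
        return record.channel(config.channel)
    if "Fpz" in record.channel_labels:
        return record.channel("Fpz")
    frontal = [c for c in ("F3", "F4") if c in record.channel_labels]
    if not frontal:
        raise KeyError(f"no Fpz/F3/F4 channel in {record.channel_labels}")
    return np.mean([record.channel(c) for c in frontal], axis=0)


def _zero_phase_band(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Zero-phase FIR band-pass on the continuous signal (filtered before
    cutting because a 0.25 Hz high-pass FIR is longer than one segment)."""
    from mne.filter import filter_data

    return filter_data(x.astype(float), fs, band[0], band[1],
                       fir_design="firwin", phase="zero", verbose="error")


def extract_epochs(record: EEGRecord, stim_times: Sequence[float],
                   config: EpochConfig = EpochConfig(),
                   condition: str = "stim") -> EpochSet:
    """Cut, band-filter and artifact-reject stimulus-locked segments.

    Segments whose wide-band peak amplitude inside the trimmed window
    exceeds Amax, or stays entirely below Amin (flat/disconnected signal),
    are rejected; the rejection count is reported on the returned set.
    """
    stim_times = np.asarray(list(stim_times), dtype=float)
    if stim_times.size == 0:
        raise EmptyEpochSetError("no stimulus events")
    sig = _pick_channel(record, config)
    narrow = _zero_phase_band(sig, record.fs, config.band)
    wide = _zero_phase_band(sig, record.fs, config.tf_band)

    n_pre = int(round(config.pre_s * record.fs))
    n_post = int(round(config.post_s * record.fs))
    trim_lo = int(round((config.pre_s - config.trim_pre_s) * record.fs))
    trim_hi = int(round((config.pre_s + config.trim_post_s) * record.fs))

    seg_narrow, seg_wide = [], []
    n_rejected = 0
    for t in stim_times:
        i0 = int(round(t * record.fs))
        lo, hi = i0 - n_pre, i0 + n_post
        if lo < 0 or hi > record.n_samples:
            continue  # too close to the record edge to cut a full segment
        w = wide[lo:hi]
        peak = np.max(np.abs(w[trim_lo:trim_hi]))
        if peak > config.amax_uV or peak < config.amin_uV:
            n_rejected += 1
            continue
        seg_wide.append(w)
        seg_narrow.append(narrow[lo:hi])
    if not seg_narrow:
        raise EmptyEpochSetError(
            f"no surviving trials ({n_rejected} rejected by amplitude limits)")
    times_full = (np.arange(n_pre + n_post) - n_pre) / record.fs
    return EpochSet(
        narrow_full=np.asarray(seg_narrow),
        wide=np.asarray(seg_wide),
        fs=record.fs,
        times_full=times_full,
        trim=slice(trim_lo, trim_hi),
        condition=condition,
        n_rejected=n_rejected,
    )


def _baseline_cols(times: np.ndarray, config: EpochConfig) -> np.ndarray:
    mask = (times >= config.baseline[0]) & (times <= config.baseline[1])
    if not np.any(mask):
        raise ValueError("baseline window outside the epoch time axis")
    return mask


def averaged_waveform(epochs: EpochSet, config: EpochConfig = EpochConfig()) -> np.ndarray:
    """Trial-averaged waveform, baseline-corrected by subtracting its mean
    over the pre-stimulus baseline window."""
    avg = epochs.data.mean(axis=0)
    return avg - avg[_baseline_cols(epochs.times, config)].mean()


def amplitude_timecourse(epochs: EpochSet, config: EpochConfig = EpochConfig()) -> np.ndarray:
    """Trial-averaged Hilbert amplitude, baseline-corrected by subtraction.

    The analytic signal is computed per full 7 s segment, then trimmed to
    the analysis window, so Hilbert boundary ripple stays outside it.
    """
    amp = np.abs(hilbert(epochs.narrow_full, axis=1))[:, epochs.trim].mean(axis=0)
    return amp - amp[_baseline_cols(epochs.times, config)].mean()


def itpc(epochs: EpochSet) -> ITPCSeries:
    """Inter-trial phase clustering of the stimulus-locked segments.

    Each segment's analytic signal is normalized to unit instantaneous
    amplitude; the magnitude of the trial average of these unit vectors is
    the ITPC, bounded in [0, 1] and invariant to per-trial amplitude
    rescaling.  Samples with zero instantaneous amplitude have no defined
    unit vector and are excluded from that time point's mean.
    """
    if epochs.n_trials < 2:
        raise ValueError("ITPC needs at least 2 trials")
    analytic = hilbert(epochs.narrow_full, axis=1)[:, epochs.trim]
    amp = np.abs(analytic)
    ok = amp > 0
    unit = np.zeros_like(analytic)
    unit[ok] = analytic[ok] / amp[ok]
    counts = ok.sum(axis=0)
    counts_safe = np.maximum(counts, 1)
    values = np.abs(unit.sum(axis=0)) / counts_safe
    values[counts == 0] = np.nan
    return ITPCSeries(times=epochs.times, values=values, n_trials=epochs.n_trials,
                      n_zero_excluded=int((~ok).sum()))


def itpc_crit(p: float, n: int) -> float:
    """Critical ITPC from the Rayleigh-Z approximation, sqrt(-ln(p)/n).

    ITPC values above this threshold reject phase uniformity across ``n``
    trials at level ``p`` (e.g. p=0.01, n=50 gives ~0.3).
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return float(np.sqrt(-np.log(p) / n))


def _tf_window_len_s(f: float, config: EpochConfig) -> float:
    """Window length interpolated linearly in frequency between the
    endpoint pairs (1 s at 0.1 Hz, 0.1 s at 25 Hz).

    Linear (not log-frequency) interpolation keeps mid-band windows long
    enough that coherent spectral leakage of the large slow oscillation
    into higher-frequency bins stays below the noise floor; with shorter
    log-interpolated windows the SO's phase locking bleeds visibly into
    the 5-15 Hz ITPC bins.
    """
    f0, f1 = config.tf_win_ref
    l0, l1 = config.tf_win_len
    x = np.clip((f - f0) / (f1 - f0), 0.0, 1.0)
    return l0 + (l1 - l0) * x


def tf_maps(epochs: EpochSet, config: EpochConfig = EpochConfig()) -> tuple[TFMap, TFMap]:
    """Time-frequency ITPC and baseline-normalized power of the raw 7 s
    segments.

    Hanning-window STFT at 0.1 s hops; the window length interpolates
    linearly in log-frequency from 1 s at 0.1 Hz down to 0.1 s at 25 Hz,
    keeping cycles-per-window roughly graded.  Power is converted to dB
    relative to the mean baseline power of its frequency row.
    """
    freqs = np.arange(config.tf_band[0], config.tf_band[1] + 1e-9, config.tf_freq_step)
    tgrid = np.arange(config.tf_tmin, config.tf_tmax + 1e-9, config.tf_time_step)
    fs = epochs.fs
    data = epochs.wide
    t_full = epochs.times_full
    max_half = _tf_window_len_s(freqs[0], config) / 2.0
    if tgrid[0] - max_half < t_full[0] or tgrid[-1] + max_half > t_full[-1] + 1.0 / fs:
        raise ValueError("STFT window extends beyond the 7 s segment; shrink the time grid")

    itpc_map = np.empty((freqs.size, tgrid.size))
    pow_map = np.empty((freqs.size, tgrid.size))
    centers = np.round((tgrid - t_full[0]) * fs).astype(int)
    for fi, f in enumerate(freqs):
        nwin = max(3, int(round(_tf_window_len_s(f, config) * fs)))
        nwin += 1 - nwin % 2  # odd length, centered windows
        half = nwin // 2
        win = get_window("hann", nwin, fftbins=False)
        tau = (np.arange(nwin) - half) / fs
        kernel = win * np.exp(-2j * np.pi * f * tau) / win.sum()
        idx = centers[:, None] + np.arange(-half, half + 1)[None, :]
        seg = data[:, idx]                       # trials x times x nwin
        coef = seg @ kernel                      # trials x times
        power = np.abs(coef) ** 2
        mag = np.abs(coef)
        unit = np.where(mag > 0, coef / np.where(mag > 0, mag, 1.0), 0.0)
        n_ok = (mag > 0).sum(axis=0)
        itpc_map[fi] = np.abs(unit.sum(axis=0)) / np.maximum(n_ok, 1)
        pow_map[fi] = power.mean(axis=0)

    base = (tgrid >= config.baseline[0]) & (tgrid <= config.baseline[1])
    if not np.any(base):
        raise ValueError("baseline window outside the time-frequency grid")
    ref = pow_map[:, base].mean(axis=1, keepdims=True)
    pow_db = 10.0 * np.log10(pow_map / ref)
    return (
        TFMap(freqs=freqs, times=tgrid, values=itpc_map, kind="itpc"),
        TFMap(freqs=freqs, times=tgrid, values=pow_db, kind="power_db"),
    )
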