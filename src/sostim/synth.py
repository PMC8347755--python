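"""Synthetic NREM-sleep EEG with ground-truth slow-oscillation structure.

Generates multichannel records that emulate deep-sleep polysomnography as
seen by a closed-loop stimulator: frontal channels (F3, F4) carry a
large-amplitude slow oscillation (SO, ~0.5-1 Hz, troughs well below the
-80 uV detection threshold) on top of 1/f background noise, optional
spindle bursts and sub-0.5 Hz drift; mastoids (M1, M2) carry noise only.
Every SO trough time is recorded as ground truth, so detector and phase
metrics downstream are testable without human recordings.

The SO is a sinusoid with per-cycle frequency jitter: cycle boundaries are
laid down one at a time with frequency ``so_freq + eps_c`` (``eps_c``
truncated Gaussian), and the instantaneous phase is piecewise linear
between boundaries.  Background noise is white Gaussian noise shaped to a
1/f^alpha spectrum; part of its power is a common-mode component shared by
all electrodes (cancelled by linked-mastoid re-referencing) and the rest is
independent per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ParameterError",
    "EvokedModel",
    "SynthParams",
    "EEGRecord",
    "generate_record",
    "generate_stim_sham_pair",
]

_VALID_FS = (100, 250, 500, 1000)


class ParameterError(ValueError):
    """Raised when a synthesis parameter is out of its valid range."""


@dataclass(frozen=True)
class EvokedModel:
    """Stimulus-locked response used to build stimulation-condition data.

    The primary effect is a *phase reset*: after each stimulus (plus
    ``latency_s``) the SO phase is pulled toward a canonical trajectory
    ``target_phase_deg + 360 * f_so * (t - t_stim - latency)`` with weight
    ``gain * (1 - exp(-u/rise_s)) * exp(-u/decay_s)`` (u = time since
    latency).  ``gain`` in [0, 1]: 0 leaves the record untouched.  The
    finite rise time is what makes the reset *pure*: it bounds the
    instantaneous-frequency excursion of the pull so the SO stays inside
    the flat passband of the SWA analysis filter, leaving the per-trial
    envelope untouched -- the reset then raises inter-trial phase
    clustering without raising Hilbert amplitude.  An optional additive
    K-complex-like transient (``kcomplex_amp_uV`` times a gamma-shaped
    negative deflection) models an evoked amplitude response instead.
    Overlapping responses sum linearly.
    """

    latency_s: float = 0.5
    gain: float = 0.9
    rise_s: float = 1.0
    decay_s: float = 1.5
    target_phase_deg: float = 0.0
    kcomplex_amp_uV: float = 0.0
    kcomplex_tau_s: float = 0.4


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic deep-sleep EEG generator.

    Defaults describe a stimulation-grade NREM3 segment: 0.8 Hz SOs of
    100 uV amplitude (troughs at -100 uV cross the -80 uV detection
    threshold), 15 uV rms of 1/f noise, no spindles or drift.
    """

    duration_s: float = 120.0
    fs: float = 250.0
    so_freq: float = 0.8            # Hz
    so_amp: float = 100.0           # uV (peak; troughs reach -so_amp)
    so_freq_jitter: float = 0.05    # Hz, per-cycle SD (truncated at 2 SD)
    noise_exponent: float = 1.0     # 1/f^alpha
    noise_rms: float = 15.0         # uV per channel
    common_noise_frac: float = 0.5  # fraction of noise *power* common-mode
    spindle_rate: float = 0.0       # events/min
    spindle_freq: float = 13.0      # Hz
    spindle_amp: float = 20.0       # uV
    spindle_dur: float = 0.5        # s (Gaussian envelope FWHM-ish)
    drift_amp: float = 0.0          # uV
    drift_freq: float = 0.05        # Hz (<0.5 Hz confound)
    evoked: Optional[EvokedModel] = None
    seed: int = 0

    def validate(self) -> None:
        if not self.duration_s > 0:
            raise ParameterError(f"duration_s must be > 0, got {self.duration_s}")
        if self.fs not in _VALID_FS:
            raise ParameterError(f"fs must be one of {_VALID_FS}, got {self.fs}")
        if self.so_amp < 0:
            raise ParameterError(f"so_amp must be >= 0, got {self.so_amp}")
        if self.so_freq <= 0:
            raise ParameterError(f"so_freq must be > 0, got {self.so_freq}")
        if self.so_freq_jitter < 0:
            raise ParameterError(f"so_freq_jitter must be >= 0, got {self.so_freq_jitter}")
        if self.noise_rms < 0:
            raise ParameterError(f"noise_rms must be >= 0, got {self.noise_rms}")
        if not 0.0 <= self.common_noise_frac <= 1.0:
            raise ParameterError(
                f"common_noise_frac must be in [0, 1], got {self.common_noise_frac}")
        if self.spindle_rate < 0:
            raise ParameterError(f"spindle_rate must be >= 0, got {self.spindle_rate}")
        if self.drift_amp < 0:
            raise ParameterError(f"drift_amp must be >= 0, got {self.drift_amp}")


@dataclass
class EEGRecord:
    """Multichannel EEG in microvolts with optional ground truth.

    ``data`` is channels x samples; ``stage_labels`` hold one AASM code per
    30 s epoch; ``truth_troughs`` are SO trough times in seconds.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    stage_labels: Optional[list[str]] = None
    truth_troughs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels must match number of rows")
        if self.stage_labels is not None:
            n_epochs = int(self.n_samples / self.fs / 30.0)
            if len(self.stage_labels) != n_epochs:
                raise ValueError(
                    f"stage_labels length {len(self.stage_labels)} != {n_epochs} 30-s epochs")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channel_labels.index(label)]
        except ValueError:
            raise KeyError(f"channel {label!r} not in {self.channel_labels}") from None


# ---------------------------------------------------------------------------
# internal synthesis pieces


def _so_cycles(params: SynthParams, rng: np.random.Generator):
    """Cycle start times and per-cycle frequencies covering the record."""
    starts = [0.0]
    freqs = []
    t = 0.0
    lo = max(params.so_freq - 2.0 * params.so_freq_jitter, 0.1 * params.so_freq)
    hi = params.so_freq + 2.0 * params.so_freq_jitter
    while t < params.duration_s:
        if params.so_freq_jitter > 0:
            f = float(np.clip(params.so_freq + params.so_freq_jitter * rng.standard_normal(), lo, hi))
        else:
            f = params.so_freq
        freqs.append(f)
        t += 1.0 / f
        starts.append(t)
    return np.asarray(starts), np.asarray(freqs)


def _so_phase(params: SynthParams, rng: np.random.Generator):
    """Unwrapped SO phase at sample times plus analytic trough times.

    Phase is 0 at t=0 (positive peak) and piecewise linear between cycle
    boundaries; the trough of cycle c falls exactly at phase (2c+1)*pi,
    i.e. half a cycle after its start.
    """
    starts, freqs = _so_cycles(params, rng)
    t = np.arange(int(round(params.duration_s * params.fs))) / params.fs
    phase_at_starts = 2.0 * np.pi * np.arange(len(starts))
    phi = np.interp(t, starts, phase_at_starts)
    troughs = starts[:-1] + 0.5 / freqs
    troughs = troughs[troughs < params.duration_s]
    return t, phi, troughs


def _one_over_f(n: int, alpha: float, rms: float, rng: np.random.Generator, fs: float) -> np.ndarray:
    """Gaussian noise spectrally shaped to 1/f^alpha, scaled to target rms."""
    white = rng.standard_normal(n)
    if rms == 0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    x *= rms / np.std(x)
    return x


def _spindles(params: SynthParams, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros_like(t)
    if params.spindle_rate <= 0:
        return out
    n_events = rng.poisson(params.spindle_rate / 60.0 * params.duration_s)
    centers = rng.uniform(0.0, params.duration_s, size=n_events)
    sd = params.spindle_dur / 2.355  # FWHM -> sigma
    for c in np.sort(centers):
        env = np.exp(-0.5 * ((t - c) / sd) ** 2)
        out += params.spindle_amp * env * np.sin(2.0 * np.pi * params.spindle_freq * (t - c))
    return out


def _drift(params: SynthParams, t: np.ndarray) -> np.ndarray:
    if params.drift_amp <= 0:
        return np.zeros_like(t)
    return params.drift_amp * np.sin(2.0 * np.pi * params.drift_freq * t)


def _components(params: SynthParams) -> dict:
    """All seed-driven pieces shared between a stim/sham pair."""
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    r_cycle, r_common, r_f3, r_f4, r_m1, r_m2, r_spin = [
        np.random.default_rng(s) for s in ss.spawn(7)
    ]
    t, phi, troughs = _so_phase(params, r_cycle)
    n = t.size
    rms_c = params.noise_rms * np.sqrt(params.common_noise_frac)
    rms_i = params.noise_rms * np.sqrt(1.0 - params.common_noise_frac)
    comp = {
        "t": t,
        "phi": phi,
        "troughs": troughs,
        "common": _one_over_f(n, params.noise_exponent, rms_c, r_common, params.fs),
        "noise": {
            "F3": _one_over_f(n, params.noise_exponent, rms_i, r_f3, params.fs),
            "F4": _one_over_f(n, params.noise_exponent, rms_i, r_f4, params.fs),
            "M1": _one_over_f(n, params.noise_exponent, rms_i, r_m1, params.fs),
            "M2": _one_over_f(n, params.noise_exponent, rms_i, r_m2, params.fs),
        },
        "spindles": _spindles(params, t, r_spin),
        "drift": _drift(params, t),
    }
    return comp


def _assemble(params: SynthParams, comp: dict, phi: np.ndarray,
              troughs: np.ndarray, extra: Optional[np.ndarray] = None) -> EEGRecord:
    so = params.so_amp * np.cos(phi)
    frontal_extra = comp["spindles"] + comp["drift"]
    if extra is not None:
        frontal_extra = frontal_extra + extra
    rows = []
    for lab in ("F3", "F4"):
        rows.append(so + frontal_extra + comp["common"] + comp["noise"][lab])
    for lab in ("M1", "M2"):
        rows.append(comp["common"] + comp["noise"][lab])
    data = np.vstack(rows)
    n_epochs = int(params.duration_s / 30.0)
    stages = ["N3"] * n_epochs if n_epochs > 0 else None
    return EEGRecord(
        data=data,
        fs=params.fs,
        channel_labels=["F3", "F4", "M1", "M2"],
        stage_labels=stages,
        truth_troughs=np.asarray(troughs, dtype=float),
    )


def generate_record(params: SynthParams) -> EEGRecord:
    """Synthesize one sleep-like record with ground-truth SO troughs.

    Frontal channels carry SO + noise (+ optional spindles/drift), mastoids
    noise only; identical params (including seed) give bit-identical data.
    """
    comp = _components(params)
    return _assemble(params, comp, comp["phi"], comp["troughs"])


def _wrap_rad(x: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - x, 2.0 * np.pi)


def _troughs_from_phase(t: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Trough times of cos(phi) found as sample-grid local minima."""
    x = np.cos(phi)
    interior = (x[1:-1] < x[:-2]) & (x[1:-1] <= x[2:]) & (x[1:-1] < 0)
    return t[1:-1][interior]


def evoked_phase_offset(params: SynthParams, stim_times: Sequence[float],
                        t: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Phase offset (rad) and additive K-complex transient (uV) produced by
    the evoked model; contributions of individual stimuli add linearly."""
    ev = params.evoked
    dphi = np.zeros_like(phi)
    kc = np.zeros_like(phi)
    target = np.deg2rad(ev.target_phase_deg)
    for ts in np.asarray(list(stim_times), dtype=float):
        i0 = int(np.ceil((ts + ev.latency_s) * params.fs))
        if i0 >= t.size:
            continue
        u = t[i0:] - ts - ev.latency_s
        canonical = target + 2.0 * np.pi * params.so_freq * u
        # phase offset continuous in time; its onset value is the minimal wrap
        raw = canonical - phi[i0:]
        cont = np.unwrap(raw)
        cont -= 2.0 * np.pi * np.round((cont[0] - _wrap_rad(raw[0])) / (2.0 * np.pi))
        w = (1.0 - np.exp(-u / ev.rise_s)) * np.exp(-u / ev.decay_s)
        dphi[i0:] += ev.gain * w * cont
        if ev.kcomplex_amp_uV != 0.0:
            g = (u / ev.kcomplex_tau_s) * np.exp(1.0 - u / ev.kcomplex_tau_s)
            kc[i0:] += -ev.kcomplex_amp_uV * g
    return dphi, kc


def generate_stim_sham_pair(params: SynthParams,
                            stim_times: Sequence[float]) -> tuple[EEGRecord, EEGRecord]:
    """Build a (stim, sham) record pair sharing the same background.

    The sham record is the base synthesis; the stim record applies the
    :class:`EvokedModel` after each time in ``stim_times``.  Phase-offset
    contributions of overlapping stimuli add linearly, as do K-complex
    transients.
    """
    if params.evoked is None:
        raise ParameterError("evoked model required to build a stimulation record")
    stim_times = np.asarray(list(stim_times), dtype=float)
    if stim_times.size and (stim_times.min() < 0 or stim_times.max() > params.duration_s):
        raise ParameterError("stim_times must lie within the record duration")
    comp = _components(params)
    sham = _assemble(params, comp, comp["phi"], comp["troughs"])

    t, phi = comp["t"], comp["phi"]
    dphi, kc = evoked_phase_offset(params, stim_times, t, phi)
    phi_stim = phi + dphi
    troughs_stim = _troughs_from_phase(t, phi_stim) if np.any(dphi) else comp["troughs"]
    stim = _assemble(params, comp, phi_stim, troughs_stim,
                     extra=kc if np.any(kc) else None)
    return stim, sham
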