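"""Streaming slow-wave trough detection.

The detection reference is the mean of the frontal channels (F3, F4)
re-referenced to linked mastoids (M1, M2).  It is low-pass filtered with a
causal 3rd-order Chebyshev type-I IIR (1 dB ripple, 4 Hz cut-off) --- an
IIR is used because the real-time loop needs short processing delays ---
and a trough is detected when the filtered sample x0 falls below the
threshold (default -80 uV) and is the minimum of the three-sample window
(x0 < x-1 and x0 <= x+1, so a flat-bottom trough fires once).  Emission
latency is exactly one sample (the rule needs x+1).

After a detection (and after any scheduler-imposed pause) the detector is
re-armed only once the filtered signal has risen above ``rearm_uV``
(default -40 uV), which prevents multiple firings inside one noisy trough.
Set ``rearm_uV=None`` for the bare three-sample rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.signal import cheby1, sosfilt, sosfilt_zi

from sostim.io import SampleStream, restream
from sostim.synth import EEGRecord

__all__ = [
    "DetectorConfig",
    "DetectionEvent",
    "design_lowpass",
    "derive_reference",
    "CausalLowpass",
    "TroughDetector",
    "StreamingDetector",
    "detect_minima",
]


class FilterDesignError(ValueError):
    """Raised when the requested IIR design is invalid or unstable."""


@dataclass(frozen=True)
class DetectorConfig:
    threshold_uV: float = -80.0
    cutoff_hz: float = 4.0
    order: int = 3
    ripple_db: float = 1.0
    frontal_channels: tuple[str, ...] = ("F3", "F4")
    mastoid_channels: tuple[str, ...] = ("M1", "M2")
    reference_channel: Optional[str] = None  # pre-derived single channel
    rearm_uV: Optional[float] = -40.0

    def __post_init__(self):
        if self.threshold_uV >= 0:
            raise ValueError("threshold_uV must be negative")


@dataclass(frozen=True)
class DetectionEvent:
    time_s: float
    sample_index: int
    amplitude: float  # filtered reference at the detected minimum (uV)


def design_lowpass(config: DetectorConfig, fs: float) -> np.ndarray:
    """Second-order sections of the causal detection low-pass."""
    if config.cutoff_hz >= fs / 2:
        raise FilterDesignError(
            f"cutoff {config.cutoff_hz} Hz must be below Nyquist ({fs / 2} Hz)")
    sos = cheby1(config.order, config.ripple_db, config.cutoff_hz, fs=fs, output="sos")
    # stability: all poles inside the unit circle
    poles = np.hstack([np.roots(sec[3:]) for sec in sos])
    if np.any(np.abs(poles) >= 1.0):
        raise FilterDesignError(
            "unstable IIR design; lower the order or raise the cutoff")
    return sos


def derive_reference(data: np.ndarray, channel_labels: Sequence[str],
                     config: DetectorConfig) -> np.ndarray:
    """mean(frontals) - mean(mastoids), computed causally per time point.

    If ``config.reference_channel`` is set, that channel is returned as-is.
    Works on any channels x samples block (streaming chunks included).
    """
    labels = list(channel_labels)

    def rows(names):
        missing = [n for n in names if n not in labels]
        if missing:
            raise KeyError(f"missing channels {missing}; available: {labels}")
        return np.asarray([labels.index(n) for n in names])

    if config.reference_channel is not None:
        return data[rows([config.reference_channel])[0]].astype(float, copy=True)
    ref = data[rows(config.frontal_channels)].mean(axis=0)
    if config.mastoid_channels:
        ref = ref - data[rows(config.mastoid_channels)].mean(axis=0)
    return ref


class CausalLowpass:
    """Sample-by-sample Chebyshev low-pass with persistent state.

    The state is initialized to the step-response steady state of the
    first sample, suppressing the start-up transient.
    """

    def __init__(self, config: DetectorConfig, fs: float):
        self.sos = design_lowpass(config, fs)
        self._zi = None
        self._zi_unit = sosfilt_zi(self.sos)

    def process(self, chunk: np.ndarray) -> np.ndarray:
        chunk = np.atleast_1d(np.asarray(chunk, dtype=float))
        if chunk.size == 0:
            return chunk
        if self._zi is None:
            self._zi = self._zi_unit * chunk[0]
        out, self._zi = sosfilt(self.sos, chunk, zi=self._zi)
        return out


class TroughDetector:
    """Causal three-sample minimum detector with re-arm hysteresis and an
    externally managed pause gate.

    ``on_detect`` (if set) is called with each event and may return a gate
    end time in seconds; detection is disabled until then and, when
    hysteresis is on, until the signal has risen above ``rearm_uV`` after
    the gate reopens.
    """

    def __init__(self, config: DetectorConfig, fs: float,
                 on_detect: Optional[Callable[[DetectionEvent], Optional[float]]] = None):
        self.config = config
        self.fs = fs
        self.on_detect = on_detect
        self._prev1 = None  # x_{i-1}
        self._prev2 = None  # x_{i-2}
        self._i = 0         # index of the incoming sample
        self._armed = True
        self._gate_end = -np.inf  # seconds

    def gate_until(self, t: float) -> None:
        self._gate_end = max(self._gate_end, t)
        if self.config.rearm_uV is not None:
            self._armed = False

    def step(self, x: float) -> Optional[DetectionEvent]:
        """Advance by one filtered sample; maybe emit the event for x_{i-1}."""
        event = None
        i0 = self._i - 1  # candidate index
        t0 = i0 / self.fs
        gated = t0 < self._gate_end
        if not gated and not self._armed and x >= self.config.rearm_uV:
            self._armed = True
        if (
            not gated
            and self._armed
            and self._prev2 is not None
            and self._prev1 < self.config.threshold_uV
            and self._prev1 < self._prev2
            and self._prev1 <= x
        ):
            event = DetectionEvent(time_s=t0, sample_index=i0, amplitude=self._prev1)
            if self.config.rearm_uV is not None:
                self._armed = False
            if self.on_detect is not None:
                gate = self.on_detect(event)
                if gate is not None:
                    self.gate_until(gate)
        self._prev2, self._prev1 = self._prev1, x
        self._i += 1
        return event

    def process(self, filtered: np.ndarray) -> list[DetectionEvent]:
        return [e for e in (self.step(float(x)) for x in filtered) if e is not None]


class StreamingDetector:
    """Reference derivation + causal low-pass + trough detection, chunked.

    Behaves identically for any chunk size: all state is per-sample.
    """

    def __init__(self, config: DetectorConfig, fs: float,
                 channel_labels: Sequence[str],
                 on_detect: Optional[Callable[[DetectionEvent], Optional[float]]] = None):
        self.config = config
        self.fs = fs
        self.channel_labels = list(channel_labels)
        self.lowpass = CausalLowpass(config, fs)
        self.trough = TroughDetector(config, fs, on_detect=on_detect)

    def gate_until(self, t: float) -> None:
        self.trough.gate_until(t)

    def process(self, chunk: np.ndarray) -> tuple[np.ndarray, list[DetectionEvent]]:
        ref = derive_reference(chunk, self.channel_labels, self.config)
        filt = self.lowpass.process(ref)
        return filt, self.trough.process(filt)


def detect_minima(source: Union[EEGRecord, SampleStream],
                  config: DetectorConfig = DetectorConfig(),
                  chunk: int = 4096) -> list[DetectionEvent]:
    """Run the full streaming detector over a record or stream (no
    stimulation scheduler; absence of detections is a valid outcome)."""
    stream = restream(source, chunk) if isinstance(source, EEGRecord) else source
    det = StreamingDetector(config, stream.fs, stream.channel_labels)
    events: list[DetectionEvent] = []
    for block in stream:
        events.extend(det.process(block)[1])
    return events


def stage_gate(events: Sequence[DetectionEvent], stage_labels: Sequence[str],
               allowed: tuple[str, ...] = ("N2", "N3")) -> list[DetectionEvent]:
    """Optional sleep-stage gate: keep only events whose 30 s epoch is
    scored as one of ``allowed`` (stimulation protocols run in stable
    NREM; whether detection was stage-gated is a protocol choice, so the
    gate is exposed rather than applied by default)."""
    out = []
    for ev in events:
        epoch = int(ev.time_s // 30.0)
        if epoch < len(stage_labels) and stage_labels[epoch] in allowed:
            out.append(ev)
    return out


def filter_delay_at(config: DetectorConfig, fs: float, freq_hz: float) -> float:
    """Phase delay (s) of the causal detection low-pass at ``freq_hz``.

    Detected minima lag the underlying SO trough by this amount; offline
    comparisons against ground-truth trough times should compensate it.
    """
    from scipy.signal import sosfreqz

    sos = design_lowpass(config, fs)
    _, h = sosfreqz(sos, worN=[freq_hz], fs=fs)
    return float(-np.angle(h[0]) / (2.0 * np.pi * freq_hz))


def causal_filtered_reference(record: EEGRecord, config: DetectorConfig) -> np.ndarray:
    """Whole-record reference passed through the causal detection filter
    (identical to the streaming path by construction)."""
    ref = derive_reference(record.data, record.channel_labels, config)
    lp = CausalLowpass(config, record.fs)
    return lp.process(ref)
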