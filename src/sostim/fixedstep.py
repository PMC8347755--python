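"""Fixed-step two-pulse stimulation scheduling.

Open-loop timing after each accepted slow-wave detection at time t:
first stimulus at t + 0.350 s (intended to land on the rising phase of the
same wave), second stimulus 1.075 s after the first, then a 2.500 s pause
during which detection is gated off.  Detections arriving while gated are
discarded; the causal filter keeps running so its state stays warm.
Stimulus times are snapped to the sample grid (nearest sample).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from sostim.detect import DetectorConfig, DetectionEvent, StreamingDetector
from sostim.io import Event, EventLog, SampleStream, restream
from sostim.synth import EEGRecord

__all__ = ["FixedStepConfig", "schedule_fixed_step", "run_fixed_step"]

METHOD = "fixed-step"


@dataclass(frozen=True)
class FixedStepConfig:
    delay1_s: float = 0.350
    isi_s: float = 1.075
    pause_s: float = 2.500

    def __post_init__(self):
        for name in ("delay1_s", "isi_s", "pause_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def dead_time_s(self) -> float:
        """Gate length after an accepted detection: delay1 + isi + pause."""
        return self.delay1_s + self.isi_s + self.pause_s


def _snap(t: float, fs: float) -> float:
    return round(t * fs) / fs


def schedule_fixed_step(detections: Sequence[Union[DetectionEvent, float]],
                        config: FixedStepConfig = FixedStepConfig(),
                        fs: float = None) -> EventLog:
    """Apply the fixed-step rule to a pre-computed detection sequence.

    Detections falling inside the gate opened by an earlier accepted
    detection are discarded.  With ``fs`` given, stimulus times snap to
    the sample grid.
    """
    log = EventLog()
    gate_end = -np.inf
    for det in detections:
        t = det.time_s if isinstance(det, DetectionEvent) else float(det)
        amp = det.amplitude if isinstance(det, DetectionEvent) else float("nan")
        if t < gate_end:
            continue
        t1 = t + config.delay1_s
        t2 = t1 + config.isi_s
        if fs is not None:
            t1, t2 = _snap(t1, fs), _snap(t2, fs)
        log.append(Event(t, "detection", METHOD, amp))
        log.append(Event(t1, "stim1", METHOD))
        log.append(Event(t2, "stim2", METHOD))
        gate_end = t + config.dead_time_s
    return log


def run_fixed_step(source: Union[EEGRecord, SampleStream],
                   detector: DetectorConfig = DetectorConfig(),
                   config: FixedStepConfig = FixedStepConfig(),
                   chunk: int = 4096) -> EventLog:
    """Stream a record through detection + fixed-step scheduling.

    The detector itself is gated until stim2 + pause after each accepted
    detection, so gated troughs are never emitted; re-arming additionally
    requires the filtered signal to rise above the detector's re-arm level
    once the gate reopens.
    """
    stream = restream(source, chunk) if isinstance(source, EEGRecord) else source
    fs = stream.fs
    log = EventLog()

    def on_detect(ev: DetectionEvent):
        t1 = _snap(ev.time_s + config.delay1_s, fs)
        t2 = _snap(t1 + config.isi_s, fs)
        log.append(Event(ev.time_s, "detection", METHOD, ev.amplitude))
        log.append(Event(t1, "stim1", METHOD))
        log.append(Event(t2, "stim2", METHOD))
        return ev.time_s + config.dead_time_s

    det = StreamingDetector(detector, fs, stream.channel_labels, on_detect=on_detect)
    for block in stream:
        det.process(block)
    return log
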