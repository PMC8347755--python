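"""Phase-locked-loop phase trackers and the PLL stimulation trigger.

Two digital PLL variants time stimuli at a target phase window of the
slow oscillation:

* **PLL-XOR** -- the binarized EEG reference and the binarized VCO output
  feed an exclusive-or phase detector whose outputs fill two binary
  buffers: PXOR (present, length L=50) and MXOR (memory, length N=1000,
  weighted by k=0.1, giving the memory a twofold higher maximal influence,
  k*N/L = 2).  Every L samples the frequency correction
  ``d_omega = 2*pi*(sum(PXOR) + k*sum(MXOR))`` updates the angular
  frequency ``omega = G*mod(omega_past - d_omega, 2*pi)`` (G=8), and the
  output phase accumulates by ``omega*Ts`` each sample.  The VCO output is
  the square wave sign(sin(phi)).

* **PLL with integral part** -- the reference is first passed through a
  causal linear-phase FIR low-pass (cut-off 0.03 Hz), then drives a
  proportional + integral error term that steers the VCO phase:
  ``Propor = EEGfilt*GP``; ``Integ(n) = Integ(n-1) + GI*EEGfilt*Ts``;
  ``ErrorS = Propor + Integ``; ``phi(n) = phi(n-1) + 2*pi*ErrorS*GVCO*Ts``;
  ``Amp(n) = sin(2*pi*fVCO*t + phi(n))`` with native frequency
  fVCO = 0.8 Hz and GVCO = 1.

Stimulation fires when, after a slow-wave detection has armed the
trigger, the PLL output phase (0 deg at the VCO positive peak) enters the
310-360 deg window (extending the 340 deg target).  If the phase skips
over the window between two samples (fast PLL), that cycle's stimulation
is skipped.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.signal import firwin, lfilter, lfilter_zi

from sostim.detect import DetectorConfig, DetectionEvent, CausalLowpass, derive_reference, TroughDetector
from sostim.fixedstep import FixedStepConfig
from sostim.io import Event, EventLog, SampleStream, restream
from sostim.synth import EEGRecord

__all__ = [
    "xor_gate",
    "PLLXORConfig",
    "PLLXOR",
    "PLLIntegralConfig",
    "PLLIntegral",
    "pll_integral_run",
    "design_fir_prefilter",
    "PLLTriggerConfig",
    "WindowTrigger",
    "run_pll_stimulator",
]

TWO_PI = 2.0 * math.pi


def xor_gate(eeg_bit: int, pll_bit: int) -> int:
    """Exclusive-or phase detector on binarized samples (signal > 0 -> 1)."""
    return int(bool(eeg_bit) != bool(pll_bit))


# ---------------------------------------------------------------------------
# PLL-XOR


@dataclass(frozen=True)
class PLLXORConfig:
    L: int = 50          # present-buffer length; also the omega update period
    N: int = 1000        # memory-buffer length
    k: float = 0.1       # past gain
    G: float = 8.0       # gain coefficient (bounds output frequency at G Hz)
    f_init: float = 0.8  # Hz, initial angular frequency of the VCO


class PLLXOR:
    """Streaming PLL-XOR state (buffers all zeros at start; allow an
    N-sample warm-up before trusting the output phase)."""

    def __init__(self, config: PLLXORConfig, fs: float):
        self.config = config
        self.Ts = 1.0 / fs
        self.pxor: deque[int] = deque([0] * config.L, maxlen=config.L)
        self.mxor: deque[int] = deque([0] * config.N, maxlen=config.N)
        self._sum_p = 0
        self._sum_m = 0
        self.omega = TWO_PI * config.f_init      # rad/s
        self.omega_past = TWO_PI * config.f_init
        self.phi = 0.0                            # accumulated output phase (rad)
        self._n = 0

    @staticmethod
    def delta_omega(sum_p: float, sum_m: float, k: float) -> float:
        """Frequency correction from the buffer sums: 2*pi*(sum_P + k*sum_M)."""
        return TWO_PI * (sum_p + k * sum_m)

    @property
    def output_bit(self) -> int:
        return 1 if math.sin(self.phi) > 0 else 0

    @property
    def phase_deg(self) -> float:
        """Output phase, 0 deg at the VCO positive peak (phi = 90 deg)."""
        return (math.degrees(self.phi) - 90.0) % 360.0

    def step(self, eeg_sample: float) -> "PLLXOR":
        g = xor_gate(1 if eeg_sample > 0 else 0, self.output_bit)
        # oldest present-buffer element migrates into the memory buffer
        migrating = self.pxor[0]
        dropped = self.mxor[0]
        self.pxor.append(g)
        self.mxor.append(migrating)
        self._sum_p += g - migrating
        self._sum_m += migrating - dropped
        self._n += 1
        if self._n % self.config.L == 0:
            d = self.delta_omega(self._sum_p, self._sum_m, self.config.k)
            self.omega = self.config.G * ((self.omega_past - d) % TWO_PI)
            self.omega_past = self.omega
        self.phi += self.omega * self.Ts
        return self


# ---------------------------------------------------------------------------
# PLL with integral part


@dataclass(frozen=True)
class PLLIntegralConfig:
    gp: float = 0.01     # proportional gain GP
    gi: float = 0.01     # integral gain GI
    gvco: float = 1.0    # VCO gain (voltage -> frequency)
    fvco: float = 0.8    # Hz, VCO native frequency (matches the SO band)
    fir_fc: float = 0.03  # Hz, pre-filter cutoff
    fir_taps_per_fs: int = 4  # taps = fir_taps_per_fs * fs + 1


class PLLIntegral:
    """One-sample-at-a-time recursion of the proportional+integral PLL."""

    def __init__(self, config: PLLIntegralConfig, fs: float):
        self.config = config
        self.Ts = 1.0 / fs
        self.integ = 0.0
        self.phi = 0.0
        self.error_s = 0.0
        self.amp = 0.0
        self.t = 0.0

    def step(self, eeg_filt: float, t: float) -> "PLLIntegral":
        c = self.config
        propor = eeg_filt * c.gp
        self.integ = self.integ + c.gi * eeg_filt * self.Ts
        self.error_s = propor + self.integ
        self.phi = self.phi + TWO_PI * self.error_s * c.gvco * self.Ts
        self.t = t
        self.amp = math.sin(TWO_PI * c.fvco * t + self.phi)
        return self

    @property
    def theta(self) -> float:
        """Total VCO phase argument 2*pi*fvco*t + phi (rad)."""
        return TWO_PI * self.config.fvco * self.t + self.phi

    @property
    def phase_deg(self) -> float:
        """Output phase, 0 deg at the VCO positive peak."""
        return (math.degrees(self.theta) - 90.0) % 360.0


def pll_integral_run(eeg_filt: np.ndarray, config: PLLIntegralConfig, fs: float,
                     t0: float = 0.0) -> dict:
    """Vectorized integral-PLL recursion (exactly equals repeated
    :meth:`PLLIntegral.step`; the recursions are cumulative sums)."""
    x = np.asarray(eeg_filt, dtype=float)
    ts = 1.0 / fs
    integ = config.gi * ts * np.cumsum(x)
    error = config.gp * x + integ
    phi = TWO_PI * config.gvco * ts * np.cumsum(error)
    t = t0 + np.arange(x.size) * ts
    theta = TWO_PI * config.fvco * t + phi
    return {
        "t": t,
        "integ": integ,
        "error": error,
        "phi": phi,
        "theta": theta,
        "amp": np.sin(theta),
        "phase_deg": (np.degrees(theta) - 90.0) % 360.0,
    }


def design_fir_prefilter(config: PLLIntegralConfig, fs: float) -> np.ndarray:
    """Causal linear-phase FIR low-pass for the integral PLL input.

    With the default 4*fs+1 taps the group delay is 2 s; at fc = 0.03 Hz
    the transition band is wide, so slow-oscillation energy is only
    partially attenuated (a stable IIR at this cutoff is not practical).
    """
    ntaps = config.fir_taps_per_fs * int(round(fs)) + 1
    return firwin(ntaps, config.fir_fc, fs=fs)


# ---------------------------------------------------------------------------
# trigger


@dataclass(frozen=True)
class PLLTriggerConfig:
    phase_window_deg: tuple[float, float] = (310.0, 360.0)
    target_phase_deg: float = 340.0
    armed_by_detection: bool = True
    warmup_s: Optional[float] = None  # default: XOR N/fs, integral FIR delay

    def __post_init__(self):
        lo, hi = self.phase_window_deg
        if not (0.0 <= lo < hi <= 360.0):
            raise ValueError("phase window must satisfy 0 <= lo < hi <= 360")


class WindowTrigger:
    """Phase-window stimulation trigger with skip detection.

    Fires on the first sample whose phase lies inside [lo, hi) while
    armed; if the phase wraps past the window between two consecutive
    samples without landing in it (fast PLL), that cycle is skipped and
    the trigger stays armed for the next cycle.
    """

    def __init__(self, config: PLLTriggerConfig):
        self.lo, self.hi = config.phase_window_deg
        self.armed = not config.armed_by_detection
        self._armed_by_detection = config.armed_by_detection
        self._prev = None
        self.n_skipped = 0

    def arm(self) -> None:
        self.armed = True

    def update(self, phase_deg: float) -> bool:
        """Advance by one phase sample; True when a stimulus fires."""
        fire = False
        if self.armed:
            in_window = self.lo <= phase_deg < self.hi
            wrapped = self._prev is not None and phase_deg < self._prev
            if in_window:
                fire = True
                if self._armed_by_detection:
                    self.armed = False
            elif wrapped and self._prev < self.lo:
                self.n_skipped += 1  # jumped over the window in one sample
        self._prev = phase_deg
        return fire


class _CausalFIR:
    def __init__(self, taps: np.ndarray):
        self.b = taps
        self._zi = None

    def process(self, chunk: np.ndarray) -> np.ndarray:
        if chunk.size == 0:
            return chunk
        if self._zi is None:
            self._zi = lfilter_zi(self.b, [1.0]) * chunk[0]
        out, self._zi = lfilter(self.b, [1.0], chunk, zi=self._zi)
        return out


def run_pll_stimulator(source: Union[EEGRecord, SampleStream],
                       variant: str = "xor",
                       detector: DetectorConfig = DetectorConfig(),
                       trigger: PLLTriggerConfig = PLLTriggerConfig(),
                       xor_config: PLLXORConfig = PLLXORConfig(),
                       integral_config: PLLIntegralConfig = PLLIntegralConfig(),
                       pause_s: float = FixedStepConfig().pause_s,
                       chunk: int = 4096,
                       collect_output: bool = False):
    """Stream a record through detection + PLL-triggered stimulation.

    The PLL advances every sample.  A slow-wave detection arms the
    trigger (when ``armed_by_detection``); the first subsequent sample
    whose PLL phase lies inside the window fires a ``pll_stim`` event with
    the trigger phase recorded, after which the detector is gated for
    ``pause_s`` and must re-arm.  Returns the event log (and, with
    ``collect_output=True``, the PLL output sample array for diagnostics).
    """
    if variant not in ("xor", "integral"):
        raise ValueError("variant must be 'xor' or 'integral'")
    stream = restream(source, chunk) if isinstance(source, EEGRecord) else source
    fs = stream.fs
    method = f"pll-{variant}"
    log = EventLog()
    pending: list[Event] = []

    lowpass = CausalLowpass(detector, fs)
    trough = TroughDetector(detector, fs)

    if variant == "xor":
        pll = PLLXOR(xor_config, fs)
        warmup = trigger.warmup_s if trigger.warmup_s is not None else xor_config.N / fs
        prefilter = None
    else:
        pll = PLLIntegral(integral_config, fs)
        taps = design_fir_prefilter(integral_config, fs)
        prefilter = _CausalFIR(taps)
        group_delay = (taps.size - 1) / 2.0 / fs
        warmup = trigger.warmup_s if trigger.warmup_s is not None else group_delay

    gate = WindowTrigger(trigger)
    out = [] if collect_output else None
    i = 0

    for block in stream:
        ref = derive_reference(block, stream.channel_labels, detector)
        filt = lowpass.process(ref)
        pll_in = prefilter.process(ref) if prefilter is not None else filt
        for j in range(filt.size):
            t = i / fs
            det_ev = trough.step(float(filt[j]))
            if det_ev is not None:
                pending.append(Event(det_ev.time_s, "detection", method, det_ev.amplitude))
                if trigger.armed_by_detection:
                    gate.arm()
            if variant == "xor":
                pll.step(float(pll_in[j]))
            else:
                pll.step(float(pll_in[j]), t)
            phase = pll.phase_deg
            if out is not None:
                out.append(math.sin(pll.phi) if variant == "xor" else pll.amp)
            if t >= warmup and gate.update(phase):
                pending.append(Event(t, "pll_stim", method, phase))
                trough.gate_until(t + pause_s)
            i += 1
    for ev in sorted(pending, key=lambda e: e.time_s):
        log.append(ev)
    if collect_output:
        return log, np.asarray(out)
    return log
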