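"""Offline Hilbert-phase evaluation and circular statistics.

Phase convention used throughout the package: 0 deg at the signal's
positive peak, 180 deg at the trough, rising phase = (180, 360) deg.  This
is the argument of the analytic signal (Hilbert transform) of a
cosine-referenced waveform, mapped to [0, 360).

Detection/stimulation timing is judged by sampling the instantaneous
phase of the filtered detection reference at event times.  By default the
*same causal* 4 Hz low-pass as the real-time path is used, so a detected
trough is a true local minimum of the evaluated signal and reads ~180 deg;
zero-phase filtering is available for analyses where filter lag matters.

Descriptive circular statistics follow the standard resultant-vector
estimators: circular variance V = 1 - R, angular deviation
sqrt(2*(1-R)), and the Fisher/Pewsey moment-based skewness and kurtosis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import hilbert, sosfiltfilt

from sostim.detect import DetectorConfig, CausalLowpass, design_lowpass, derive_reference
from sostim.synth import EEGRecord

__all__ = [
    "PhaseSeries",
    "CircularSummary",
    "instantaneous_phase",
    "phase_at_events",
    "circular_summary",
    "polar_histogram",
    "plot_polar_histogram",
]


@dataclass
class PhaseSeries:
    """Event phases in degrees, all in [0, 360) (0 deg = positive peak)."""

    phases: np.ndarray

    def __post_init__(self):
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.size and (self.phases.min() < 0 or self.phases.max() >= 360):
            raise ValueError("phases must lie in [0, 360)")

    def __len__(self) -> int:
        return self.phases.size


@dataclass(frozen=True)
class CircularSummary:
    mean_deg: float
    variance: float      # circular variance 1 - R, unitless in [0, 1]
    std_deg: float       # angular deviation sqrt(2*(1-R)), degrees
    sem_deg: float
    skewness: float
    kurtosis: float
    n: int
    mean_undefined: bool = False


def _filtered_signal(x: np.ndarray, fs: float, config: DetectorConfig,
                     mode: str) -> np.ndarray:
    if mode == "none":
        return np.asarray(x, dtype=float)
    if mode == "causal":
        return CausalLowpass(config, fs).process(np.asarray(x, dtype=float))
    if mode == "zero-phase":
        sos = design_lowpass(config, fs)
        return sosfiltfilt(sos, np.asarray(x, dtype=float))
    raise ValueError("filter mode must be 'causal', 'zero-phase' or 'none'")


def instantaneous_phase(signal: np.ndarray, fs: float,
                        config: DetectorConfig = DetectorConfig(),
                        filter_mode: str = "causal") -> np.ndarray:
    """Instantaneous phase (degrees, [0, 360)) of a single-channel signal.

    The signal is band-limited by the 4 Hz low-pass before the Hilbert
    transform (``filter_mode='none'`` skips filtering for already
    band-limited input).
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise ValueError("signal must contain at least 2 samples")
    y = _filtered_signal(x, fs, config, filter_mode)
    return np.mod(np.degrees(np.angle(hilbert(y))), 360.0)


def phase_at_events(record: EEGRecord, event_times_s: Sequence[float],
                    config: DetectorConfig = DetectorConfig(),
                    filter_mode: str = "causal",
                    channel: Optional[str] = None) -> PhaseSeries:
    """Instantaneous phase of the detection reference at each event time
    (nearest sample)."""
    times = np.asarray(list(event_times_s), dtype=float)
    if times.size == 0:
        return PhaseSeries(np.empty(0))
    idx = np.round(times * record.fs).astype(int)
    bad = (idx < 0) | (idx >= record.n_samples)
    if np.any(bad):
        raise IndexError(f"events outside the signal span: {times[bad].tolist()}")
    if channel is not None:
        ref = record.channel(channel)
    else:
        ref = derive_reference(record.data, record.channel_labels, config)
    phase = instantaneous_phase(ref, record.fs, config, filter_mode)
    return PhaseSeries(phase[idx])


def circular_summary(series: PhaseSeries) -> CircularSummary:
    """Resultant-vector descriptive statistics of event phases.

    When R = 0 (e.g. perfectly antipodal phases) the circular mean is
    undefined; the summary is returned with ``mean_undefined=True`` and a
    NaN mean.
    """
    theta = np.deg2rad(np.asarray(series.phases, dtype=float))
    n = theta.size
    if n < 1:
        raise ValueError("need at least one phase")
    z1 = np.mean(np.exp(1j * theta))
    r = float(np.abs(z1))
    mu = float(np.angle(z1))
    undefined = r < 1e-12
    mean_deg = float("nan") if undefined else np.mod(np.degrees(mu), 360.0)
    variance = 1.0 - r
    std_deg = float(np.degrees(np.sqrt(max(2.0 * (1.0 - r), 0.0))))
    sem_deg = std_deg / np.sqrt(n)
    z2 = np.mean(np.exp(2j * theta))
    r2, mu2 = float(np.abs(z2)), float(np.angle(z2))
    if r >= 1.0 - 1e-12:  # degenerate (all phases equal): no dispersion
        skew = 0.0
        kurt = 0.0
    else:
        skew = r2 * np.sin(mu2 - 2.0 * mu) / (1.0 - r) ** 1.5
        kurt = (r2 * np.cos(mu2 - 2.0 * mu) - r ** 4) / (1.0 - r) ** 2
    return CircularSummary(
        mean_deg=mean_deg,
        variance=float(variance),
        std_deg=std_deg,
        sem_deg=float(sem_deg),
        skewness=float(skew),
        kurtosis=float(kurt),
        n=n,
        mean_undefined=undefined,
    )


def polar_histogram(series: PhaseSeries, nbins: int = 20):
    """Counts over equal half-open bins [a, b) partitioning [0, 360).

    Returns ``(counts, edges)``; the counts always sum to ``len(series)``.
    """
    if nbins < 1:
        raise ValueError("nbins must be >= 1")
    edges = np.linspace(0.0, 360.0, nbins + 1)
    # np.histogram closes the last bin; phases are < 360 so the convention
    # [a, b) holds for every bin.
    counts, _ = np.histogram(series.phases, bins=edges)
    return counts, edges


def plot_polar_histogram(series: PhaseSeries, nbins: int = 20, ax=None):
    """Polar histogram with the mean-phase radius line (red)."""
    import matplotlib.pyplot as plt

    counts, edges = polar_histogram(series, nbins)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    centers = np.deg2rad((edges[:-1] + edges[1:]) / 2.0)
    ax.bar(centers, counts, width=np.deg2rad(360.0 / nbins), alpha=0.7)
    summ = circular_summary(series)
    if not summ.mean_undefined and counts.sum() > 0:
        ax.plot([0, np.deg2rad(summ.mean_deg)], [0, counts.max()], color="red", lw=2)
    return ax
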