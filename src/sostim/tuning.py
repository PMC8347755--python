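"""Grid-search tuning of the integral-PLL gains.

The proportional and integral gains (GP, GI) are varied over a
logarithmic grid spanning [1e-4, 1e2] and the full detection + PLL
stimulator is simulated on training records at Fs = 100 Hz for every grid
point.  Each candidate is scored by one of three criteria (all mean
squared errors pooled over every stimulation event of every training
record):

* ``phase``      -- squared angular distance between the EEG phase at
  stimulation and the desired phase (312 deg), in deg^2.  Differences are
  wrapped to (-180, 180] before squaring.
* ``time-phase`` -- squared time distance between the stimulation and the
  earliest post-detection time at which the EEG phase reaches the desired
  phase, in s^2 (guards against the PLL fitting slow drifts at
  aliasing-like frequencies).
* ``fixed-time`` -- squared distance from detection + 0.35 s, in s^2
  (the fixed-step method's timing used as the reference).

Besides the argmin, the result reports per-record stimulation counts and
a spectral summary (dominant frequency and -6 dB range) of the winning
PLL output, which is how over-fast or drift-locked solutions show up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.signal import periodogram

from sostim.detect import DetectorConfig, derive_reference
from sostim.io import EventLog
from sostim.phase import instantaneous_phase
from sostim.pll import PLLIntegralConfig, PLLTriggerConfig, run_pll_stimulator
from sostim.synth import EEGRecord

__all__ = [
    "UndefinedCriterionError",
    "AttributionError",
    "TuningSpec",
    "TuningResult",
    "criterion_phase",
    "criterion_time_phase",
    "criterion_fixed_time",
    "dominant_frequency",
    "grid_search",
]


class UndefinedCriterionError(RuntimeError):
    """The criterion has no value (no stimulation events)."""


class AttributionError(RuntimeError):
    """A stimulation event has no preceding detection to attribute it to."""


def _wrap_deg(x: np.ndarray) -> np.ndarray:
    """Wrap angle differences to (-180, 180] degrees."""
    return 180.0 - np.mod(180.0 - np.asarray(x, dtype=float), 360.0)


def criterion_phase(stim_phases_deg: Sequence[float],
                    desired_phase_deg: float = 312.0) -> float:
    """Mean squared wrapped angular error (deg^2) of stimulation phases."""
    phases = np.asarray(list(stim_phases_deg), dtype=float)
    if phases.size == 0:
        raise UndefinedCriterionError("no stimulation events")
    return float(np.mean(_wrap_deg(desired_phase_deg - phases) ** 2))


def _attribute(stim_times: np.ndarray, detection_times: np.ndarray) -> np.ndarray:
    """Index of the latest detection at or before each stimulation."""
    idx = np.searchsorted(detection_times, stim_times, side="right") - 1
    if np.any(idx < 0):
        bad = stim_times[idx < 0]
        raise AttributionError(f"stimulations before any detection: {bad.tolist()}")
    return idx


def _phase_crossing_time(phase_unwrapped: np.ndarray, fs: float, i_start: int,
                         desired_deg: float, horizon_s: float,
                         before: bool = False) -> Optional[float]:
    """Earliest time after sample ``i_start`` (or latest before, with
    ``before=True``) at which the unwrapped phase reaches the desired
    angle (mod 360)."""
    d = np.deg2rad(desired_deg % 360.0)
    p0 = phase_unwrapped[i_start]
    if not before:
        level = p0 + (d - p0) % (2.0 * np.pi)
        stop = min(phase_unwrapped.size, i_start + int(round(horizon_s * fs)) + 1)
        seg = phase_unwrapped[i_start:stop]
        hits = np.flatnonzero(seg >= level)
        if hits.size == 0:
            return None
        return (i_start + hits[0]) / fs
    level = p0 - (p0 - d) % (2.0 * np.pi)
    start = max(0, i_start - int(round(horizon_s * fs)))
    seg = phase_unwrapped[start:i_start + 1]
    hits = np.flatnonzero(seg >= level)
    if hits.size == 0:
        return None
    return (start + hits[0]) / fs


def criterion_time_phase(stim_times: Sequence[float], detection_times: Sequence[float],
                         phase_unwrapped: np.ndarray, fs: float,
                         desired_phase_deg: float = 312.0,
                         horizon_s: float = 5.0,
                         before_detection: bool = False) -> tuple[float, int]:
    """Mean squared time error (s^2) against the desired-phase crossing.

    For each stimulation the reference time is the earliest time after its
    detection at which the EEG phase reaches ``desired_phase_deg``
    (``before_detection=True`` selects the literal pre-detection reading
    instead).  Events with no crossing inside the horizon are excluded;
    their count is returned alongside the mse.
    """
    stim = np.asarray(list(stim_times), dtype=float)
    det = np.asarray(list(detection_times), dtype=float)
    if stim.size == 0:
        raise UndefinedCriterionError("no stimulation events")
    idx = _attribute(stim, det)
    errors, excluded = [], 0
    for t_stim, i in zip(stim, idx):
        i_det = int(round(det[i] * fs))
        t_ref = _phase_crossing_time(phase_unwrapped, fs, i_det, desired_phase_deg,
                                     horizon_s, before=before_detection)
        if t_ref is None:
            excluded += 1
            continue
        errors.append((t_ref - t_stim) ** 2)
    if not errors:
        raise UndefinedCriterionError("no stimulation with a phase crossing in the horizon")
    return float(np.mean(errors)), excluded


def criterion_fixed_time(stim_times: Sequence[float], detection_times: Sequence[float],
                         desired_delay_s: float = 0.35) -> float:
    """Mean squared error (s^2) from detection + desired delay."""
    stim = np.asarray(list(stim_times), dtype=float)
    det = np.asarray(list(detection_times), dtype=float)
    if stim.size == 0:
        raise UndefinedCriterionError("no stimulation events")
    idx = _attribute(stim, det)
    return float(np.mean((det[idx] + desired_delay_s - stim) ** 2))


def dominant_frequency(x: np.ndarray, fs: float) -> tuple[float, tuple[float, float]]:
    """Dominant narrowband frequency of a signal and its -6 dB range.

    Returns ``(f_peak, (f_lo, f_hi))`` from the periodogram (DC excluded);
    the range is the contiguous band around the peak with power >= 1/4 of
    the peak power.
    """
    f, pxx = periodogram(np.asarray(x, dtype=float), fs=fs)
    pxx[0] = 0.0
    i = int(np.argmax(pxx))
    thresh = pxx[i] / 4.0
    lo = i
    while lo > 1 and pxx[lo - 1] >= thresh:
        lo -= 1
    hi = i
    while hi < pxx.size - 1 and pxx[hi + 1] >= thresh:
        hi += 1
    return float(f[i]), (float(f[lo]), float(f[hi]))


@dataclass
class TuningSpec:
    training_records: list[EEGRecord]
    criterion: str = "fixed-time"  # {'phase', 'time-phase', 'fixed-time'}
    gp_grid: np.ndarray = field(default_factory=lambda: np.logspace(-4, 2, 20))
    gi_grid: np.ndarray = field(default_factory=lambda: np.logspace(-4, 2, 20))
    desired_phase_deg: float = 312.0
    desired_delay_s: float = 0.35
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    trigger: PLLTriggerConfig = field(default_factory=PLLTriggerConfig)
    base_config: PLLIntegralConfig = field(default_factory=PLLIntegralConfig)
    horizon_s: float = 5.0

    def __post_init__(self):
        if self.criterion not in ("phase", "time-phase", "fixed-time"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        for g in (self.gp_grid, self.gi_grid):
            g = np.asarray(g, dtype=float)
            if g.size and (g.min() < 1e-4 - 1e-12 or g.max() > 1e2 + 1e-9):
                raise ValueError("gain grid must lie within [1e-4, 1e2]")


@dataclass
class TuningResult:
    table: "np.recarray"          # fields gp, gi, mse, n_events
    best_gp: float
    best_gi: float
    best_mse: float
    tie: bool
    stim_counts: list[int]        # per training record, at the best point
    dominant_freq_hz: float
    spectral_range_hz: tuple[float, float]
    n_excluded: int = 0


def _pooled_criterion(spec: TuningSpec, logs: list[EventLog],
                      phase_tracks: list[np.ndarray], fs_list: list[float]):
    """Pool events of all records and evaluate the chosen criterion."""
    excluded = 0
    if spec.criterion == "phase":
        phases = []
        for log, track, fs in zip(logs, phase_tracks, fs_list):
            stim = log.times("pll_stim")
            idx = np.round(stim * fs).astype(int)
            wrapped = np.mod(np.degrees(track[idx]), 360.0)
            phases.extend(wrapped.tolist())
        return criterion_phase(phases, spec.desired_phase_deg), excluded
    if spec.criterion == "fixed-time":
        errs, n = 0.0, 0
        for log in logs:
            stim = log.times("pll_stim")
            if stim.size == 0:
                continue
            det = log.times("detection")
            idx = _attribute(stim, det)
            errs += np.sum((det[idx] + spec.desired_delay_s - stim) ** 2)
            n += stim.size
        if n == 0:
            raise UndefinedCriterionError("no stimulation events")
        return float(errs / n), excluded
    # time-phase
    errs, n = 0.0, 0
    for log, track, fs in zip(logs, phase_tracks, fs_list):
        stim = log.times("pll_stim")
        if stim.size == 0:
            continue
        det = log.times("detection")
        idx = _attribute(stim, det)
        for t_stim, i in zip(stim, idx):
            t_ref = _phase_crossing_time(track, fs, int(round(det[i] * fs)),
                                         spec.desired_phase_deg, spec.horizon_s)
            if t_ref is None:
                excluded += 1
                continue
            errs += (t_ref - t_stim) ** 2
            n += 1
    if n == 0:
        raise UndefinedCriterionError("no stimulation events")
    return float(errs / n), excluded


def grid_search(spec: TuningSpec) -> TuningResult:
    """Exhaustive (GP, GI) grid search of the integral-PLL stimulator.

    Grid points producing zero events across all records get an undefined
    (NaN) mse, are excluded from the argmin, and trigger a warning.  Ties
    resolve to the first point in deterministic grid order (gp-major) and
    are flagged.
    """
    if not spec.training_records:
        raise ValueError("need at least one training record")
    # the EEG phase track of each record does not depend on the gains
    tracks, fs_list = [], []
    for rec in spec.training_records:
        ref = derive_reference(rec.data, rec.channel_labels, spec.detector)
        deg = instantaneous_phase(ref, rec.fs, spec.detector, filter_mode="causal")
        tracks.append(np.unwrap(np.deg2rad(deg)))
        fs_list.append(rec.fs)

    rows = []
    results = {}
    total_excluded = 0
    for gp in np.asarray(spec.gp_grid, dtype=float):
        for gi in np.asarray(spec.gi_grid, dtype=float):
            cfg = replace(spec.base_config, gp=float(gp), gi=float(gi))
            logs = [
                run_pll_stimulator(rec, variant="integral", detector=spec.detector,
                                   trigger=spec.trigger, integral_config=cfg)
                for rec in spec.training_records
            ]
            n_events = int(sum(len(log.of_kind("pll_stim")) for log in logs))
            try:
                mse, excl = _pooled_criterion(spec, logs, tracks, fs_list)
            except UndefinedCriterionError:
                warnings.warn(f"grid point (gp={gp:g}, gi={gi:g}) produced no events; "
                              "mse undefined", stacklevel=2)
                mse, excl = float("nan"), 0
            total_excluded += excl
            rows.append((float(gp), float(gi), mse, n_events))
            results[(float(gp), float(gi))] = logs

    table = np.rec.fromrecords(
        rows, names="gp,gi,mse,n_events", formats="f8,f8,f8,i8")
    mses = table.mse
    defined = np.flatnonzero(~np.isnan(mses))
    if defined.size == 0:
        raise UndefinedCriterionError("every grid point produced zero events")
    best_i = int(defined[np.argmin(mses[defined])])
    best_mse = float(mses[best_i])
    tie = bool(np.sum(np.isclose(mses[defined], best_mse, rtol=0, atol=0)) > 1)
    best_gp, best_gi = float(table.gp[best_i]), float(table.gi[best_i])

    best_logs = results[(best_gp, best_gi)]
    stim_counts = [len(log.of_kind("pll_stim")) for log in best_logs]
    best_cfg = replace(spec.base_config, gp=best_gp, gi=best_gi)
    _, output = run_pll_stimulator(spec.training_records[0], variant="integral",
                                   detector=spec.detector, trigger=spec.trigger,
                                   integral_config=best_cfg, collect_output=True)
    f_peak, f_range = dominant_frequency(output, fs_list[0])
    return TuningResult(table=table, best_gp=best_gp, best_gi=best_gi, best_mse=best_mse,
                        tie=tie, stim_counts=stim_counts, dominant_freq_hz=f_peak,
                        spectral_range_hz=f_range, n_excluded=total_excluded)
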