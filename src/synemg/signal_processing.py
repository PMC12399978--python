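"""Conditioning of raw EMG and kinematic series into normalized cycle data.

Raw surface EMG (2000 Hz) is band-pass filtered (50-300 Hz), full-wave
rectified and linearly enveloped; each muscle's envelope is normalized by
its maximum over all trials.  Kinematic series (200 Hz) are low-pass
filtered at 10 Hz.  Double-poling cycles are segmented from the pole-tip
height (poling phase: highest to lowest marker position; recovery: back up
to the next peak) and every series is resampled to a fixed 100-point grid,
50 points per phase.

All filters are applied forward-backward (zero phase), so the effective
order doubles; the envelope low-pass cutoff (6 Hz) is a package default,
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = ["RawChannelSeries", "DpCycle", "filter_emg", "filter_kinematics",
           "normalize_emg", "segment_cycles", "time_normalize",
           "N_GRID", "N_PHASE"]

N_GRID = 100   # points per normalized cycle
N_PHASE = 50   # points per phase (poling, recovery)


@dataclass
class RawChannelSeries:
    """A uniformly sampled single-channel time series."""

    samples: np.ndarray
    rate: float
    label: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.shape[0]) / self.rate


@dataclass
class DpCycle:
    """One double-poling cycle: [start, transition) poling, [transition, end) recovery."""

    start: int
    transition: int
    end: int
    rate: float

    def __post_init__(self):
        if not self.start < self.transition < self.end:
            raise ValueError("cycle boundaries must satisfy start < transition < end")

    @property
    def duration(self) -> float:
        return (self.end - self.start) / self.rate


def filter_emg(raw: RawChannelSeries, band=(50.0, 300.0), order: int = 4,
               envelope_cutoff: float = 6.0) -> RawChannelSeries:
    """Band-pass, rectify and envelope a raw EMG channel (zero phase).

    Requires the sampling rate to support the band's upper edge
    (rate >= 2 * band[1]).
    """
    lo, hi = band
    if raw.rate < 2 * hi:
        raise ValueError(
            f"sampling rate {raw.rate} Hz too low for a {lo}-{hi} Hz band")
    nyq = raw.rate / 2
    sos_bp = sps.butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    sos_lp = sps.butter(order, envelope_cutoff / nyq, btype="lowpass", output="sos")
    band_passed = sps.sosfiltfilt(sos_bp, raw.samples)
    env = sps.sosfiltfilt(sos_lp, np.abs(band_passed))
    return RawChannelSeries(np.maximum(env, 0.0), raw.rate, raw.label)


def filter_kinematics(raw: RawChannelSeries, cutoff: float = 10.0,
                      order: int = 4) -> RawChannelSeries:
    """Fourth-order zero-phase Butterworth low-pass at 10 Hz."""
    if raw.rate <= 2 * cutoff:
        raise ValueError(
            f"sampling rate {raw.rate} Hz too low for a {cutoff} Hz cutoff")
    sos = sps.butter(order, cutoff / (raw.rate / 2), btype="lowpass", output="sos")
    return RawChannelSeries(sps.sosfiltfilt(sos, raw.samples), raw.rate, raw.label)


def normalize_emg(trials: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Scale a muscle's envelopes by its maximum over all trials.

    Input: one envelope array per trial (same muscle).  The global maximum
    over all trials becomes 1; all-zero channels are rejected because their
    normalization is undefined.
    """
    arrs = [np.asarray(t, dtype=float) for t in trials]
    if not arrs:
        raise ValueError("no trials given")
    peak = max(float(a.max()) if a.size else 0.0 for a in arrs)
    if peak <= 0:
        raise ValueError("all-zero channel: EMG normalization undefined")
    return [a / peak for a in arrs]


def segment_cycles(pole_tip_height: RawChannelSeries,
                   min_prominence_frac: float = 0.10,
                   min_separation_s: float = 0.5) -> list[DpCycle]:
    """Segment double-poling cycles from the pole-tip height trajectory.

    A cycle starts at a height maximum (pole plant: poling phase begins),
    passes through the minimum (pole extraction: recovery begins) and ends
    at the next maximum.  Peaks are detected with a minimum prominence of
    10% of the signal range and a minimum separation of 0.5 s, both
    configurable.
    """
    x = pole_tip_height.samples
    rng = float(x.max() - x.min())
    if rng <= 0:
        raise ValueError("flat height signal: no cycles detectable")
    dist = max(1, int(round(min_separation_s * pole_tip_height.rate)))
    peaks, _ = sps.find_peaks(x, prominence=min_prominence_frac * rng, distance=dist)
    if len(peaks) < 2:
        raise ValueError("fewer than two height maxima: no full cycle present")
    cycles = []
    for s, e in zip(peaks[:-1], peaks[1:]):
        trans = s + int(np.argmin(x[s:e]))
        if not s < trans < e:
            continue  # degenerate cycle (monotone segment)
        cycles.append(DpCycle(int(s), int(trans), int(e), pole_tip_height.rate))
    return cycles


def _phase_grid(t0: float, t1: float, n: int) -> np.ndarray:
    # half-open sampling so that consecutive phases/cycles tile the series
    return t0 + (t1 - t0) * np.arange(n) / n


def time_normalize(series: np.ndarray, cycle: DpCycle,
                   kind: str = "linear") -> np.ndarray:
    """Resample one cycle of a series onto the 100-point grid (50 + 50).

    The poling span [start, transition) and recovery span [transition, end)
    are each sampled at 50 equispaced points (half-open, so a cycle already
    on a uniform 50+50 grid maps to itself).  Interpolation is linear by
    default, cubic via ``kind='cubic'``.
    """
    series = np.asarray(series, dtype=float)
    if not (0 <= cycle.start and cycle.end <= series.shape[0]):
        raise ValueError("cycle boundaries outside the series")
    if cycle.transition == cycle.start or cycle.end == cycle.transition:
        raise ValueError("degenerate phase with zero duration")
    idx = np.arange(series.shape[0], dtype=float)
    targets = np.concatenate([
        _phase_grid(cycle.start, cycle.transition, N_PHASE),
        _phase_grid(cycle.transition, cycle.end, N_PHASE),
    ])
    if kind == "linear":
        return np.interp(targets, idx, series)
    elif kind == "cubic":
        from scipy.interpolate import CubicSpline
        return CubicSpline(idx, series)(targets)
    raise ValueError(f"unknown interpolation kind {kind!r}")


def phase_labels() -> np.ndarray:
    """Phase label per grid point: 'poling' for 0-49, 'recovery' for 50-99."""
    return np.array(["poling"] * N_PHASE + ["recovery"] * N_PHASE)
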