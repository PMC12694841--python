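"""Blink detection on the filtered bipolar VEOG.

A blink is a local maximum of the positive-going derivation at or above an
amplitude threshold (default 100 uV).  A refractory rule enforces a minimum
spacing between detected peaks (default 250 ms): whenever two supra-threshold
local maxima fall closer than the minimum interval, the larger one is kept
(ties resolved to the earlier peak).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from veogblink.signal_io import BipolarVEOG, SegmentSpec

__all__ = [
    "BlinkEvent",
    "BlinkSeries",
    "detect_blinks",
    "compute_ibis",
    "DEFAULT_THRESHOLD_UV",
    "DEFAULT_MIN_INTERVAL_S",
]

DEFAULT_THRESHOLD_UV = 100.0
DEFAULT_MIN_INTERVAL_S = 0.25


@dataclass(frozen=True)
class BlinkEvent:
    peak_time: float  # seconds from segment start
    peak_amplitude: float  # uV on the blink-positive derivation
    peak_index: int


@dataclass
class BlinkSeries:
    """Time-ordered blink events for one segment."""

    events: list[BlinkEvent]
    duration: float
    segment: SegmentSpec | None = None
    min_interval: float = DEFAULT_MIN_INTERVAL_S

    def __post_init__(self):
        times = [e.peak_time for e in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("blink events must be strictly increasing in time")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def peak_times(self) -> np.ndarray:
        return np.array([e.peak_time for e in self.events], dtype=np.float64)

    @property
    def peak_amplitudes(self) -> np.ndarray:
        return np.array([e.peak_amplitude for e in self.events], dtype=np.float64)


def _min_distance_samples(min_interval: float, fs: float) -> int:
    # smallest integer sample gap whose duration is >= min_interval
    return max(1, int(math.ceil(min_interval * fs - 1e-9)))


def _refractory_prune(indices: np.ndarray, heights: np.ndarray, d: int) -> np.ndarray:
    """Greedy amplitude-ordered suppression: visit candidates from largest to
    smallest (ties: earlier first) and keep each one that is >= ``d`` samples
    from every already-kept peak."""
    order = np.lexsort((indices, -heights))
    keep = np.zeros(indices.size, dtype=bool)
    kept: list[int] = []
    for pos in order:
        idx = indices[pos]
        if all(abs(idx - k) >= d for k in kept):
            keep[pos] = True
            kept.append(idx)
    return np.sort(indices[keep])


def detect_blinks(
    veog: BipolarVEOG,
    threshold: float = DEFAULT_THRESHOLD_UV,
    min_interval: float = DEFAULT_MIN_INTERVAL_S,
    segment: SegmentSpec | None = None,
) -> BlinkSeries:
    """Detect blink peaks on a (filtered) bipolar VEOG segment.

    Peaks are sought on the positive-going signal only.  Plateau maxima
    resolve to the plateau midpoint; supra-threshold maxima at the first or
    last interior sample count, half-cut waveforms without an interior
    maximum do not.  An empty or all-subthreshold signal yields an empty
    series, never an error.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_interval <= 0:
        raise ValueError("min_interval must be positive")
    x = veog.samples
    duration = veog.duration
    if x.size < 3:
        return BlinkSeries([], duration, segment, min_interval)

    candidates, _ = sps.find_peaks(x, height=threshold)
    d = _min_distance_samples(min_interval, veog.fs)
    kept = _refractory_prune(candidates, x[candidates], d)

    events = [
        BlinkEvent(peak_time=i / veog.fs, peak_amplitude=float(x[i]), peak_index=int(i))
        for i in kept
    ]
    return BlinkSeries(events, duration, segment, min_interval)


def compute_ibis(series: BlinkSeries) -> np.ndarray:
    """Successive differences of peak times (seconds); empty for < 2 events."""
    if len(series) < 2:
        return np.empty(0, dtype=np.float64)
    return np.diff(series.peak_times)
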