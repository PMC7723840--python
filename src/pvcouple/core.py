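"""Core containers for extracellular recording sessions.

The analyses in this package operate on three substrates: uniformly sampled
local field potential (LFP) traces, sorted spike trains, and behavioral-state
interval labels (active wakefulness AW, quiet wakefulness QW, REM sleep,
slow-wave sleep SWS).  Everything downstream — band-pass filtering, oscillation
event detection, spike-phase statistics, optogenetic tagging — consumes these
containers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

STATES = ("AW", "QW", "REM", "SWS")


@dataclass
class BandDefinition:
    """A named frequency band with edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"invalid band edges: {self.low}-{self.high} Hz")

    def validate_for(self, sampling_rate: float) -> None:
        if self.high >= sampling_rate / 2:
            raise ValueError(
                f"band {self.name} upper edge {self.high} Hz >= Nyquist "
                f"({sampling_rate / 2} Hz)"
            )


# Medial prefrontal cortex bands. The "delta" band doubles as the ~4 Hz
# oscillation component seen in mouse PFC during wakefulness.
MPFC_BANDS = {
    "delta": BandDefinition("delta", 2.0, 5.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "slow_gamma": BandDefinition("slow_gamma", 30.0, 50.0),
    "fast_gamma": BandDefinition("fast_gamma", 50.0, 80.0),
    "hfo": BandDefinition("hfo", 100.0, 250.0),
}

# Dorsal hippocampal CA1 bands.
DCA1_BANDS = {
    "delta": BandDefinition("delta", 2.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 12.0),
    "gamma": BandDefinition("gamma", 30.0, 80.0),
    "ripple": BandDefinition("ripple", 100.0, 250.0),
}

REGION_BANDS = {"mPFC": MPFC_BANDS, "dCA1": DCA1_BANDS}


@dataclass
class LfpTrace:
    """Uniformly sampled LFP voltage series in millivolts."""

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def slice(self, start: float, end: float) -> "LfpTrace":
        """Return the sub-trace covering [start, end) in seconds."""
        i0 = max(0, int(round((start - self.start_time) * self.sampling_rate)))
        i1 = min(self.n_samples, int(round((end - self.start_time) * self.sampling_rate)))
        return LfpTrace(self.samples[i0:i1], self.sampling_rate,
                        self.start_time + i0 / self.sampling_rate)


@dataclass
class SpikeTrain:
    """Ascending spike times (seconds) for one sorted unit."""

    times: np.ndarray
    unit_id: str
    cell_class: str = "unknown"  # {"PV", "PN", "unknown"}

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if self.times.size > 1 and np.any(np.diff(self.times) < 0):
            raise ValueError(f"spike times for unit {self.unit_id} are not ascending")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def restrict(self, intervals) -> "SpikeTrain":
        """Keep spikes falling inside any of the given (start, end) intervals."""
        if self.times.size == 0:
            return self
        mask = np.zeros(self.times.size, dtype=bool)
        for iv in intervals:
            start, end = (iv.start, iv.end) if hasattr(iv, "start") else iv
            mask |= (self.times >= start) & (self.times < end)
        return SpikeTrain(self.times[mask], self.unit_id, self.cell_class)


@dataclass
class StateInterval:
    """One contiguous behavioral-state epoch."""

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("interval start must precede end")

    @property
    def duration(self) -> float:
        return self.end - self.start


def intervals_for_state(intervals, label: str):
    return [iv for iv in intervals if iv.label == label]


def check_tiling(intervals, total_duration: float, atol: float = 1e-9):
    """Return a list of tiling problems (empty when intervals exactly tile
    [0, total_duration] without gaps or overlaps)."""
    issues = []
    if not intervals:
        return ["no intervals"]
    ivs = sorted(intervals, key=lambda iv: iv.start)
    if abs(ivs[0].start) > atol:
        issues.append(f"first interval starts at {ivs[0].start}, not 0")
    for a, b in zip(ivs[:-1], ivs[1:]):
        if b.start < a.end - atol:
            issues.append(f"overlap between {a.label}@{a.start:.3f} and {b.label}@{b.start:.3f}")
        elif b.start > a.end + atol:
            issues.append(f"gap between {a.end:.3f} and {b.start:.3f}")
    if abs(ivs[-1].end - total_duration) > atol:
        issues.append(f"last interval ends at {ivs[-1].end}, not {total_duration}")
    return issues


@dataclass
class OscillationEvent:
    """A detected (or embedded ground-truth) band-limited transient."""

    band: str
    start: float
    end: float
    peak_time: float
    peak_power_sd: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("event start must precede end")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class PsdEstimate:
    """One-sided power spectral density (mV^2/Hz)."""

    frequencies: np.ndarray
    power: np.ndarray
    method: str

    def band_power(self, band: BandDefinition) -> float:
        """Integrated power in the band (trapezoid over the PSD grid)."""
        f, p = self.frequencies, self.power
        mask = (f >= band.low) & (f <= band.high)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(p[mask], f[mask]))


@dataclass
class SessionBundle:
    """Everything recorded in one session, on a shared time base."""

    lfp: dict  # region name -> LfpTrace
    spikes: list  # list of SpikeTrain
    states: list  # list of StateInterval
    protocol: Optional[object] = None  # OptoProtocol
    movement: Optional[np.ndarray] = None  # per-LFP-sample movement scalar
    ground_truth: Optional[object] = None  # GroundTruth (synthetic sessions)

    @property
    def duration(self) -> float:
        return max(tr.duration for tr in self.lfp.values())
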