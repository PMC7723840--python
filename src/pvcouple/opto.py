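"""Optogenetic tagging and stimulation-effect analysis.

A unit is opto-tagged as a PV interneuron when short laser pulses (5 ms,
typically 1 Hz, 100 trials) evoke at least one spike within 10 ms of pulse
onset in more than 60% of trials.  The evoked window is half-open at the
onset: a spike exactly at the onset is not evoked, a spike exactly at
onset + 10 ms is.

Sustained stimulation (10 s blocks) is analyzed by comparing per-unit firing
rates and per-band LFP power between ON blocks and equal-length OFF windows
immediately preceding each block, with Wilcoxon signed-rank tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import BandDefinition, LfpTrace, SpikeTrain
from .signal_processing import welch_psd

EVOKED_WINDOW = 0.010
PV_PROB_THRESHOLD = 0.60


@dataclass
class OptoProtocol:
    """Laser stimulation protocol for one session."""

    pulse_onsets: np.ndarray
    pulse_width: float = 0.005
    frequency: float = 1.0
    power_mw: float = 10.0
    mode: str = "pulse"  # {"pulse", "sustained"}
    sustained_duration: float = 10.0

    def __post_init__(self) -> None:
        self.pulse_onsets = np.asarray(self.pulse_onsets, dtype=float)
        if self.pulse_onsets.size == 0:
            raise ValueError("protocol needs at least one pulse onset")
        gaps = np.diff(self.pulse_onsets)
        if np.any(gaps <= 0):
            raise ValueError("pulse onsets must be strictly ascending")
        min_gap = self.sustained_duration if self.mode == "sustained" else self.pulse_width
        if gaps.size and gaps.min() < min_gap:
            raise ValueError("pulses overlap: inter-onset interval below pulse width")

    @property
    def n_trials(self) -> int:
        return self.pulse_onsets.size

    @classmethod
    def regular(cls, n_trials: int, frequency: float = 1.0, start: float = 1.0, **kw):
        onsets = start + np.arange(n_trials) / frequency
        return cls(pulse_onsets=onsets, frequency=frequency, **kw)


@dataclass
class OptoTagResult:
    unit_id: str
    firing_probability: float
    mean_latency: float  # seconds; nan when no evoked spikes
    evoked_spikes_per_trial: float
    suppression_time: float  # seconds; nan when undefined
    is_pv: bool
    waveform_correlation: float = float("nan")


def evoked_response(spikes: SpikeTrain, protocol: OptoProtocol, window: float = EVOKED_WINDOW):
    """Per-trial evoked spike counts and first-spike latencies.

    A spike is evoked when it falls in (onset, onset + window].  Trials with
    no evoked spike contribute no latency.
    """
    if protocol.mode != "pulse":
        raise ValueError("evoked_response requires a pulse protocol")
    onsets = protocol.pulse_onsets
    times = spikes.times
    lo = np.searchsorted(times, onsets, side="right")  # exclude spike at onset
    hi = np.searchsorted(times, onsets + window, side="right")  # include at +window
    counts = hi - lo
    latencies = times[lo[counts > 0]] - onsets[counts > 0]
    return counts, latencies


def firing_probability(counts: np.ndarray) -> float:
    """Fraction of trials with at least one evoked spike."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("no trials")
    return float(np.mean(counts >= 1))


@dataclass
class Psth:
    bin_edges: np.ndarray  # seconds relative to pulse onset
    rate: np.ndarray  # spikes/s per trial
    n_trials: int

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


def psth(
    spikes: SpikeTrain,
    onsets: np.ndarray,
    bin_width: float = 0.003,
    span: tuple = (-0.050, 0.100),
) -> Psth:
    """Peri-stimulus time histogram in spikes/s per trial."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    onsets = np.asarray(onsets, dtype=float)
    n_bins = int(round((span[1] - span[0]) / bin_width))
    edges = span[0] + np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins)
    times = spikes.times
    for onset in onsets:
        rel = times[(times >= onset + span[0]) & (times < onset + span[1])] - onset
        counts += np.histogram(rel, bins=edges)[0]
    rate = counts / (onsets.size * bin_width)
    return Psth(bin_edges=edges, rate=rate, n_trials=onsets.size)


def suppression_time(hist: Psth, baseline_rate: Optional[float] = None) -> float:
    """Post-evoked-peak firing suppression duration, in seconds.

    Measured from the first post-peak bin whose rate falls below baseline to
    the first of 3 consecutive bins recovering to >= 50% of baseline; 0 when
    the rate never drops below baseline.  Baseline defaults to the mean rate
    of the pre-onset bins.
    """
    centers = hist.bin_centers
    post = centers > 0
    if not post.any() or centers[post][-1] < 0.1 - hist.bin_width:
        raise ValueError("PSTH must cover at least 100 ms after onset")
    if baseline_rate is None:
        pre = centers < 0
        baseline_rate = float(hist.rate[pre].mean()) if pre.any() else 0.0
    if baseline_rate <= 0:
        warnings.warn("zero baseline rate: suppression time undefined")
        return float("nan")
    post_idx = np.flatnonzero(post)
    peak = post_idx[int(np.argmax(hist.rate[post_idx]))]
    below = np.flatnonzero(hist.rate[peak + 1 :] < baseline_rate)
    if below.size == 0:
        return 0.0
    start = peak + 1 + below[0]
    recovered = hist.rate[start:] >= 0.5 * baseline_rate
    run = 0
    for i, ok in enumerate(recovered):
        run = run + 1 if ok else 0
        if run == 3:
            end = start + i - 2
            return float((end - start) * hist.bin_width)
    return float((hist.rate.size - start) * hist.bin_width)


def waveform_correlation(mean_spont: np.ndarray, mean_evoked: np.ndarray) -> float:
    """Pearson r between mean spontaneous and mean evoked spike waveforms."""
    a = np.asarray(mean_spont, dtype=float)
    b = np.asarray(mean_evoked, dtype=float)
    if a.shape != b.shape:
        raise ValueError("waveforms must have equal length")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance waveform: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def tag_unit(
    spikes: SpikeTrain,
    protocol: OptoProtocol,
    window: float = EVOKED_WINDOW,
    prob_threshold: float = PV_PROB_THRESHOLD,
    waveform_pair: Optional[tuple] = None,
) -> OptoTagResult:
    """Classify one unit from its pulse-evoked responses.

    PV classification requires firing probability strictly above the
    threshold (exactly 60% does not qualify).
    """
    counts, latencies = evoked_response(spikes, protocol, window=window)
    prob = firing_probability(counts)
    hist = psth(spikes, protocol.pulse_onsets)
    try:
        supp = suppression_time(hist)
    except ValueError:
        supp = float("nan")
    wf_r = float("nan")
    if waveform_pair is not None:
        wf_r = waveform_correlation(*waveform_pair)
    return OptoTagResult(
        unit_id=spikes.unit_id,
        firing_probability=prob,
        mean_latency=float(latencies.mean()) if latencies.size else float("nan"),
        evoked_spikes_per_trial=float(counts.mean()),
        suppression_time=supp,
        is_pv=bool(prob > prob_threshold),
        waveform_correlation=wf_r,
    )


def _epoch_rate(times: np.ndarray, epochs) -> float:
    total_t = sum(e - s for s, e in epochs)
    count = sum(
        np.searchsorted(times, e) - np.searchsorted(times, s) for s, e in epochs
    )
    return count / total_t if total_t > 0 else float("nan")


def sustained_effect(
    units: Sequence[SpikeTrain],
    protocol: OptoProtocol,
    lfp: Optional[LfpTrace] = None,
    bands: Optional[Sequence[BandDefinition]] = None,
) -> dict:
    """ON/OFF comparison for sustained (10 s block) stimulation.

    OFF epochs are equal-length windows immediately preceding each ON block.
    Returns per-unit ON/OFF rates with a Wilcoxon signed-rank test across
    units, and per-band ON/OFF Welch power with a signed-rank test across
    trials when an LFP trace is supplied.
    """
    if protocol.mode != "sustained":
        raise ValueError("sustained_effect requires a sustained protocol")
    dur = protocol.sustained_duration
    on_epochs = [(t, t + dur) for t in protocol.pulse_onsets]
    off_epochs = [(t - dur, t) for t in protocol.pulse_onsets]
    if off_epochs[0][0] < 0:
        raise ValueError("no room for an OFF window before the first block")

    report: dict = {"n_units": len(units), "n_trials": len(on_epochs)}
    unit_rows = []
    for u in units:
        unit_rows.append(
            {
                "unit_id": u.unit_id,
                "cell_class": u.cell_class,
                "rate_on": _epoch_rate(u.times, on_epochs),
                "rate_off": _epoch_rate(u.times, off_epochs),
            }
        )
    report["unit_rates"] = unit_rows
    on = np.array([r["rate_on"] for r in unit_rows])
    off = np.array([r["rate_off"] for r in unit_rows])
    if len(units) >= 5 and np.any(on != off):
        stat, p = stats.wilcoxon(off, on)
        report["rate_test"] = {"statistic": float(stat), "p": float(p)}
    elif len(units) >= 5:
        report["rate_test"] = {"statistic": 0.0, "p": 1.0}
    else:
        warnings.warn("fewer than 5 units: rate comparison reported without test")
        report["rate_test"] = None

    if lfp is not None and bands:
        band_rows = []
        for band in bands:
            p_on, p_off = [], []
            for (s0, e0), (s1, e1) in zip(on_epochs, off_epochs):
                try:
                    p_on.append(welch_psd(lfp.slice(s0, e0)).band_power(band))
                    p_off.append(welch_psd(lfp.slice(s1, e1)).band_power(band))
                except ValueError:
                    continue
            row = {
                "band": band.name,
                "power_on": p_on,
                "power_off": p_off,
                "mean_on": float(np.mean(p_on)) if p_on else float("nan"),
                "mean_off": float(np.mean(p_off)) if p_off else float("nan"),
            }
            if len(p_on) >= 5 and not np.allclose(p_on, p_off):
                stat, p = stats.wilcoxon(p_off, p_on)
                row["test"] = {"statistic": float(stat), "p": float(p)}
            else:
                row["test"] = None
            band_rows.append(row)
        report["band_power"] = band_rows
    return report
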