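"""Synthetic recording sessions with known ground truth.

The generator emulates the statistical structure the analysis chain assumes:

* a semi-Markov behavioral-state sequence (AW/QW/REM/SWS) with
  truncated-exponential dwell times,
* an LFP trace built from 1/f^alpha Gaussian background noise plus
  state-dependent band-limited sinusoidal components and embedded
  Hann-windowed HFO bursts (100-250 Hz) at Poisson times,
* spike trains phase-locked to a chosen oscillation component, drawn as an
  inhomogeneous Poisson process by thinning with instantaneous rate
  rate(t) = base_rate(state) * 2 pi * vonMisesDensity(phase(t); mu, kappa),
* optogenetic sessions with probabilistic pulse-evoked spikes at ~6 ms
  latency followed by background suppression, and sustained-stimulation
  blocks that scale PV rates up and pyramidal (PN) rates down.

Everything is driven by one integer seed; each component draws from its own
deterministic sub-stream, so regenerating any piece is byte-identical.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np

from .core import (
    STATES,
    LfpTrace,
    MPFC_BANDS,
    OscillationEvent,
    SessionBundle,
    SpikeTrain,
    StateInterval,
)
from .opto import OptoProtocol
from .phase_locking import instantaneous_phase
from .signal_processing import bandpass_filter, sliding_rms
from scipy import special


@dataclass
class UnitSpec:
    """Ground-truth parameters for one simulated unit."""

    unit_id: str
    cell_class: str = "PV"  # {"PV", "PN"}
    base_rate: Dict[str, float] = field(
        default_factory=lambda: {s: 10.0 for s in STATES}
    )
    coupling_band: Optional[str] = "hfo"
    kappa: float = 2.0
    mu_deg: float = 220.0
    opto_evoked_prob: float = 0.8
    opto_latency_mean: float = 0.006
    suppression_duration: float = 0.030
    sustained_factor: float = 3.0  # rate multiplier during sustained ON blocks

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if any(r < 0 for r in self.base_rate.values()):
            raise ValueError("rates must be non-negative")
        if not (0 <= self.opto_evoked_prob <= 1):
            raise ValueError("evoked probability must lie in [0, 1]")
        self.mu_deg = float(np.mod(self.mu_deg, 360.0))


def _default_band_amplitudes() -> Dict[tuple, float]:
    """(state, band) -> component amplitude in mV.

    Chosen so each state's spectrum shows the oscillations characteristic of
    that state: theta with nested gamma and a ~4 Hz component during AW,
    strong theta during REM, prominent delta during SWS, weak rhythms in QW.
    """
    return {
        ("AW", "delta"): 0.03,
        ("AW", "theta"): 0.05,
        ("AW", "slow_gamma"): 0.02,
        ("AW", "fast_gamma"): 0.015,
        ("QW", "theta"): 0.015,
        ("QW", "delta"): 0.02,
        ("REM", "theta"): 0.06,
        ("REM", "slow_gamma"): 0.015,
        ("SWS", "delta"): 0.08,
    }


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic session generator."""

    seed: int = 0
    total_duration: float = 120.0
    sampling_rate: float = 1000.0
    state_dwell_means: Dict[str, float] = field(
        default_factory=lambda: {"AW": 60.0, "QW": 30.0, "REM": 40.0, "SWS": 80.0}
    )
    min_dwell: float = 5.0
    band_amplitudes: Dict[tuple, float] = field(default_factory=_default_band_amplitudes)
    noise_exponent: float = 1.0
    noise_scale: float = 0.05  # mV, SD of the 1/f background
    hfo_rate: Dict[str, float] = field(
        default_factory=lambda: {"AW": 0.3, "QW": 0.1, "REM": 0.1, "SWS": 0.5}
    )
    hfo_duration_mean: float = 0.040
    hfo_duration_sigma: float = 0.25  # log-normal shape
    hfo_amplitude_sd_multiple: float = 4.0
    unit_specs: List[UnitSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.total_duration <= 0:
            raise ValueError("total_duration must be positive")
        if any(v <= 0 for v in self.state_dwell_means.values()):
            raise ValueError("dwell means must be positive")
        highest = max(b.high for b in MPFC_BANDS.values())
        if self.sampling_rate <= 2 * highest:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} must exceed twice the highest "
                f"band edge ({highest} Hz)"
            )


@dataclass
class GroundTruth:
    """What was actually embedded in a synthetic session."""

    events: List[OscillationEvent]
    unit_params: Dict[str, UnitSpec]
    state_intervals: List[StateInterval]


def _rng(seed: int, component: str) -> np.random.Generator:
    """Deterministic per-component sub-stream of the session seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(component.encode())])
    )


def gen_state_sequence(config: SyntheticConfig) -> List[StateInterval]:
    """Semi-Markov state sequence tiling [0, total_duration].

    Dwell times are exponential with the configured per-state mean, left
    truncated at ``min_dwell`` (so realized means are min_dwell + mean by the
    memoryless property); successive states are drawn uniformly among the
    other allowed states.
    """
    rng = _rng(config.seed, "states")
    labels = [s for s in STATES if s in config.state_dwell_means]
    if not labels:
        raise ValueError("no states configured")
    intervals: List[StateInterval] = []
    t = 0.0
    state = labels[int(rng.integers(len(labels)))]
    while t < config.total_duration:
        dwell = config.min_dwell + rng.exponential(config.state_dwell_means[state])
        end = min(t + dwell, config.total_duration)
        intervals.append(StateInterval(state, t, end))
        t = end
        if len(labels) > 1:
            others = [s for s in labels if s != state]
            state = others[int(rng.integers(len(others)))]
    return intervals


def one_over_f_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise with a 1/f^exponent power spectrum."""
    white = rng.standard_normal(n)
    if exponent == 0:
        return white
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * scale, n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


_BAND_COMPONENT_FREQ_MARGIN = 0.15  # keep jittered tones inside the band


def gen_lfp(states: List[StateInterval], config: SyntheticConfig):
    """Build the LFP trace and its ground-truth HFO event list."""
    fs = config.sampling_rate
    n = int(round(config.total_duration * fs))
    t = np.arange(n) / fs
    rng = _rng(config.seed, "lfp")

    trace = np.zeros(n)
    if config.noise_scale > 0:
        trace += config.noise_scale * one_over_f_noise(n, config.noise_exponent, rng)

    # state-dependent sinusoidal band components with per-interval frequency
    # and phase jitter, short cosine ramps at interval edges
    for iv in states:
        i0, i1 = int(round(iv.start * fs)), int(round(iv.end * fs))
        if i1 <= i0:
            continue
        seg_t = t[i0:i1]
        ramp = np.ones(i1 - i0)
        n_ramp = min(int(0.1 * fs), (i1 - i0) // 4)
        if n_ramp > 0:
            edge = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
            ramp[:n_ramp] = edge
            ramp[-n_ramp:] = edge[::-1]
        for band_name, band in MPFC_BANDS.items():
            amp = config.band_amplitudes.get((iv.label, band_name), 0.0)
            if amp <= 0:
                continue
            span = band.high - band.low
            f_c = rng.uniform(
                band.low + _BAND_COMPONENT_FREQ_MARGIN * span,
                band.high - _BAND_COMPONENT_FREQ_MARGIN * span,
            )
            phi0 = rng.uniform(0, 2 * np.pi)
            trace[i0:i1] += amp * ramp * np.sin(2 * np.pi * f_c * seg_t + phi0)

    events: List[OscillationEvent] = []
    if any(r > 0 for r in config.hfo_rate.values()):
        if not np.any(trace):
            # SD-relative burst amplitude is undefined on a silent background
            warnings.warn("silent background: skipping HFO burst embedding")
        else:
            hfo_band = MPFC_BANDS["hfo"]
            background = LfpTrace(trace.copy(), fs)
            filt = bandpass_filter(background, hfo_band)
            _, env = sliding_rms(filt)
            bg_mean, bg_sd = float(env.mean()), float(env.std())
            target_rms = bg_mean + config.hfo_amplitude_sd_multiple * bg_sd
            brng = _rng(config.seed, "hfo_bursts")
            # log-normal duration with the configured distribution mean
            mu_ln = np.log(config.hfo_duration_mean) - config.hfo_duration_sigma**2 / 2
            for iv in states:
                rate = config.hfo_rate.get(iv.label, 0.0)
                if rate <= 0:
                    continue
                n_bursts = brng.poisson(rate * iv.duration)
                for _ in range(n_bursts):
                    dur = float(brng.lognormal(mu_ln, config.hfo_duration_sigma))
                    dur = min(max(dur, 0.015), 0.200)
                    f_b = brng.uniform(hfo_band.low + 10, hfo_band.high - 10)
                    start = brng.uniform(iv.start, max(iv.start, iv.end - dur))
                    i0 = int(round(start * fs))
                    length = int(round(dur * fs))
                    if i0 + length > n:
                        length = n - i0
                    if length < 4:
                        continue
                    win = np.hanning(length)
                    tt = np.arange(length) / fs
                    phi0 = brng.uniform(0, 2 * np.pi)
                    # Hann window RMS over its own support is sqrt(3/8); scale
                    # the tone so the burst-center envelope reaches target_rms
                    amp = target_rms * np.sqrt(2.0)
                    trace[i0 : i0 + length] += amp * win * np.sin(
                        2 * np.pi * f_b * tt + phi0
                    )
                    events.append(
                        OscillationEvent(
                            band="hfo",
                            start=start,
                            end=start + length / fs,
                            peak_time=start + length / fs / 2,
                            peak_power_sd=config.hfo_amplitude_sd_multiple,
                        )
                    )
            events.sort(key=lambda e: e.start)

    gt = GroundTruth(events=events, unit_params={}, state_intervals=list(states))
    return LfpTrace(trace, fs), gt


def _rate_over_time(states: List[StateInterval], base_rate: Dict[str, float],
                    n: int, fs: float) -> np.ndarray:
    rate = np.zeros(n)
    for iv in states:
        i0, i1 = int(round(iv.start * fs)), min(n, int(round(iv.end * fs)))
        rate[i0:i1] = base_rate.get(iv.label, 0.0)
    return rate


def gen_state_spikes(
    spec: UnitSpec,
    states: List[StateInterval],
    seed: int = 0,
) -> SpikeTrain:
    """Homogeneous Poisson spikes per state at the unit's base rates."""
    rng = _rng(seed, f"spikes:{spec.unit_id}")
    pieces = []
    for iv in states:
        rate = spec.base_rate.get(iv.label, 0.0)
        if rate <= 0:
            continue
        n = rng.poisson(rate * iv.duration)
        pieces.append(rng.uniform(iv.start, iv.end, n))
    if not pieces:
        return SpikeTrain(np.empty(0), spec.unit_id, spec.cell_class)
    return SpikeTrain(np.sort(np.concatenate(pieces)), spec.unit_id, spec.cell_class)


def gen_phase_locked_spikes(
    trace: LfpTrace,
    spec: UnitSpec,
    states: List[StateInterval],
    seed: Optional[int] = None,
) -> SpikeTrain:
    """Inhomogeneous-Poisson spikes phase-locked to one oscillation band.

    Thinning against the exact rate bound base_rate * e^kappa / I0(kappa)
    (the 2 pi * von Mises density maximum), so the time-averaged rate equals
    the state base rate whenever the phase is traversed uniformly; kappa = 0
    reduces to a homogeneous Poisson process per state.
    """
    if seed is None:
        seed = 0
    if spec.coupling_band is None or spec.kappa == 0:
        return gen_state_spikes(spec, states, seed=seed)

    rng = _rng(seed, f"spikes:{spec.unit_id}:coupled")
    fs = trace.sampling_rate
    n = trace.n_samples
    rate_t = _rate_over_time(states, spec.base_rate, n, fs)
    max_rate = float(rate_t.max())
    if max_rate == 0:
        return SpikeTrain(np.empty(0), spec.unit_id, spec.cell_class)

    band = MPFC_BANDS[spec.coupling_band]
    filtered = bandpass_filter(trace, band)
    phase = instantaneous_phase(filtered)
    mu = np.radians(spec.mu_deg)
    # 2 pi * vonMises density peaks at e^kappa / I0(kappa) = 1 / i0e(kappa)
    peak_factor = 1.0 / float(special.i0e(spec.kappa))
    lam_max = max_rate * peak_factor

    n_cand = rng.poisson(lam_max * trace.duration)
    cand = np.sort(rng.uniform(0, trace.duration, n_cand)) + trace.start_time
    frac_idx = (cand - trace.start_time) * fs
    idx = np.minimum(frac_idx.astype(int), n - 1)
    # interpolate phase on the circle at the exact candidate times (a
    # nearest-sample lookup biases fast oscillations by ~half a sample,
    # tens of degrees at 100-250 Hz)
    ph_cand = np.interp(frac_idx, np.arange(n), np.unwrap(phase))
    # 2 pi * f(phi) / peak = exp(kappa (cos(phi - mu) - 1))
    lam = rate_t[idx] * peak_factor * np.exp(spec.kappa * (np.cos(ph_cand - mu) - 1.0))
    accept = rng.uniform(size=n_cand) < lam / lam_max
    return SpikeTrain(cand[accept], spec.unit_id, spec.cell_class)


def gen_opto_session(
    spec: UnitSpec,
    protocol: OptoProtocol,
    config: SyntheticConfig,
    background_rate: Optional[float] = None,
) -> SpikeTrain:
    """Spike train for one unit under laser stimulation.

    Pulse mode: per pulse, with probability ``opto_evoked_prob`` one evoked
    spike at onset + latency (Gaussian, SD 1 ms, truncated into (0, 10 ms]),
    and background spikes are suppressed for ``suppression_duration`` after
    each evoked spike.

    Sustained mode: the unit's rate is multiplied by ``sustained_factor``
    inside each ON block (PV factors > 1, PN factors < 1).
    """
    rng = _rng(config.seed, f"opto:{spec.unit_id}")
    if background_rate is None:
        background_rate = spec.base_rate.get("AW", 0.0)
    t_end = float(protocol.pulse_onsets[-1]) + (
        protocol.sustained_duration if protocol.mode == "sustained" else 1.0
    )

    if protocol.mode == "sustained":
        n_cand = rng.poisson(max(background_rate, background_rate * spec.sustained_factor, 1e-9) * t_end)
        lam_max = max(background_rate, background_rate * spec.sustained_factor)
        if lam_max == 0:
            return SpikeTrain(np.empty(0), spec.unit_id, spec.cell_class)
        cand = np.sort(rng.uniform(0, t_end, n_cand))
        in_on = np.zeros(n_cand, dtype=bool)
        for onset in protocol.pulse_onsets:
            in_on |= (cand >= onset) & (cand < onset + protocol.sustained_duration)
        lam = np.where(in_on, background_rate * spec.sustained_factor, background_rate)
        accept = rng.uniform(size=n_cand) < lam / lam_max
        return SpikeTrain(cand[accept], spec.unit_id, spec.cell_class)

    # pulse mode: background + evoked + suppression
    n_bg = rng.poisson(background_rate * t_end) if background_rate > 0 else 0
    bg = np.sort(rng.uniform(0, t_end, n_bg))

    evoked_times = []
    for onset in protocol.pulse_onsets:
        if rng.uniform() >= spec.opto_evoked_prob:
            continue
        while True:  # truncate latency into (0, 10 ms]
            lat = rng.normal(spec.opto_latency_mean, 0.001)
            if 0.0 < lat <= 0.010:
                break
        evoked_times.append(onset + lat)
    evoked = np.asarray(evoked_times)

    if evoked.size and spec.suppression_duration > 0 and bg.size:
        keep = np.ones(bg.size, dtype=bool)
        for ev in evoked:
            keep &= ~((bg > ev) & (bg <= ev + spec.suppression_duration))
        bg = bg[keep]

    times = np.sort(np.concatenate([bg, evoked]))
    return SpikeTrain(times, spec.unit_id, spec.cell_class)


def default_unit_specs() -> List[UnitSpec]:
    """Three PV units, one per firing-rate subtype, plus one pyramidal unit.

    Subtype rate profiles mirror the three observed patterns: AW-elevated,
    AW+REM-elevated, and state-invariant; all PV units couple to HFOs near
    the trough (~220 degrees).
    """
    return [
        UnitSpec("pv1", "PV", {"AW": 15.0, "QW": 5.0, "REM": 5.0, "SWS": 5.0},
                 "hfo", 2.0, 220.0),
        UnitSpec("pv2", "PV", {"AW": 15.0, "QW": 5.0, "REM": 15.0, "SWS": 5.0},
                 "hfo", 2.0, 220.0),
        UnitSpec("pv3", "PV", {"AW": 8.0, "QW": 8.0, "REM": 8.0, "SWS": 8.0},
                 "hfo", 2.0, 220.0),
        UnitSpec("pn1", "PN", {"AW": 2.0, "QW": 1.5, "REM": 1.5, "SWS": 1.0},
                 None, 0.0, 0.0, opto_evoked_prob=0.0, sustained_factor=0.05),
    ]


def generate_session(config: SyntheticConfig,
                     protocol: Optional[OptoProtocol] = None) -> SessionBundle:
    """Full synthetic session: states, LFP, phase-locked spikes, ground truth."""
    specs = config.unit_specs or default_unit_specs()
    states = gen_state_sequence(config)
    lfp, gt = gen_lfp(states, config)
    gt.unit_params = {s.unit_id: s for s in specs}
    spikes = [
        gen_phase_locked_spikes(lfp, s, states, seed=config.seed) for s in specs
    ]
    movement = np.zeros(lfp.n_samples)
    fs = config.sampling_rate
    for iv in states:
        if iv.label == "AW":
            i0, i1 = int(round(iv.start * fs)), int(round(iv.end * fs))
            movement[i0:i1] = 1.0
    return SessionBundle(
        lfp={"mPFC": lfp},
        spikes=spikes,
        states=states,
        protocol=protocol,
        movement=movement,
        ground_truth=gt,
    )
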