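"""Filtering, envelope computation, oscillation-event detection, and spectra.

High-frequency oscillation (HFO) and ripple detection follow a dual-threshold
rule on the RMS envelope of the band-passed trace: contiguous runs above a
core threshold (in SD units above the background mean) seed events, and each
event's boundaries are then pushed outward to where the envelope falls back
below a lower edge threshold.  Cortical HFOs use core 2 SD / edge 1 SD;
hippocampal ripples use core 5 SD / edge 2 SD.

Time-varying spectra come from an adaptive autoregressive (AAR) model whose
coefficient vector follows a random walk tracked by a Kalman filter, with
fixed-interval (Rauch-Tung-Striebel) smoothing of the coefficient sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import BandDefinition, LfpTrace, OscillationEvent, PsdEstimate

# Elliptic filter design shared by all band-pass operations.  Applied
# forward-backward (zero phase) so spike-phase relations are preserved; the
# two passes double the ripple in dB, so the design ripple is 0.2 dB to keep
# the overall passband response within ~0.5 dB of unity.
FILTER_ORDER = 4
PASSBAND_RIPPLE_DB = 0.2
STOPBAND_ATTEN_DB = 40.0


def design_bandpass(band: BandDefinition, sampling_rate: float) -> np.ndarray:
    """Second-order sections for the zero-phase elliptic band-pass."""
    band.validate_for(sampling_rate)
    return sps.ellip(
        FILTER_ORDER,
        PASSBAND_RIPPLE_DB,
        STOPBAND_ATTEN_DB,
        [band.low, band.high],
        btype="bandpass",
        fs=sampling_rate,
        output="sos",
    )


def bandpass_gain(band: BandDefinition, sampling_rate: float, freq: float) -> float:
    """Amplitude gain of the forward-backward filter at one frequency."""
    sos = design_bandpass(band, sampling_rate)
    _, h = sps.sosfreqz(sos, worN=[freq], fs=sampling_rate)
    return float(np.abs(h[0]) ** 2)  # filtfilt squares the magnitude response


def bandpass_filter(trace: LfpTrace, band: BandDefinition) -> LfpTrace:
    """Zero-phase elliptic band-pass; output has the input's length."""
    sos = design_bandpass(band, trace.sampling_rate)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if trace.n_samples <= padlen:
        raise ValueError(
            f"trace of {trace.n_samples} samples too short for band {band.name} "
            f"(needs > {padlen})"
        )
    filtered = sps.sosfiltfilt(sos, trace.samples)
    return LfpTrace(filtered, trace.sampling_rate, trace.start_time)


def sliding_rms(trace: LfpTrace, window: float = 0.010, step: float = 0.001):
    """Root-mean-square envelope: `window`-long centered windows every `step`.

    Returns (times, rms).  Windows are shrunk at the trace edges rather than
    zero-padded, so a constant trace maps to a constant envelope.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if window < step:
        raise ValueError("window must be >= step")
    if window > trace.duration:
        raise ValueError("window longer than trace")
    fs = trace.sampling_rate
    x2 = trace.samples.astype(float) ** 2
    csum = np.concatenate(([0.0], np.cumsum(x2)))
    half = window / 2.0
    n = trace.n_samples
    step_n = max(1, int(round(step * fs)))
    centers = np.arange(0, n, step_n)
    lo = np.maximum(0, np.ceil((centers - half * fs)).astype(int))
    hi = np.minimum(n, np.floor(centers + half * fs).astype(int) + 1)
    counts = hi - lo
    rms = np.sqrt((csum[hi] - csum[lo]) / counts)
    times = trace.start_time + centers / fs
    return times, rms


def _runs_above(mask: np.ndarray):
    """Start/stop index pairs (half-open) of True runs."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[0::2], edges[1::2]))


def detect_events(
    trace: LfpTrace,
    band: BandDefinition,
    core_sd: float,
    edge_sd: float,
    min_duration: float = 0.015,
    merge_gap: float = 0.010,
    window: float = 0.010,
    step: float = 0.001,
):
    """Dual-threshold oscillation-event detection on the RMS envelope.

    The envelope is z-scored against a background mean/SD estimated over the
    whole epoch with one re-estimation pass that excludes samples already
    above the core threshold (so the events themselves do not inflate the
    background).  Runs above ``core_sd`` seed events; boundaries extend
    outward to the ``edge_sd`` crossing; events closer than ``merge_gap`` are
    merged and events shorter than ``min_duration`` dropped.
    """
    if not (core_sd > edge_sd > 0):
        raise ValueError("need core_sd > edge_sd > 0")
    filtered = bandpass_filter(trace, band)
    times, env = sliding_rms(filtered, window=window, step=step)

    m, s = float(env.mean()), float(env.std())
    if s == 0.0:
        warnings.warn("flat envelope: no background variability, no events")
        return []
    keep = env < m + core_sd * s
    if keep.any():
        m, s = float(env[keep].mean()), float(env[keep].std())
    if s == 0.0:
        warnings.warn("flat background envelope, no events")
        return []
    z = (env - m) / s

    raw = []
    for i0, i1 in _runs_above(z >= core_sd):
        lo = i0
        while lo > 0 and z[lo - 1] >= edge_sd:
            lo -= 1
        hi = i1
        while hi < z.size and z[hi] >= edge_sd:
            hi += 1
        raw.append([lo, hi])

    merged = []
    gap_pts = merge_gap / step
    for lo, hi in raw:
        if merged and lo - merged[-1][1] <= gap_pts:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])

    events = []
    for lo, hi in merged:
        start, end = times[lo], times[min(hi, times.size - 1)]
        if end - start < min_duration:
            continue
        seg = slice(lo, hi)
        peak_idx = lo + int(np.argmax(z[seg]))
        events.append(
            OscillationEvent(
                band=band.name,
                start=float(start),
                end=float(end),
                peak_time=float(times[peak_idx]),
                peak_power_sd=float(z[peak_idx]),
            )
        )
    return events


def welch_psd(trace: LfpTrace, nperseg: int = 512, overlap: float = 0.25) -> PsdEstimate:
    """Welch PSD: Hann window, 512-sample segments, 25% overlap by default."""
    if trace.n_samples < nperseg:
        raise ValueError(f"trace shorter than one segment ({nperseg} samples)")
    freqs, power = sps.welch(
        trace.samples,
        fs=trace.sampling_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)),
        detrend=False,
    )
    return PsdEstimate(freqs, power, method="welch")


@dataclass
class AarSpectrogram:
    """Time-varying AR spectrum plus the tracked model state."""

    times: np.ndarray
    frequencies: np.ndarray
    power: np.ndarray  # (time, freq)
    coefficients: np.ndarray  # smoothed A_t, (time, p)
    sigma_e2: np.ndarray  # innovation variance per output time
    order: int
    sampling_rate: float = 1000.0

    def peak_frequency(self) -> np.ndarray:
        return self.frequencies[np.argmax(self.power, axis=1)]

    def mean_spectrum(self, t0: float = -np.inf, t1: float = np.inf) -> PsdEstimate:
        """Spectrum of the time-averaged model over [t0, t1].

        Averaging the AR coefficients (rather than the per-time power, whose
        mean is dominated by transient near-pole blow-ups) gives a stable
        stationary-segment estimate.
        """
        mask = (self.times >= t0) & (self.times <= t1)
        if not mask.any():
            raise ValueError("no estimates in the requested window")
        a_bar = self.coefficients[mask].mean(axis=0)
        s_bar = float(np.median(self.sigma_e2[mask]))
        power = ar_spectrum(a_bar, s_bar, self.sampling_rate, self.frequencies)
        return PsdEstimate(self.frequencies, power, method="aar")


def aar_spectrogram(
    trace: LfpTrace,
    p: int = 10,
    sigma_w2: float | None = None,
    freq_grid: np.ndarray | None = None,
    forgetting: float = 0.99,
    smooth: bool = True,
    out_rate: float = 100.0,
) -> AarSpectrogram:
    """Adaptive-AR spectrogram via Kalman tracking of the coefficient vector.

    Model: X_t = H_t^T A_t + E_t with H_t = (X_{t-1}, ..., X_{t-p}) and a
    random-walk state A_{t+1} = A_t + W_t (state-noise variance ``sigma_w2``
    per coefficient).  The innovation variance sigma_e^2 is tracked by an
    exponentially weighted average of squared one-step prediction errors.
    After the forward pass an RTS fixed-interval smoother removes the
    estimation lag, and the spectrum is evaluated as

        f(t, w) = sigma_e^2(t) / ( fs * |1 - sum_j A_t(j) e^{-2 pi i w j / fs}|^2 ).

    Output is decimated to ``out_rate`` estimates per second.
    """
    if p < 1:
        raise ValueError("order p must be >= 1")
    x = trace.samples
    n = x.size
    if n <= 10 * p:
        raise ValueError("trace too short for the requested AR order")
    fs = trace.sampling_rate
    var_x = float(np.var(x))
    if sigma_w2 is None:
        # the AR coefficients are dimensionless, so the random-walk step
        # variance is an absolute constant, not scaled to signal variance;
        # 1e-7 balances stationary accuracy (coefficient wander ~0.05 over
        # 30 s) against adaptation speed (~0.5 s to a resonance jump)
        sigma_w2 = 1e-7
    if freq_grid is None:
        freq_grid = np.linspace(0.5, fs / 2 - 0.5, 256)
    freq_grid = np.asarray(freq_grid, dtype=float)

    a = np.zeros(p)
    cov = np.eye(p)
    s_e2 = var_x if var_x > 0 else 1.0

    n_steps = n - p
    a_filt = np.empty((n_steps, p))
    cov_filt = np.empty((n_steps, p, p)) if smooth else None
    s_e2_track = np.empty(n_steps)

    eye = np.eye(p)
    for i in range(n_steps):
        t = p + i
        # predict (random walk: mean unchanged, covariance grows)
        cov = cov + sigma_w2 * eye
        h = x[t - p : t][::-1]  # (X_{t-1}, ..., X_{t-p})
        # innovation and gain
        ch = cov @ h
        s = float(h @ ch) + s_e2
        innov = x[t] - float(h @ a)
        k = ch / s
        a = a + k * innov
        # Joseph-form covariance update for numerical symmetry
        ikh = eye - np.outer(k, h)
        cov = ikh @ cov @ ikh.T + s_e2 * np.outer(k, k)
        s_e2 = forgetting * s_e2 + (1.0 - forgetting) * innov * innov
        a_filt[i] = a
        s_e2_track[i] = s_e2
        if smooth:
            cov_filt[i] = cov

    if smooth:
        a_sm = a_filt.copy()
        for i in range(n_steps - 2, -1, -1):
            pred_cov = cov_filt[i] + sigma_w2 * eye
            gain = np.linalg.solve(pred_cov.T, cov_filt[i].T).T
            a_sm[i] = a_filt[i] + gain @ (a_sm[i + 1] - a_filt[i])
        coeffs = a_sm
    else:
        coeffs = a_filt

    stride = max(1, int(round(fs / out_rate)))
    idx = np.arange(0, n_steps, stride)
    coeffs_out = coeffs[idx]
    s_e2_out = s_e2_track[idx]
    times = trace.start_time + (p + idx) / fs

    # f(t, w) on the grid, vectorized over output times
    j = np.arange(1, p + 1)
    basis = np.exp(-2j * np.pi * np.outer(freq_grid, j) / fs)  # (freq, p)
    denom = np.abs(1.0 - coeffs_out @ basis.T) ** 2  # (time, freq)
    power = s_e2_out[:, None] / (fs * np.maximum(denom, 1e-12))

    return AarSpectrogram(
        times=times,
        frequencies=freq_grid,
        power=power,
        coefficients=coeffs_out,
        sigma_e2=s_e2_out,
        order=p,
        sampling_rate=fs,
    )


def ar_spectrum(coeffs: np.ndarray, sigma_e2: float, fs: float, freqs: np.ndarray) -> np.ndarray:
    """Closed-form AR spectrum for fixed coefficients (oracle for tests)."""
    coeffs = np.asarray(coeffs, dtype=float)
    j = np.arange(1, coeffs.size + 1)
    basis = np.exp(-2j * np.pi * np.outer(np.asarray(freqs, float), j) / fs)
    return sigma_e2 / (fs * np.abs(1.0 - basis @ coeffs) ** 2)
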