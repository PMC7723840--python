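"""Spike-LFP phase-locking statistics.

Instantaneous phase comes from the Hilbert analytic signal of a band-passed
trace, with the convention 0 rad at the oscillation peak and +-pi at the
trough (angles increase with time, so reported degrees live in [0, 360)).

For a sample of n spike phases phi_k:

* mean resultant length  R = |sum_k e^{i phi_k}| / n,
* Rayleigh statistic     Z = n R^2, with tail probability from the finite
  series  P = e^{-Z} (1 + (2Z - Z^2)/(4n)
                        - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)),
  clipped into (0, 1];
* von Mises fit: preferred phase mu = circular mean direction, concentration
  kappa solved from I1(kappa)/I0(kappa) = R by bracketed root finding;
* pairwise phase consistency
  PPC = sum_{j != k} cos(theta_j - theta_k) / (N (N-1)),
  computed through the O(N) identity (n R^2 - 1)/(n - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy import signal as sps
from scipy import special

from .core import LfpTrace, SpikeTrain

N_MIN = 10  # minimum spike count for any circular statistic
SIGNIFICANCE_ALPHA = 0.001
KAPPA_CAP = 1e3


@dataclass
class PhaseSample:
    """Spike phases (radians in [-pi, pi)) for one unit/band/state cell."""

    phases: np.ndarray
    source_band: str = ""
    state_label: str = "all"
    n_total: int = 0  # spikes before interval restriction

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.n_total == 0:
            self.n_total = self.phases.size

    @property
    def n(self) -> int:
        return self.phases.size


@dataclass
class PhaseLockingResult:
    n: int
    r_bar: float
    mu_deg: float
    z: float
    p: float
    kappa: float
    ppc: float
    peak_density: float
    significant: bool


def instantaneous_phase(filtered: LfpTrace) -> np.ndarray:
    """Phase (radians, (-pi, pi]) of the analytic signal of a filtered trace."""
    x = filtered.samples
    if not np.any(x):
        raise ValueError("all-zero input: phase undefined")
    return np.angle(sps.hilbert(x))


def phase_to_deg(phases: np.ndarray) -> np.ndarray:
    return np.mod(np.degrees(phases), 360.0)


def spike_phases(
    spikes: SpikeTrain,
    phase: np.ndarray,
    trace: LfpTrace,
    restrict: Optional[Sequence] = None,
    band: str = "",
    state_label: str = "all",
    method: str = "interpolate",
) -> PhaseSample:
    """Phase of the oscillation at each spike time.

    Phases are interpolated on the circle (through the unwrapped phase), so a
    spike between two samples gets the angular midpoint rather than a naive
    linear blend across the +-pi seam.  ``method='nearest'`` uses the nearest
    sample instead.
    """
    t0 = trace.start_time
    fs = trace.sampling_rate
    times = spikes.times
    n_total = times.size
    if restrict is not None:
        mask = np.zeros(times.size, dtype=bool)
        for iv in restrict:
            start, end = (iv.start, iv.end) if hasattr(iv, "start") else iv
            mask |= (times >= start) & (times < end)
        times = times[mask]
    span_ok = (times >= t0) & (times <= t0 + (phase.size - 1) / fs)
    times = times[span_ok]
    if times.size == 0:
        warnings.warn("no spikes inside restriction intervals")
        return PhaseSample(np.empty(0), band, state_label, n_total)
    if method == "nearest":
        idx = np.clip(np.round((times - t0) * fs).astype(int), 0, phase.size - 1)
        ph = phase[idx]
    else:
        unwrapped = np.unwrap(phase)
        ph = np.interp((times - t0) * fs, np.arange(phase.size), unwrapped)
    ph = np.mod(ph + np.pi, 2 * np.pi) - np.pi
    return PhaseSample(ph, band, state_label, n_total)


def _resultant(phases: np.ndarray):
    c = np.exp(1j * phases).mean()
    return float(np.abs(c)), float(np.angle(c))


def rayleigh_test(sample: PhaseSample | np.ndarray, n_min: int = N_MIN):
    """Rayleigh test for circular uniformity: returns (R_bar, Z, P).

    P uses the finite-series tail approximation (see module docstring); the
    series can go negative for Z large relative to n, so the value is clipped
    into (0, 1].
    """
    phases = sample.phases if isinstance(sample, PhaseSample) else np.asarray(sample)
    n = phases.size
    if n < n_min:
        raise ValueError(f"need at least {n_min} spikes for the Rayleigh test, got {n}")
    r_bar, _ = _resultant(phases)
    z = n * r_bar**2
    p = rayleigh_p(z, n)
    return r_bar, z, p


def rayleigh_p(z, n):
    """Finite-series Rayleigh tail probability, clipped into (0, 1]."""
    z = np.asarray(z, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    tiny = np.finfo(float).tiny
    return float(np.clip(p, tiny, 1.0)) if p.ndim == 0 else np.clip(p, tiny, 1.0)


def bessel_ratio(kappa: float) -> float:
    """I1(kappa)/I0(kappa), numerically stable for large kappa."""
    return float(special.i1e(kappa) / special.i0e(kappa))


def fit_von_mises(sample: PhaseSample | np.ndarray, n_min: int = N_MIN):
    """Fit a von Mises distribution; returns (mu_rad, kappa).

    kappa is the unique non-negative root of I1(k)/I0(k) - R_bar; R_bar very
    close to 1 caps kappa at 1e3 with a warning.
    """
    phases = sample.phases if isinstance(sample, PhaseSample) else np.asarray(sample)
    if phases.size < n_min:
        raise ValueError(f"need at least {n_min} spikes for the von Mises fit")
    r_bar, mu = _resultant(phases)
    kappa = kappa_from_r(r_bar)
    return mu, kappa


def kappa_from_r(r_bar: float) -> float:
    """Invert the Bessel ratio: solve I1(k)/I0(k) = r_bar for k >= 0."""
    if r_bar <= 0.0:
        return 0.0
    if r_bar >= 1.0 - 1e-6:
        warnings.warn("mean resultant length at the degenerate limit; kappa capped")
        return KAPPA_CAP
    if bessel_ratio(KAPPA_CAP) <= r_bar:
        return KAPPA_CAP
    return float(
        optimize.brentq(lambda k: bessel_ratio(k) - r_bar, 0.0, KAPPA_CAP, xtol=1e-8)
    )


def ppc(sample: PhaseSample | np.ndarray) -> float:
    """Pairwise phase consistency via the O(N) identity (n R^2 - 1)/(n - 1)."""
    phases = sample.phases if isinstance(sample, PhaseSample) else np.asarray(sample)
    n = phases.size
    if n < 2:
        raise ValueError("PPC needs at least 2 spikes")
    r_bar, _ = _resultant(phases)
    return (n * r_bar**2 - 1.0) / (n - 1.0)


def ppc_pairwise(phases: np.ndarray) -> float:
    """PPC by the explicit double sum over spike pairs (O(N^2) oracle form)."""
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n < 2:
        raise ValueError("PPC needs at least 2 spikes")
    s, c = np.sin(phases), np.cos(phases)
    total = np.outer(s, s) + np.outer(c, c)
    return float((total.sum() - n) / (n * (n - 1.0)))


def peak_density(kappa: float) -> float:
    """Fitted von Mises density at the preferred phase: e^k / (2 pi I0(k))."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    return float(1.0 / (2.0 * np.pi * special.i0e(kappa)))


def phase_histogram(phases: np.ndarray, n_bins: int = 20):
    """Density-normalized phase histogram over [0, 360) degrees."""
    deg = phase_to_deg(np.asarray(phases))
    counts, edges = np.histogram(deg, bins=n_bins, range=(0.0, 360.0))
    width_rad = np.radians(360.0 / n_bins)
    density = counts / (counts.sum() * width_rad) if counts.sum() else counts.astype(float)
    return edges, density


def analyze_sample(sample: PhaseSample, n_min: int = N_MIN,
                   alpha: float = SIGNIFICANCE_ALPHA) -> PhaseLockingResult:
    """All phase-locking statistics for one spike-phase sample."""
    r_bar, z, p = rayleigh_test(sample, n_min=n_min)
    mu, kappa = fit_von_mises(sample, n_min=n_min)
    return PhaseLockingResult(
        n=sample.n,
        r_bar=r_bar,
        mu_deg=float(np.mod(np.degrees(mu), 360.0)),
        z=z,
        p=p,
        kappa=kappa,
        ppc=ppc(sample),
        peak_density=peak_density(kappa),
        significant=bool(p < alpha),
    )
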