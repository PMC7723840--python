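# Methods

This note documents the models, estimators, and numerical choices behind
`pvcouple`, and what the synthetic-data validation does and does not
establish.

## Signal model and filtering

LFP traces are uniformly sampled voltage series (mV, 1 kHz nominal). All
band-pass operations use a 4th-order elliptic design (0.2 dB passband ripple,
40 dB stopband attenuation) applied forward–backward. The two passes square
the magnitude response, so the effective zero-phase filter stays within
~0.5 dB of unity across the passband (a 6 Hz tone in the 4–8 Hz theta band
comes through at 0.974 amplitude) while doubling stopband rejection.
Zero-phase filtering matters here because spike–phase relations are the
object of study: any group delay would masquerade as a phase preference.
The band registry is fixed per region — mPFC: delta 2–5, theta 4–8,
slow gamma 30–50, fast gamma 50–80, HFO 100–250 Hz; dCA1: delta 2–4,
theta 4–12, gamma 30–80, ripple 100–250 Hz. The mPFC delta band doubles as
the ~4 Hz component prominent in mouse PFC during wakefulness.

## Oscillation-event detection

Events are detected on the RMS envelope of the band-passed trace (10 ms
sliding window, 1 ms step; edge windows are shrunk, not zero-padded). The
envelope is z-scored against a background mean/SD estimated over the whole
analyzed epoch, with one re-estimation pass excluding samples already above
the core threshold so that the events themselves do not inflate the
background. Contiguous runs above the core threshold seed events; boundaries
extend outward to the edge-threshold crossing; events separated by less than
10 ms merge; events shorter than 15 ms are dropped. Defaults: HFO core 2 SD /
edge 1 SD, ripple core 5 SD / edge 2 SD.

Numerical choices: the 15 ms minimum duration corresponds to ~2–3 cycles at
100–250 Hz. A Hann-enveloped 40 ms burst whose peak reaches 4 SD stays above
the 1 SD edge threshold for only ~18–25 ms, so a longer minimum silently
discards genuine short events; with 15 ms, detection sensitivity on embedded
4 SD/40 ms bursts is 0.93–0.97 with ~8 ms median boundary error, at a
false-event rate of ~3/s on pure 1/f noise (the 2 SD core threshold is
deliberately permissive; raise `core_sd` or `min_duration` for conservative
event calls). A perfectly flat envelope (SD = 0) yields no events with a
warning rather than an error.

## Spectral estimation

Welch PSDs use 512-sample Hann segments with 25% overlap (the fraction is
configurable; 75% is the common alternative reading of "1/4 overlapping").
One-sided densities in mV²/Hz; integrated power over unit-variance white
noise recovers 1.0 within a few percent.

The time-varying spectrum uses an adaptive autoregressive model
X_t = Σ_j A_t(j) X_{t−j} + E_t of order p (default 10) whose coefficient
vector follows a random walk A_{t+1} = A_t + W_t. A Kalman filter with
observation vector H_t = (X_{t−1}, …, X_{t−p}) tracks A_t; the covariance
update uses the Joseph form to preserve symmetry/PSD-ness; an RTS
fixed-interval smoother removes the estimation lag. The innovation variance
σ_e²(t) is tracked by an exponentially weighted average of squared one-step
prediction errors (forgetting 0.99). The spectrum is evaluated as
f(t,ω) = σ_e²(t) / (f_s |1 − Σ_j A_t(j) e^{−2πiωj/f_s}|²), decimated to 100
estimates/s by default.

The state-noise variance σ_w² defaults to 1e-7 per coefficient. It is an
absolute constant, not scaled to the signal variance: the AR coefficients are
dimensionless, and larger steps let the tracked vector wander (random-walk
excursions grow as the square root of the step count, shrinking estimated
pole radii and pushing spectral peaks toward DC), while much smaller steps
leave the initial-condition transient unresolved and slow adaptation.
For stationary-segment summaries, `AarSpectrogram.mean_spectrum` evaluates
the spectrum of the time-averaged coefficients rather than averaging per-time
power, which a handful of transient near-pole excursions would otherwise
dominate. With these defaults the tracker locks onto an AR(2) resonance
switch from 6 to 150 Hz within ~0.5 s and places stationary-segment peaks
within 1 Hz of the closed-form AR spectrum across seeds.

## Phase-locking statistics

Instantaneous phase is the angle of the Hilbert analytic signal of the
band-passed trace, with 0° at the oscillation peak and 180° at the trough
(angles increase with time). Spike phases are interpolated through the
unwrapped phase — interpolating naively across the ±π seam, or snapping to
the nearest sample, biases fast bands (at 150 Hz the phase advances ~54° per
1 kHz sample); a nearest-sample mode is available by flag.

For a phase sample of size n (minimum 10 for any statistic):
R̄ = |Σe^{iφ}|/n; Z = nR̄²; P from the finite series
e^{−Z}(1 + (2Z−Z²)/(4n) − (24Z−132Z²+76Z³−9Z⁴)/(288n²)), clipped into
(0, 1] because the series goes negative when Z approaches its maximum n;
significance is declared at P < 0.001. The von Mises concentration κ is the
root of I₁(κ)/I₀(κ) = R̄ found by bracketed bisection (Brent, tolerance
1e-8, ratio computed with exponentially scaled Bessel functions); R̄ ≥ 1−1e-6
caps κ at 1e3 with a warning. PPC is computed by the O(N) identity
(nR̄² − 1)/(n − 1); its exact equality with the explicit pairwise double sum
is a tested invariant, and E[PPC] = (I₁(κ)/I₀(κ))² for von Mises samples is
verified by simulation. Peak coupling density is the fitted von Mises density
at μ, e^κ/(2πI₀(κ)), strictly increasing in κ. Phase histograms default to
20 bins of 18°.

Whether coupling to a transient band (HFO) should use all spikes in a state
or only spikes inside detected events is left to the caller; the default uses
all spikes within the state restriction, which dilutes but does not bias the
coupling estimate when the oscillation is absent between events.

## Optogenetic tagging

A spike is laser-evoked when it falls in (onset, onset + 10 ms]; the window
is half-open at the onset because a spike coincident with the laser rise
cannot have been caused by it, and closed at 10 ms to match the latency
criterion exactly. Firing probability is the fraction of trials with at
least one evoked spike; classification as PV requires probability strictly
greater than 0.60, so a unit at exactly 60% is not tagged. Evoked
spikes/trial is the mean window count (multi-spike trials count fully).
PSTHs are trial-aligned rates (default 3 ms bins, −50 to +100 ms).

Suppression time is measured from the first post-peak PSTH bin below the
pre-onset baseline rate to the first of three consecutive bins recovering to
at least 50% of baseline; a PSTH never dropping below baseline gives 0, and a
zero baseline is flagged undefined. The three-bin run guards against single
noisy bins ending the suppression estimate early. Sustained stimulation
(10 s blocks) is summarized per unit as ON-block versus preceding
equal-length OFF-window rates with a Wilcoxon signed-rank test across units,
and per band as ON/OFF Welch band power with a signed-rank test across
trials; fewer than five units or trials yields the descriptive report
without a test.

## State analysis

Per-state firing rates are spike counts divided by total time in that state;
a state never visited is flagged NaN rather than zero. Subtype ratios floor
the SWS denominator at 0.05 Hz. The elevated-ratio threshold is 1.5: at the
effect sizes typical of state-modulated PV units (3× rate changes), assignment
is insensitive to this choice over a wide range, and the k-medoids
alternative on log-ratios (`cluster_subtypes_kmedoids`) reproduces the
threshold rule's partitions on synthetic populations, so the transparent
threshold rule is the default. The residual REM-only pattern and
non-finite ratios are reported unclassified.

The Friedman test uses the tie-corrected chi-square approximation over
within-unit ranks (exact permutation distributions agree within 0.02 at
n = 6 in tests); Dunn's pairwise z tests on mean ranks are
Bonferroni-corrected over the six state pairs.

The optional LFP state classifier scores 2 s epochs: movement above threshold
→ AW; otherwise the dominant 1–10 Hz peak of a zero-padded Hann periodogram
decides — a prominent peak below 4.6 Hz → SWS, above → REM, no prominent
slow peak → QW — followed by a 3-epoch majority vote. The peak-frequency
rule replaces band-power sums because the delta (2–5 Hz) and theta (4–8 Hz)
bands overlap; summed power cannot separate a 4.4 Hz slow-wave rhythm from a
4.8 Hz theta rhythm, while the peak location can. This classifier is a
convenience for unlabeled sessions, validated only on synthetic data; real
scoring normally uses video plus LFP inspection.

## Synthetic sessions

The generator is statistical, not biophysical. A semi-Markov state sequence
draws per-state dwell times from exponentials (means: AW 60, QW 30, REM 40,
SWS 80 s) left-truncated at 5 s, with uniform transitions among the other
states. The LFP is 1/f^α Gaussian noise (α = 1, 0.05 mV SD) plus per-state
band-limited sinusoids (frequency drawn per interval within the band, random
phase, 100 ms cosine edge ramps): theta with nested slow/fast gamma and a
delta-range component during AW, strong theta in REM, strong delta in SWS,
weak rhythms in QW. HFO bursts are Hann-windowed tones (frequency uniform in
110–240 Hz, duration log-normal with 40 ms mean), embedded at Poisson times
(0.5/s in SWS, 0.3/s in AW by default) with amplitude calibrated so the burst
envelope exceeds the background 100–250 Hz RMS by a configured SD multiple
(default 4). Burst amplitude/duration distributions are not constrained by
published data; they are exposed in the configuration.

Spike trains are inhomogeneous Poisson by thinning with instantaneous rate
base_rate(state) × 2π·vonMises(φ(t); μ, κ), bounded by the exact maximum
base_rate·e^κ/I₀(κ); κ = 0 reduces to a homogeneous Poisson process per
state, and the time-averaged rate equals the base rate when phase is
traversed uniformly. Opto sessions emit, per pulse and with the configured
probability, one evoked spike at onset plus a Gaussian latency (mean 6 ms,
SD 1 ms, truncated into (0, 10 ms] so evoked spikes stay inside the tagging
window), suppress background spikes for the configured duration after each
evoked spike, and in sustained mode scale PV rates up (×3) and pyramidal
rates down (×0.05) inside ON blocks. All randomness flows from a single
session seed through named sub-streams (CRC-split SeedSequences), so every
artifact is reproducible byte-for-byte.

What passing the synthetic validation shows: each estimator recovers the
parameters of data generated under its own assumptions, at realistic sample
sizes, with correctly calibrated null distributions. What it does not show:
robustness to non-sinusoidal or non-stationary oscillations, spike-sorting
contamination, electrode drift, volume-conduction artifacts, movement
artifacts in the LFP, or mislabeled behavioral states — none of which the
generator emulates.

## Problem sizes

Validation runs use 200 s single-state sessions for event detection (~100
embedded bursts), 60 s for AAR tracking, n = 10,000 draws × 100 replicates
for circular-statistic recovery, 100-trial protocols × 100 replicates for
opto tagging, and 50 replicates of 30 units × 10 min/state for subtype
recovery; the full pipeline demonstration uses 120–900 s sessions with four
units. These sizes put Monte-Carlo error well inside each stated tolerance
while keeping the whole suite fast.
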