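# pvcouple

Analysis toolkit for *in vivo* extracellular recordings of cortical
parvalbumin (PV) interneurons: oscillation-band filtering and event
detection, spike–LFP phase-locking statistics, optogenetic tagging, and
behavioral-state-dependent firing analysis — together with a synthetic
session generator that provides ground truth for every stage.

## Who it is for

Electrophysiologists working with tetrode/optrode recordings from mouse
medial prefrontal cortex (mPFC) or hippocampal dCA1: one or more LFP channels
(1 kHz), sorted spike trains, laser stimulation protocols, and
behavioral-state labels (active wakefulness AW, quiet wakefulness QW, REM and
slow-wave sleep SWS). Because raw recordings of this kind are rarely shared,
every analysis here is validated against simulated sessions whose oscillation
events, coupling parameters, firing rates, and evoked-response probabilities
are known exactly.

## What it computes

**Oscillation events.** Each trace is band-pass filtered (zero-phase
elliptic; mPFC bands delta 2–5, theta 4–8, slow gamma 30–50, fast gamma
50–80, HFO 100–250 Hz; dCA1 delta 2–4, theta 4–12, gamma 30–80, ripple
100–250 Hz). The RMS envelope (10 ms window, 1 ms step) is z-scored against
the background; runs above a core threshold seed events and boundaries extend
to an edge threshold (HFO: 2/1 SD; ripple: 5/2 SD).

**Spectra.** Welch PSD (512-point Hann, 25% overlap) and a time-varying
spectrum from an adaptive autoregressive (AAR) model: the AR coefficient
vector A_t follows a random walk tracked by a Kalman filter with
fixed-interval (RTS) smoothing, and

    f(t, ω) = σ_e²(t) / ( f_s · |1 − Σ_j A_t(j) e^{−2πiωj/f_s}|² ).

**Phase locking.** Spike phases are sampled from the Hilbert phase of the
band-filtered LFP (0° = oscillation peak, 180° = trough). For n spike phases:
mean resultant length R̄, preferred phase μ, Rayleigh statistic Z = nR̄² with
the finite-series tail probability

    P = e^{−Z} ( 1 + (2Z − Z²)/(4n) − (24Z − 132Z² + 76Z³ − 9Z⁴)/(288n²) ),

a von Mises fit with concentration κ solved from I₁(κ)/I₀(κ) = R̄, the peak
coupling density e^κ/(2πI₀(κ)), and the bias-free pairwise phase consistency

    PPC = Σ_{j≠k} cos(θ_j − θ_k) / (N(N−1))  =  (nR̄² − 1)/(n − 1).

**Optogenetic tagging.** Spikes in the 10 ms window after a laser pulse
(half-open: a spike at the onset does not count, one at exactly +10 ms does)
are evoked; units with evoked firing probability strictly above 60% over the
trials are tagged PV. Latency, evoked spikes/trial, PSTHs, post-burst
suppression time, and sustained-stimulation (10 s) ON/OFF rate and band-power
comparisons (Wilcoxon signed-rank) are also provided.

**State subtyping.** Per-state firing rates feed the ratios FR_AW/FR_SWS and
FR_REM/FR_SWS: subtype 1 = AW-elevated, subtype 2 = AW+REM-elevated,
subtype 3 = state-invariant (ratio ≥ 1.5 counts as elevated). Cohort state
effects use the Friedman test with Dunn–Bonferroni post hocs. A rule-based
LFP/movement state classifier is included for sessions without manual labels.

## Worked example

```python
from pvcouple import SyntheticConfig, RunConfig, generate_session, run_pipeline

bundle = generate_session(SyntheticConfig(seed=7, total_duration=900.0))
run_pipeline(bundle, RunConfig(seed=7), "demo")
```

The default synthetic session contains three HFO-coupled PV units (ground
truth κ = 2, μ = 220°, one per firing subtype) and one uncoupled pyramidal
unit. `demo/phaselock/results.csv` then contains (theta and HFO rows over the
whole session):

```
unit_id  band    n    r_bar  mu_deg      z          p   kappa        ppc  significant
    pv1 theta 7254 0.006772   146.2 0.3327      0.717 0.01354 -9.201e-05            0
    pv2 theta 7975  0.00571   323.3 0.2601      0.771 0.01142 -9.279e-05            0
    pv3 theta 7166  0.01032     149 0.7638     0.4659 0.02065 -3.296e-05            0
    pv1   hfo 7254   0.6954   220.7   3508 2.225e-308   1.986     0.4836            1
    pv2   hfo 7975   0.6996   218.9   3904 2.225e-308   2.011     0.4894            1
    pv3   hfo 7166   0.6965   219.9   3476 2.225e-308   1.992      0.485            1
```

All three PV units are significantly locked to the HFO band (P below the
0.001 criterion; the series P underflows to the smallest positive float) with
preferred phases within ~1° of the generating 220° trough-locking and fitted
κ within 1% of the generating κ = 2; none is locked to theta. The subtype
table (`demo/states/subtypes.csv`) recovers each unit's rate profile:

```
unit_id  rate_aw  rate_qw  rate_rem  rate_sws  ratio_aw  ratio_rem  subtype
    pv1     15.2     4.83      4.55      4.99      3.05      0.912        1
    pv2     14.6     4.89      15.5      4.97      2.93       3.11        2
    pv3     7.64     8.43      8.07      8.07     0.946          1        3
```

i.e. the AW-elevated, AW+REM-elevated, and state-invariant profiles are
assigned subtypes 1, 2 and 3 exactly as generated (rates are in Hz; the
ratios are FR_AW/FR_SWS and FR_REM/FR_SWS).

The same stages are available from the shell:

```bash
pvcouple simulate --seed 7 --out session/
pvcouple detect session/ --band hfo --core-sd 2 --edge-sd 1 --out events.csv
pvcouple run session/ --seed 7 --out results/
```

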