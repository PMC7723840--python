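"""Behavioral-state-conditioned firing analysis and subtype assignment.

Units are subtyped from the ratios FR_AW/FR_SWS and FR_REM/FR_SWS of their
state-conditioned mean firing rates: subtype 1 fires preferentially during
active wakefulness, subtype 2 during both AW and REM sleep, and subtype 3
shows no state preference.  A ratio counts as "elevated" at >= 1.5 by
default.  State effects within a cohort are tested with the Friedman test
(chi-square approximation, tie-corrected) followed by Dunn's pairwise
comparisons with Bonferroni correction over the six state pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

from .core import STATES, LfpTrace, SpikeTrain, StateInterval
from .signal_processing import welch_psd

RATE_FLOOR = 0.05  # Hz, guards ratio denominators
RATIO_THRESHOLD = 1.5


@dataclass
class StateRates:
    unit_id: str
    rates: Dict[str, float]  # Hz per state; nan when the state has no time
    state_times: Dict[str, float]  # seconds spent in each state


@dataclass
class SubtypeAssignment:
    unit_id: str
    ratio_aw: float
    ratio_rem: float
    subtype: Optional[int]  # 1, 2, 3, or None (unclassified: REM-only pattern)
    floored: bool = False


def state_firing_rates(spikes: SpikeTrain, intervals: Sequence[StateInterval]) -> StateRates:
    """Mean firing rate per behavioral state (spike count / time in state)."""
    if not intervals:
        raise ValueError("no state intervals")
    times = {s: 0.0 for s in STATES}
    counts = {s: 0 for s in STATES}
    for iv in intervals:
        times[iv.label] += iv.duration
        lo = np.searchsorted(spikes.times, iv.start)
        hi = np.searchsorted(spikes.times, iv.end)
        counts[iv.label] += int(hi - lo)
    rates = {}
    for s in STATES:
        if times[s] > 0:
            rates[s] = counts[s] / times[s]
        else:
            rates[s] = float("nan")
    return StateRates(spikes.unit_id, rates, times)


def subtype_ratios(rates: StateRates, floor: float = RATE_FLOOR):
    """(FR_AW/FR_SWS, FR_REM/FR_SWS), denominators floored to avoid blow-up."""
    sws = rates.rates.get("SWS", float("nan"))
    floored = not np.isfinite(sws) or sws < floor
    denom = floor if floored else sws
    return rates.rates["AW"] / denom, rates.rates["REM"] / denom, floored


def assign_subtype(ratio_aw: float, ratio_rem: float,
                   threshold: float = RATIO_THRESHOLD) -> Optional[int]:
    """Threshold rule on the two rate ratios.

    Subtype 1: AW elevated only; subtype 2: AW and REM elevated; subtype 3:
    neither.  The residual REM-only pattern, or non-finite ratios (a state
    never visited), are left unclassified (None).
    """
    if not (np.isfinite(ratio_aw) and np.isfinite(ratio_rem)):
        return None
    aw_el = ratio_aw >= threshold
    rem_el = ratio_rem >= threshold
    if aw_el and not rem_el:
        return 1
    if aw_el and rem_el:
        return 2
    if not aw_el and not rem_el:
        return 3
    return None


def subtype_unit(spikes: SpikeTrain, intervals: Sequence[StateInterval],
                 floor: float = RATE_FLOOR,
                 threshold: float = RATIO_THRESHOLD) -> SubtypeAssignment:
    rates = state_firing_rates(spikes, intervals)
    r_aw, r_rem, floored = subtype_ratios(rates, floor=floor)
    return SubtypeAssignment(
        unit_id=spikes.unit_id,
        ratio_aw=float(r_aw),
        ratio_rem=float(r_rem),
        subtype=assign_subtype(r_aw, r_rem, threshold=threshold),
        floored=floored,
    )


def cluster_subtypes_kmedoids(ratio_pairs, n_clusters: int = 3, max_iter: int = 100):
    """Alternative subtype assignment: k-medoids (PAM) on log-ratios.

    ``ratio_pairs`` is an (n, 2) array of (FR_AW/FR_SWS, FR_REM/FR_SWS).
    Clusters are labelled by their medoid's position against the threshold
    rule (AW-elevated only -> 1, both -> 2, otherwise 3), so the output is
    comparable with :func:`assign_subtype`.  Deterministic: medoids are
    initialized greedily (the point minimizing total distance first).
    """
    pts = np.log(np.maximum(np.asarray(ratio_pairs, dtype=float), 1e-6))
    n = pts.shape[0]
    if n < n_clusters:
        raise ValueError("need at least one point per cluster")
    dist = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < n_clusters:
        d_min = dist[:, medoids].min(axis=1)
        medoids.append(int(np.argmax(d_min)))
    medoids = np.array(medoids)
    for _ in range(max_iter):
        labels = np.argmin(dist[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for k in range(n_clusters):
            members = np.flatnonzero(labels == k)
            if members.size:
                within = dist[np.ix_(members, members)].sum(axis=1)
                new_medoids[k] = members[int(np.argmin(within))]
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    labels = np.argmin(dist[:, medoids], axis=1)
    cluster_subtype = {}
    for k, m in enumerate(medoids):
        r_aw, r_rem = np.exp(pts[m])
        cluster_subtype[k] = assign_subtype(r_aw, r_rem) or 3
    return np.array([cluster_subtype[k] for k in labels]), medoids


@dataclass
class FriedmanResult:
    statistic: float
    pvalue: float
    n_units: int
    n_conditions: int
    posthoc: Dict[tuple, float]  # (state_i, state_j) -> Bonferroni-adjusted p


def friedman_statistic(matrix: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square over within-row average ranks."""
    matrix = np.asarray(matrix, dtype=float)
    n, k = matrix.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, matrix)
    col_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    # tie correction
    tie_term = 0.0
    for row in matrix:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_term / (n * k * (k**2 - 1))
    if denom <= 0:
        return 0.0
    return float(stat / denom)


def state_effect_test(rate_matrix: np.ndarray,
                      condition_labels: Sequence[str] = STATES,
                      alpha: float = 0.05) -> FriedmanResult:
    """Friedman test across repeated state conditions plus Dunn post hoc.

    ``rate_matrix`` is units x conditions.  Dunn's pairwise z statistics use
    the mean-rank difference with SE sqrt(k(k+1)/(6n)); p-values are two
    sided and Bonferroni-multiplied by the number of pairs.
    """
    matrix = np.asarray(rate_matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 3:
        raise ValueError("need at least 3 units (rows)")
    n, k = matrix.shape
    if np.all(matrix == matrix[:, :1]):
        return FriedmanResult(0.0, 1.0, n, k, {})
    stat = friedman_statistic(matrix)
    pvalue = float(stats.chi2.sf(stat, k - 1))

    ranks = np.apply_along_axis(stats.rankdata, 1, matrix)
    mean_ranks = ranks.mean(axis=0)
    n_pairs = k * (k - 1) // 2
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    posthoc = {}
    for i in range(k):
        for j in range(i + 1, k):
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * n_pairs)
            posthoc[(condition_labels[i], condition_labels[j])] = float(p)
    return FriedmanResult(stat, pvalue, n, k, posthoc)


# ---------------------------------------------------------------------------
# Rule-based LFP state classifier (best effort; real scoring used video)

def classify_states_from_lfp(
    pfc: LfpTrace,
    ca1: Optional[LfpTrace] = None,
    movement: Optional[np.ndarray] = None,
    epoch: float = 2.0,
    move_threshold: float = 0.5,
    split_freq: float = 4.6,
    prominence_threshold: float = 5.0,
) -> List[StateInterval]:
    """Score 2 s epochs into AW/QW/REM/SWS from the dominant slow rhythm.

    Movement above threshold marks AW.  Without movement, each epoch's
    zero-padded Hann periodogram is searched for its dominant peak in the
    1-10 Hz range: a prominent peak below ``split_freq`` marks SWS (delta /
    slow-wave dominated), a prominent peak above marks REM (theta dominated),
    and epochs without a prominent slow rhythm (including silent input) are
    QW.  The frequency split is used instead of band-power sums because the
    delta (2-5 Hz) and theta (4-8 Hz) bands overlap.  Epoch labels are
    smoothed by a 3-epoch majority vote and merged.
    """
    fs = pfc.sampling_rate
    n_epochs = int(pfc.duration // epoch)
    if n_epochs == 0:
        raise ValueError("trace shorter than one epoch")
    labels = []
    seg_len = int(epoch * fs)
    nfft = 1 << int(np.ceil(np.log2(seg_len * 8)))  # ~0.06 Hz grid at 2 s
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    win = np.hanning(seg_len)

    def dominant_peak(seg: np.ndarray):
        spec = np.abs(np.fft.rfft(seg * win, nfft)) ** 2
        slow = (freqs >= 1.0) & (freqs <= 10.0)
        ref = (freqs >= 1.0) & (freqs <= 30.0)
        med = float(np.median(spec[ref]))
        i = int(np.argmax(spec[slow]))
        peak = float(spec[slow][i])
        prom = peak / med if med > 0 else np.inf
        return float(freqs[slow][i]), prom

    for e in range(n_epochs):
        i0 = e * seg_len
        seg = pfc.samples[i0 : i0 + seg_len]
        if movement is not None:
            mv = float(np.mean(movement[i0 : i0 + seg_len]))
            if mv > move_threshold:
                labels.append("AW")
                continue
        if not np.any(seg):
            labels.append("QW")
            continue
        f_peak, prom = dominant_peak(seg)
        if ca1 is not None:
            cf, cprom = dominant_peak(ca1.samples[i0 : i0 + seg_len])
            if cprom > prom:
                f_peak, prom = cf, cprom
        if prom < prominence_threshold:
            labels.append("QW")
        elif f_peak >= split_freq:
            labels.append("REM")
        else:
            labels.append("SWS")

    # 3-epoch majority smoothing
    smoothed = list(labels)
    for i in range(1, len(labels) - 1):
        trio = labels[i - 1 : i + 2]
        for lab in set(trio):
            if trio.count(lab) >= 2:
                smoothed[i] = lab
                break

    intervals: List[StateInterval] = []
    for i, lab in enumerate(smoothed):
        start, end = i * epoch, (i + 1) * epoch
        if intervals and intervals[-1].label == lab:
            intervals[-1] = StateInterval(lab, intervals[-1].start, end)
        else:
            intervals.append(StateInterval(lab, start, end))
    # extend the last interval to cover the trailing partial epoch
    if intervals and intervals[-1].end < pfc.duration:
        last = intervals[-1]
        intervals[-1] = StateInterval(last.label, last.start, pfc.duration)
    return intervals
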