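"""End-to-end session analysis: events -> spectra -> phase locking -> opto
tagging -> state subtyping, with deterministic, config-hashed outputs.

Output layout (one directory per run)::

    events/      per-region, per-band oscillation event tables (CSV)
    psd/         Welch PSDs per region and state (CSV)
    phaselock/   per unit x state x band circular statistics (CSV)
    opto/        tagging table / sustained-stimulation report
    states/      rates, subtype assignments, Friedman results
    report.json  run summary (counts, config hash)
    config.json  the run configuration, archived verbatim
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from . import io as pio
from .core import (
    REGION_BANDS,
    STATES,
    LfpTrace,
    SessionBundle,
    check_tiling,
    intervals_for_state,
)
from .opto import sustained_effect, tag_unit
from .phase_locking import N_MIN, analyze_sample, instantaneous_phase, spike_phases
from .signal_processing import bandpass_filter, detect_events, welch_psd
from .states import state_effect_test, state_firing_rates, subtype_unit

logger = logging.getLogger("pvcouple")

FLOAT_FMT = pio.FLOAT_FMT

# dual-threshold settings per event band: (core_sd, edge_sd)
DEFAULT_THRESHOLDS = {"hfo": (2.0, 1.0), "ripple": (5.0, 2.0)}


@dataclass
class RunConfig:
    """Serializable knobs of a pipeline run."""

    seed: int = 0
    core_sd: float = 2.0
    edge_sd: float = 1.0
    ripple_core_sd: float = 5.0
    ripple_edge_sd: float = 2.0
    min_duration: float = 0.015
    merge_gap: float = 0.010
    alpha: float = 0.001
    n_min: int = N_MIN
    opto_window: float = 0.010
    prob_threshold: float = 0.60
    ratio_threshold: float = 1.5
    rate_floor: float = 0.05
    phaselock_bands: tuple = ("delta", "theta", "slow_gamma", "fast_gamma", "hfo")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phaselock_bands"] = list(d["phaselock_bands"])
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def validate_bundle(bundle: SessionBundle) -> list:
    """Machine-readable diagnostics; empty list means the bundle is clean."""
    issues = []
    rates = {r: tr.sampling_rate for r, tr in bundle.lfp.items()}
    if len(set(rates.values())) > 1:
        issues.append({"kind": "sampling_rate", "detail": f"mixed rates {rates}"})
    durations = {r: tr.duration for r, tr in bundle.lfp.items()}
    if max(durations.values()) - min(durations.values()) > 1.0:
        issues.append({"kind": "time_base", "detail": f"mismatched durations {durations}"})
    for tr in bundle.spikes:
        if tr.times.size > 1 and np.any(np.diff(tr.times) < 0):
            issues.append({"kind": "spike_order", "detail": f"unit {tr.unit_id} unsorted"})
        if tr.times.size and tr.times[-1] > bundle.duration + 1.0:
            issues.append(
                {"kind": "spike_span", "detail": f"unit {tr.unit_id} exceeds session span"}
            )
    tiling = check_tiling(bundle.states, bundle.duration, atol=1e-6)
    for msg in tiling:
        issues.append({"kind": "state_tiling", "detail": msg})
    if bundle.protocol is not None:
        onsets = bundle.protocol.pulse_onsets
        if onsets[-1] > bundle.duration:
            issues.append({"kind": "protocol", "detail": "pulses extend past session end"})
    return issues


def _fatal(issues) -> bool:
    return any(i["kind"] in ("sampling_rate", "time_base") for i in issues)


def run_pipeline(bundle: SessionBundle, config: RunConfig, out_dir) -> dict:
    """Run every applicable stage and write the report bundle to ``out_dir``."""
    out = Path(out_dir)
    issues = validate_bundle(bundle)
    if _fatal(issues):
        raise ValueError(f"bundle validation failed: {issues}")
    for issue in issues:
        logger.warning("validation: %s", issue)

    for sub in ("events", "psd", "phaselock", "opto", "states"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    chash = config.config_hash
    summary: dict = {"config_hash": chash, "issues": issues, "stages": {}}
    pio.write_json(config.to_dict(), out / "config.json")

    # --- oscillation events -------------------------------------------------
    n_events = {}
    for region, trace in bundle.lfp.items():
        bands = REGION_BANDS.get(region, REGION_BANDS["mPFC"])
        for band_name, (core, edge) in (
            ("hfo", (config.core_sd, config.edge_sd)),
            ("ripple", (config.ripple_core_sd, config.ripple_edge_sd)),
        ):
            if band_name not in bands:
                continue
            events = detect_events(
                trace, bands[band_name], core, edge,
                min_duration=config.min_duration, merge_gap=config.merge_gap,
            )
            pio.write_events_csv(events, out / "events" / f"{region}_{band_name}.csv")
            n_events[f"{region}:{band_name}"] = len(events)
    summary["stages"]["events"] = n_events

    # --- Welch PSDs per region and state ------------------------------------
    psd_counts = 0
    for region, trace in bundle.lfp.items():
        rows = []
        psd = welch_psd(trace)
        for f, p in zip(psd.frequencies, psd.power):
            rows.append({"state": "all", "freq_hz": f, "power": p})
        for state in STATES:
            ivs = intervals_for_state(bundle.states, state)
            segs = [trace.slice(iv.start, iv.end) for iv in ivs]
            segs = [s for s in segs if s.n_samples >= 512]
            if not segs:
                continue
            acc = None
            for s in segs:
                est = welch_psd(s)
                w = s.n_samples
                acc = est.power * w if acc is None else acc + est.power * w
            total = sum(s.n_samples for s in segs)
            for f, p in zip(psd.frequencies, acc / total):
                rows.append({"state": state, "freq_hz": f, "power": p})
            psd_counts += 1
        pd.DataFrame(rows).to_csv(
            out / "psd" / f"{region}_welch.csv", index=False, float_format=FLOAT_FMT
        )
    summary["stages"]["psd"] = psd_counts

    # --- phase locking per unit x state x band -------------------------------
    pl_rows = []
    region = "mPFC" if "mPFC" in bundle.lfp else next(iter(bundle.lfp))
    trace = bundle.lfp[region]
    bands = REGION_BANDS.get(region, REGION_BANDS["mPFC"])
    for band_name in config.phaselock_bands:
        if band_name not in bands:
            continue
        filtered = bandpass_filter(trace, bands[band_name])
        phase = instantaneous_phase(filtered)
        for unit in bundle.spikes:
            for state in ("all",) + STATES:
                ivs = (
                    None if state == "all" else intervals_for_state(bundle.states, state)
                )
                if ivs is not None and not ivs:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sample = spike_phases(
                        unit, phase, trace, restrict=ivs,
                        band=band_name, state_label=state,
                    )
                row = {
                    "unit_id": unit.unit_id,
                    "state": state,
                    "band": band_name,
                    "n": sample.n,
                }
                if sample.n >= config.n_min:
                    res = analyze_sample(sample, n_min=config.n_min, alpha=config.alpha)
                    row.update(
                        r_bar=res.r_bar, mu_deg=res.mu_deg, z=res.z, p=res.p,
                        kappa=res.kappa, ppc=res.ppc, peak_density=res.peak_density,
                        significant=int(res.significant),
                    )
                pl_rows.append(row)
    pl_df = pd.DataFrame(pl_rows)
    pl_df.to_csv(out / "phaselock" / "results.csv", index=False, float_format=FLOAT_FMT)
    summary["stages"]["phaselock"] = len(pl_rows)

    # --- opto tagging / sustained stimulation -------------------------------
    if bundle.protocol is not None and bundle.protocol.mode == "pulse":
        tag_rows = []
        for unit in bundle.spikes:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = tag_unit(
                    unit, bundle.protocol,
                    window=config.opto_window, prob_threshold=config.prob_threshold,
                )
            tag_rows.append(
                {
                    "unit_id": res.unit_id,
                    "firing_probability": res.firing_probability,
                    "mean_latency_s": res.mean_latency,
                    "evoked_per_trial": res.evoked_spikes_per_trial,
                    "suppression_s": res.suppression_time,
                    "is_pv": int(res.is_pv),
                }
            )
        pd.DataFrame(tag_rows).to_csv(
            out / "opto" / "tags.csv", index=False, float_format=FLOAT_FMT
        )
        summary["stages"]["opto"] = {
            "n_units": len(tag_rows),
            "n_pv": int(sum(r["is_pv"] for r in tag_rows)),
        }
    elif bundle.protocol is not None and bundle.protocol.mode == "sustained":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = sustained_effect(
                bundle.spikes, bundle.protocol, trace, list(bands.values())
            )
        slim = {
            "n_units": report["n_units"],
            "n_trials": report["n_trials"],
            "rate_test": report["rate_test"],
            "unit_rates": report["unit_rates"],
            "band_power": [
                {k: v for k, v in row.items() if k not in ("power_on", "power_off")}
                for row in report.get("band_power", [])
            ],
        }
        pio.write_json(slim, out / "opto" / "sustained.json")
        summary["stages"]["opto"] = {"mode": "sustained", "n_units": report["n_units"]}
    else:
        summary["stages"]["opto"] = None
        logger.info("no opto protocol: tagging stage skipped")

    # --- state-dependent firing ----------------------------------------------
    state_rows = []
    rate_matrix = []
    for unit in bundle.spikes:
        rates = state_firing_rates(unit, bundle.states)
        assign = subtype_unit(
            unit, bundle.states, floor=config.rate_floor,
            threshold=config.ratio_threshold,
        )
        row = {"unit_id": unit.unit_id, "cell_class": unit.cell_class}
        row.update({f"rate_{s.lower()}": rates.rates[s] for s in STATES})
        row.update(
            ratio_aw=assign.ratio_aw, ratio_rem=assign.ratio_rem,
            subtype=assign.subtype if assign.subtype is not None else -1,
        )
        state_rows.append(row)
        if all(np.isfinite(rates.rates[s]) for s in STATES):
            rate_matrix.append([rates.rates[s] for s in STATES])
    pd.DataFrame(state_rows).to_csv(
        out / "states" / "subtypes.csv", index=False, float_format=FLOAT_FMT
    )
    if len(rate_matrix) >= 3:
        fr = state_effect_test(np.array(rate_matrix))
        pio.write_json(
            {
                "statistic": fr.statistic,
                "p": fr.pvalue,
                "n_units": fr.n_units,
                "posthoc": {f"{a}-{b}": p for (a, b), p in fr.posthoc.items()},
            },
            out / "states" / "friedman.json",
        )
        summary["stages"]["state_test"] = {"p": fr.pvalue}
    else:
        summary["stages"]["state_test"] = None
    pio.write_states_csv(bundle.states, out / "states" / "intervals.csv")

    summary["stages"]["n_units"] = len(bundle.spikes)
    pio.write_json(summary, out / "report.json")
    return summary
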