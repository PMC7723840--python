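"""Plain-text and HDF5 interchange for sessions and analysis tables.

Formats: LFP as two-column CSV (time_s, mv) or HDF5 (dataset ``samples`` with
a ``sampling_rate`` attribute); spikes as CSV (unit_id, time_s); states as
CSV (label, start_s, end_s); events as CSV (band, start_s, end_s, peak_s,
peak_sd); ground truth and reports as JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .core import LfpTrace, OscillationEvent, SpikeTrain, StateInterval

FLOAT_FMT = "%.10g"


def write_lfp_csv(trace: LfpTrace, path) -> None:
    df = pd.DataFrame({"time_s": trace.times, "mv": trace.samples})
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_lfp_csv(path) -> LfpTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / np.median(np.diff(t)) if t.size > 1 else 1000.0
    return LfpTrace(df["mv"].to_numpy(), float(round(fs, 6)), float(t[0]))


def write_lfp_hdf5(trace: LfpTrace, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        ds = f.create_dataset("samples", data=trace.samples)
        ds.attrs["sampling_rate"] = trace.sampling_rate
        ds.attrs["start_time"] = trace.start_time


def read_lfp_hdf5(path) -> LfpTrace:
    import h5py

    with h5py.File(path, "r") as f:
        ds = f["samples"]
        return LfpTrace(ds[...], float(ds.attrs["sampling_rate"]),
                        float(ds.attrs.get("start_time", 0.0)))


def write_spikes_csv(trains: List[SpikeTrain], path) -> None:
    rows = [
        {"unit_id": tr.unit_id, "cell_class": tr.cell_class, "time_s": t}
        for tr in trains
        for t in tr.times
    ]
    pd.DataFrame(rows, columns=["unit_id", "cell_class", "time_s"]).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_spikes_csv(path) -> List[SpikeTrain]:
    df = pd.read_csv(path)
    trains = []
    for uid, grp in df.groupby("unit_id", sort=True):
        cls = str(grp["cell_class"].iloc[0]) if "cell_class" in grp else "unknown"
        trains.append(SpikeTrain(np.sort(grp["time_s"].to_numpy()), str(uid), cls))
    return trains


def write_states_csv(intervals: List[StateInterval], path) -> None:
    df = pd.DataFrame(
        [{"label": iv.label, "start_s": iv.start, "end_s": iv.end} for iv in intervals]
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_states_csv(path) -> List[StateInterval]:
    df = pd.read_csv(path)
    return [
        StateInterval(str(r.label), float(r.start_s), float(r.end_s))
        for r in df.itertuples()
    ]


def write_events_csv(events: List[OscillationEvent], path) -> None:
    df = pd.DataFrame(
        [
            {
                "band": e.band,
                "start_s": e.start,
                "end_s": e.end,
                "peak_s": e.peak_time,
                "peak_sd": e.peak_power_sd,
            }
            for e in events
        ],
        columns=["band", "start_s", "end_s", "peak_s", "peak_sd"],
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_events_csv(path) -> List[OscillationEvent]:
    df = pd.read_csv(path)
    return [
        OscillationEvent(str(r.band), float(r.start_s), float(r.end_s),
                         float(r.peak_s), float(r.peak_sd))
        for r in df.itertuples()
    ]


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def ground_truth_to_dict(gt) -> dict:
    return {
        "events": [asdict(e) for e in gt.events],
        "unit_params": {uid: asdict(s) for uid, s in gt.unit_params.items()},
        "state_intervals": [asdict(iv) for iv in gt.state_intervals],
    }
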