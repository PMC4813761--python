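"""Text and HDF5 input/output.

Events travel as tab-separated text (one row per event, header row
mandatory, empty fields for absent values); continuous recordings, source
series and time-frequency images live in HDF5 containers with a
ground-truth group when the data are simulated.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd

from .sim.race import SessionBehavior
from .sim.sources import events_table
from .sim.sensors import SensorRecording

__all__ = [
    "write_events_tsv",
    "read_events_tsv",
    "write_summary_tsv",
    "save_recording",
    "load_recording",
    "sha256_file",
    "write_manifest",
]

EVENT_COLUMNS = [
    "onset_s",
    "duration_s",
    "event_type",
    "trial_index",
    "condition",
    "outcome",
    "soa_s",
    "rt_s",
]


def write_events_tsv(session_or_events: Union[SessionBehavior, pd.DataFrame], path) -> Path:
    """Write the events table in the package's TSV dialect."""
    ev = (
        events_table(session_or_events)
        if isinstance(session_or_events, SessionBehavior)
        else session_or_events
    )
    out = pd.DataFrame(
        {
            "onset_s": ev["onset"],
            "duration_s": ev["duration"],
            "event_type": ev["event_type"],
            "trial_index": ev["trial_index"],
            "condition": ev.get("condition", ""),
            "outcome": ev["outcome"],
            "soa_s": ev["soa"],
            "rt_s": ev["rt"],
        }
    )
    path = Path(path)
    out.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.6f")
    return path


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events file {path} lacks columns {sorted(missing)}")
    return df.rename(
        columns={
            "onset_s": "onset",
            "duration_s": "duration",
            "soa_s": "soa",
            "rt_s": "rt",
        }
    )


def write_summary_tsv(rows: pd.DataFrame, path) -> Path:
    """Per-session behavioral summary rows (the printed-table roster)."""
    path = Path(path)
    rows.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.4f")
    return path


def _write_ds(group: h5py.Group, name: str, data) -> None:
    group.create_dataset(name, data=data, track_times=False)


def save_recording(rec: SensorRecording, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        _write_ds(f, "data", rec.data)
        f.attrs["sfreq"] = rec.sfreq
        f.attrs["t0"] = rec.t0
        _write_ds(f, "channel_names", np.array(rec.channel_names, dtype="S"))
        if rec.channel_positions is not None:
            _write_ds(f, "channel_positions", rec.channel_positions)
        if rec.events is not None:
            ev = f.create_group("events")
            _write_ds(ev, "onset", rec.events["onset"].to_numpy(float))
            _write_ds(ev, "event_type", rec.events["event_type"].to_numpy(dtype="S"))
            _write_ds(ev, "trial_index", rec.events["trial_index"].to_numpy(int))
        gt = rec.ground_truth
        if gt:
            g = f.create_group("ground_truth")
            if "source_data" in gt:
                _write_ds(g, "source_data", gt["source_data"])
            if "orientations" in gt:
                _write_ds(g, "orientations", gt["orientations"])
            if "names" in gt:
                _write_ds(g, "names", np.array(gt["names"], dtype="S"))
    return path


def load_recording(path) -> SensorRecording:
    with h5py.File(path, "r") as f:
        events = None
        if "events" in f:
            events = pd.DataFrame(
                {
                    "onset": f["events/onset"][()],
                    "event_type": [s.decode() for s in f["events/event_type"][()]],
                    "trial_index": f["events/trial_index"][()],
                }
            )
        gt = {}
        if "ground_truth" in f:
            g = f["ground_truth"]
            for k in g:
                v = g[k][()]
                gt[k] = [s.decode() for s in v] if v.dtype.kind == "S" else v
        return SensorRecording(
            data=f["data"][()],
            sfreq=float(f.attrs["sfreq"]),
            channel_names=[s.decode() for s in f["channel_names"][()]],
            channel_positions=f["channel_positions"][()] if "channel_positions" in f else None,
            events=events,
            t0=float(f.attrs.get("t0", 0.0)),
            ground_truth=gt,
        )


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(paths, out_path, meta: Optional[dict] = None) -> Path:
    out_path = Path(out_path)
    entries = {str(Path(p).name): sha256_file(p) for p in paths}
    payload = {"files": entries}
    if meta:
        payload["meta"] = meta
    out_path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return out_path
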