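"""File I/O: TraceSet HDF5, long-format CSV tables, JSON summaries, YAML config.

HDF5 datasets are written with ``track_times=False`` so identical data
produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd
import yaml

from fearscope.core import DataError, EventSeries, TraceSet
from fearscope.synthetic import ExperimentSchedule


def write_traceset(path, traceset: TraceSet) -> None:
    with h5py.File(path, "w") as f:
        for name, data in (
            ("traces", traceset.traces),
            ("coords", traceset.coords),
            ("plane", traceset.plane),
            ("neuron_ids", traceset.neuron_ids),
        ):
            f.create_dataset(name, data=data, track_times=False)
        f.attrs["rate"] = traceset.rate


def read_traceset(path) -> TraceSet:
    try:
        with h5py.File(path, "r") as f:
            return TraceSet(
                traces=f["traces"][...],
                coords=f["coords"][...],
                plane=f["plane"][...],
                rate=float(f.attrs["rate"]),
                neuron_ids=f["neuron_ids"][...],
            )
    except (KeyError, OSError) as exc:
        raise DataError(f"cannot read TraceSet from {path}: {exc}") from exc


def write_events(path, events: EventSeries) -> None:
    events.table.to_csv(path, index=False)


def read_events(path) -> EventSeries:
    try:
        table = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise DataError(f"malformed events CSV {path}: {exc}") from exc
    if table.empty:
        return EventSeries.empty()
    return EventSeries(table)


def write_behavior(path, movement_index: np.ndarray, freezing, frame_rate: float) -> None:
    n = len(movement_index)
    frame = pd.DataFrame(
        {
            "time_s": np.arange(n) / frame_rate,
            "movement_index": movement_index,
            "freezing": np.asarray(freezing, dtype=int)
            if freezing is not None
            else np.full(n, -1),
        }
    )
    frame.to_csv(path, index=False)


def read_behavior(path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise DataError(f"malformed behavior CSV {path}: {exc}") from exc
    required = {"time_s", "movement_index", "freezing"}
    if not required.issubset(frame.columns):
        raise DataError(f"behavior CSV {path} missing columns {required}")
    return frame


def write_schedule(path, schedule: ExperimentSchedule) -> None:
    rows = [
        {"event": "beep", "time_s": t, "duration_s": 0.1} for t in schedule.beep_onsets
    ]
    rows += [
        {"event": "block", "time_s": s, "duration_s": e - s}
        for s, e in schedule.block_intervals
    ]
    rows += [
        {"event": "us", "time_s": t, "duration_s": schedule.us_duration}
        for t in schedule.us_onsets
    ]
    frame = pd.DataFrame(rows).sort_values(["time_s", "event"], ignore_index=True)
    frame.attrs["day_kind"] = schedule.day_kind
    header = f"# day_kind={schedule.day_kind} session_length={schedule.session_length}\n"
    with open(path, "w") as f:
        f.write(header)
        frame.to_csv(f, index=False)


def read_schedule(path) -> ExperimentSchedule:
    with open(path) as f:
        header = f.readline()
        if not header.startswith("#"):
            raise DataError(f"schedule CSV {path} lacks its metadata header")
        meta = dict(item.split("=") for item in header[1:].split())
        frame = pd.read_csv(f)
    blocks = frame[frame["event"] == "block"]
    return ExperimentSchedule(
        day_kind=meta["day_kind"],
        beep_onsets=frame.loc[frame["event"] == "beep", "time_s"].to_numpy(),
        block_intervals=[
            (row.time_s, row.time_s + row.duration_s) for row in blocks.itertuples()
        ],
        us_onsets=frame.loc[frame["event"] == "us", "time_s"].to_numpy(),
        us_duration=1.0,
        session_length=float(meta["session_length"]),
    )


def write_json(path, payload: Any) -> None:
    def convert(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serialisable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=convert))


def read_json(path) -> Any:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise DataError(f"malformed JSON {path}: {exc}") from exc


def read_config(path) -> dict:
    try:
        config = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise DataError(f"malformed YAML config {path}: {exc}") from exc
    if not isinstance(config, dict):
        raise DataError(f"config {path} must be a mapping")
    if "seed" not in config:
        raise DataError("config must set an explicit seed")
    return config


def write_config(path, config: dict) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))
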