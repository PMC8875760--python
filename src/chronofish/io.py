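"""Readers and writers for the pipeline's plain-text tabular formats.

Formats (all comma-separated CSV with a header row, '.' decimals, UTF-8;
metadata in leading ``# key: value`` comment lines):

* tracking CSV — long-format locomotor table emulating a video-tracker
  export: ``subject_id, group_label, bin_start_h, distance_cm``, with
  ``bin_min``, ``t0_ref`` and the lighting schedule in the header.
* velocity CSV — ``subject_id, time_s, velocity_cm_s`` at uniform sampling.
* plate CSV — per-well bioluminescence counts emulating a plate-counter
  export: ``well_id, time_h, counts`` with ``sample_min`` and ``dd_onset_h``.

Readers validate hard: uniform bins, no gaps or duplicates, nonnegative
distances/velocities — a malformed file is an error (naming the subject and
row), never silently repaired.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ActivityTrace, LumTrace, VelocityTrace
from .schedule import LightSchedule

__all__ = [
    "write_tracking_csv",
    "read_tracking_csv",
    "write_velocity_csv",
    "read_velocity_csv",
    "write_plate_csv",
    "read_plate_csv",
    "write_truth_json",
]


def _write_with_metadata(path, meta: dict, df: pd.DataFrame) -> None:
    with open(path, "w", newline="") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def _read_metadata(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
    return meta


def _require(meta: dict, key: str, path) -> str:
    if key not in meta:
        raise ValueError(f"{path}: missing '# {key}:' metadata line")
    return meta[key]


def write_tracking_csv(traces: list[ActivityTrace], path) -> None:
    if not traces:
        raise ValueError("no traces to write")
    first = traces[0]
    rows = []
    for tr in traces:
        if tr.bin_min != first.bin_min:
            raise ValueError("all traces in one file must share bin_min")
        for t, v in zip(tr.times_h, tr.values):
            rows.append((tr.subject_id, tr.group_label, t, v))
    df = pd.DataFrame(rows, columns=["subject_id", "group_label", "bin_start_h", "distance_cm"])
    meta = {
        "format": "chronofish tracking v1",
        "bin_min": first.bin_min,
        "t0_ref": first.t0_ref,
        "schedule": first.schedule.to_json(),
    }
    _write_with_metadata(path, meta, df)


def read_tracking_csv(path) -> list[ActivityTrace]:
    meta = _read_metadata(path)
    bin_min = float(_require(meta, "bin_min", path))
    t0_ref = _require(meta, "t0_ref", path)
    schedule = LightSchedule.from_json(_require(meta, "schedule", path))
    df = pd.read_csv(path, comment="#")
    required = {"subject_id", "group_label", "bin_start_h", "distance_cm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bin_h = bin_min / 60.0
    traces = []
    for subject_id, sub in df.groupby("subject_id", sort=False):
        t = sub["bin_start_h"].to_numpy(dtype=float)
        v = sub["distance_cm"].to_numpy(dtype=float)
        expected = np.arange(t.size) * bin_h
        if not np.allclose(t, expected, atol=1e-6):
            bad = int(np.argmax(~np.isclose(t, expected, atol=1e-6)))
            row = int(sub.index[bad]) + 2  # header + 1-based
            raise ValueError(
                f"{path}: subject {subject_id!r} has a gap or duplicate at "
                f"bin {bad} (file row ~{row})"
            )
        if np.any(v < 0):
            bad = int(np.argmax(v < 0))
            row = int(sub.index[bad]) + 2
            raise ValueError(
                f"{path}: subject {subject_id!r} has negative distance at file row ~{row}"
            )
        groups = sub["group_label"].unique()
        traces.append(
            ActivityTrace(
                subject_id=str(subject_id),
                group_label=str(groups[0]),
                bin_min=bin_min,
                values=v,
                schedule=schedule,
                t0_ref=t0_ref,
            )
        )
    return traces


def write_velocity_csv(traces: list[VelocityTrace], path) -> None:
    if not traces:
        raise ValueError("no traces to write")
    first = traces[0]
    rows = []
    for tr in traces:
        times_s = np.arange(tr.values.size) * tr.sample_s
        for t, v in zip(times_s, tr.values):
            rows.append((tr.subject_id, t, v))
    df = pd.DataFrame(rows, columns=["subject_id", "time_s", "velocity_cm_s"])
    meta = {
        "format": "chronofish velocity v1",
        "sample_s": first.sample_s,
        "schedule": first.schedule.to_json(),
    }
    _write_with_metadata(path, meta, df)


def read_velocity_csv(path) -> list[VelocityTrace]:
    meta = _read_metadata(path)
    sample_s = float(_require(meta, "sample_s", path))
    schedule = LightSchedule.from_json(_require(meta, "schedule", path))
    df = pd.read_csv(path, comment="#")
    required = {"subject_id", "time_s", "velocity_cm_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    traces = []
    for subject_id, sub in df.groupby("subject_id", sort=False):
        t = sub["time_s"].to_numpy(dtype=float)
        v = sub["velocity_cm_s"].to_numpy(dtype=float)
        expected = np.arange(t.size) * sample_s
        if not np.allclose(t, expected, atol=1e-6):
            raise ValueError(f"{path}: subject {subject_id!r} has nonuniform sampling")
        if np.any(v < 0):
            bad = int(np.argmax(v < 0))
            row = int(sub.index[bad]) + 2
            raise ValueError(
                f"{path}: subject {subject_id!r} has negative velocity at file row ~{row}"
            )
        traces.append(
            VelocityTrace(
                subject_id=str(subject_id), sample_s=sample_s, values=v, schedule=schedule
            )
        )
    return traces


def write_plate_csv(wells: list[LumTrace], path) -> None:
    if not wells:
        raise ValueError("no wells to write")
    first = wells[0]
    rows = []
    for well in wells:
        for t, v in zip(well.times_h, well.values):
            rows.append((well.well_id, t, v))
    df = pd.DataFrame(rows, columns=["well_id", "time_h", "counts"])
    meta = {
        "format": "chronofish plate v1",
        "sample_min": first.sample_min,
        "dd_onset_h": first.dd_onset_h,
        "schedule": first.schedule.to_json(),
    }
    _write_with_metadata(path, meta, df)


def read_plate_csv(path) -> list[LumTrace]:
    meta = _read_metadata(path)
    sample_min = float(_require(meta, "sample_min", path))
    dd_onset_h = float(_require(meta, "dd_onset_h", path))
    schedule = LightSchedule.from_json(_require(meta, "schedule", path))
    df = pd.read_csv(path, comment="#")
    required = {"well_id", "time_h", "counts"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    wells = []
    for well_id, sub in df.groupby("well_id", sort=False):
        t = sub["time_h"].to_numpy(dtype=float)
        v = sub["counts"].to_numpy(dtype=float)
        expected = np.arange(t.size) * (sample_min / 60.0)
        if not np.allclose(t, expected, atol=1e-6):
            raise ValueError(f"{path}: well {well_id!r} has a gap or nonuniform sampling")
        wells.append(
            LumTrace(
                well_id=str(well_id),
                sample_min=sample_min,
                values=v,
                schedule=schedule,
                dd_onset_h=dd_onset_h,
            )
        )
    return wells


def write_truth_json(traces, path) -> None:
    """Sidecar JSON of simulator ground-truth parameters, keyed by id."""
    out = {}
    for tr in traces:
        key = getattr(tr, "subject_id", None) or getattr(tr, "well_id")
        out[key] = tr.truth
    Path(path).write_text(json.dumps(out, indent=2))
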