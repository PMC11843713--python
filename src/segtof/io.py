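"""Persisted table schemas, waveform container and run manifests.

Unit convention across all files: times ps, energies keV, charges mV*ps,
voltages mV.  Event tables are CSV with a fixed column set
(:data:`segtof.pipeline.EVENT_COLUMNS`); arrival tables are CSV with one
row per detected photon; waveforms go into an HDF5 container.  Every run
writes a JSON manifest recording configs, seeds and per-stage event
counts, so outputs are traceable and bit-for-bit reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .events import ORIGIN_NAMES, EmissionEvent
from .pipeline import EVENT_COLUMNS
from .waveform import Waveform

__all__ = [
    "write_event_table",
    "read_event_table",
    "validate_event_table",
    "write_arrival_tables",
    "read_arrival_tables",
    "write_waveforms",
    "read_waveforms",
    "write_manifest",
    "read_manifest",
]

_FLOAT_FORMAT = "%.6f"
ARRIVAL_COLUMNS = ["event_id", "pixel", "time_ps", "origin_tag"]
EVENTS_META_COLUMNS = [
    "event_id",
    "energy_kev",
    "interaction_time_ps",
    "reference_timestamp_ps",
]


def write_event_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write an event-record table as CSV (stable float formatting, so
    write -> read -> write is byte-identical)."""
    validate_event_table(df)
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_event_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_event_table(df)
    return df


def validate_event_table(df: pd.DataFrame) -> None:
    """Raise with the missing column names if the schema is incomplete."""
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table is missing columns: {', '.join(missing)}")


def write_arrival_tables(
    events: list[EmissionEvent], arrivals_path: str | Path, events_path: str | Path
) -> None:
    """Write the per-photon arrival table and the per-event metadata table."""
    rows = []
    for ev in events:
        for pixel, times, origins in (
            ("A", ev.arrivals_a, ev.origins_a),
            ("B", ev.arrivals_b, ev.origins_b),
        ):
            for t, o in zip(times, origins):
                rows.append(
                    {
                        "event_id": ev.event_id,
                        "pixel": pixel,
                        "time_ps": t,
                        "origin_tag": ORIGIN_NAMES[int(o)],
                    }
                )
    pd.DataFrame(rows, columns=ARRIVAL_COLUMNS).to_csv(
        arrivals_path, index=False, float_format=_FLOAT_FORMAT
    )
    meta = pd.DataFrame(
        [
            {
                "event_id": ev.event_id,
                "energy_kev": ev.deposited_energy_kev,
                "interaction_time_ps": ev.interaction_time_ps,
                "reference_timestamp_ps": ev.reference_timestamp_ps,
            }
            for ev in events
        ],
        columns=EVENTS_META_COLUMNS,
    )
    meta.to_csv(events_path, index=False, float_format=_FLOAT_FORMAT)


def read_arrival_tables(
    arrivals_path: str | Path, events_path: str | Path
) -> list[EmissionEvent]:
    """Rebuild EmissionEvents from the two CSV tables."""
    name_to_code = {v: k for k, v in ORIGIN_NAMES.items()}
    arr = pd.read_csv(arrivals_path)
    meta = pd.read_csv(events_path)
    grouped = dict(tuple(arr.groupby("event_id"))) if len(arr) else {}
    events = []
    for _, row in meta.iterrows():
        g = grouped.get(row["event_id"])
        parts = {"A": (np.empty(0), []), "B": (np.empty(0), [])}
        if g is not None:
            for pixel in ("A", "B"):
                sub = g[g["pixel"] == pixel]
                parts[pixel] = (
                    sub["time_ps"].to_numpy(float),
                    [name_to_code[o] for o in sub["origin_tag"]],
                )
        events.append(
            EmissionEvent(
                event_id=int(row["event_id"]),
                deposited_energy_kev=float(row["energy_kev"]),
                interaction_time_ps=float(row["interaction_time_ps"]),
                arrivals_a=parts["A"][0],
                arrivals_b=parts["B"][0],
                origins_a=np.asarray(parts["A"][1], dtype=np.int8),
                origins_b=np.asarray(parts["B"][1], dtype=np.int8),
                reference_timestamp_ps=float(row["reference_timestamp_ps"]),
            )
        )
    return events


def write_waveforms(
    waveforms: dict[tuple[int, str], Waveform], path: str | Path
) -> None:
    """Store waveforms in an HDF5 container keyed by (event_id, pixel)."""
    with h5py.File(path, "w") as f:
        for (event_id, pixel), w in waveforms.items():
            g = f.create_group(f"event_{event_id:08d}/{pixel}")
            g.attrs["event_id"] = event_id
            g.attrs["pixel"] = pixel
            g.attrs["t0_ps"] = w.t0
            g.attrs["dt_ps"] = w.dt
            g.create_dataset("samples_mV", data=w.samples)


def read_waveforms(path: str | Path) -> dict[tuple[int, str], Waveform]:
    out: dict[tuple[int, str], Waveform] = {}
    with h5py.File(path, "r") as f:
        for ev_key in f:
            for pixel in f[ev_key]:
                g = f[ev_key][pixel]
                out[(int(g.attrs["event_id"]), str(g.attrs["pixel"]))] = Waveform(
                    t0=float(g.attrs["t0_ps"]),
                    dt=float(g.attrs["dt_ps"]),
                    samples=g["samples_mV"][()],
                )
    return out


def write_manifest(path: str | Path, **entries) -> None:
    """Write a JSON run manifest (configs, seeds, stage counts, paths)."""
    doc = {}
    for key, value in entries.items():
        if dataclasses.is_dataclass(value) and not isinstance(value, type):
            value = dataclasses.asdict(value)
        doc[key] = value
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True, default=str) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
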