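"""File I/O and unit handling.

Native formats are plain CSV:

* signal CSV — columns ``sample``, ``time_s`` (both optional) and
  ``gyro_y_rad_s`` or ``gyro_y_deg_s`` (required, deg converted on load);
* events CSV — ``side,event,sample_index,time_s,emitted_at_index``.

A minimal XML dialect with per-frame foot-contact flags is also accepted
as a reference-event source (motion-capture suites export foot contacts
this way): contact onsets become FS events, offsets become FO events.
The dialect is a documented approximation, not any vendor's schema:

    <footContacts sampling_rate="100" side="left">
      <frame index="0" contact="0"/> ...
    </footContacts>
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .core import EVENT_KINDS, EventLog, GaitEvent, GyroSeries

__all__ = [
    "SchemaError",
    "SamplingError",
    "read_gyro_csv",
    "write_gyro_csv",
    "read_events_csv",
    "write_events_csv",
    "read_reference_events",
    "read_foot_contact_xml",
]

GYRO_RAD_COL = "gyro_y_rad_s"
GYRO_DEG_COL = "gyro_y_deg_s"


class SchemaError(ValueError):
    """Input file does not match the expected column schema."""


class SamplingError(ValueError):
    """Timestamps are inconsistent with uniform sampling at the stated rate."""


def read_gyro_csv(
    path: str | Path,
    sampling_rate: float = 100.0,
    units: str | None = None,
    side: str = "",
) -> GyroSeries:
    """Load a single-channel angular-velocity CSV as a rad/s series.

    ``units`` may be ``"rad"`` or ``"deg"``; if omitted it is inferred
    from which gyro column is present.  A ``time_s`` column, when present,
    is checked for uniformity within 1% of 1/sampling_rate; a ``sample``
    column must count 0, 1, 2, …
    """
    path = Path(path)
    df = pd.read_csv(path)
    if units not in (None, "rad", "deg"):
        raise ValueError("units must be 'rad' or 'deg'")
    col = None
    if units in (None, "rad") and GYRO_RAD_COL in df.columns:
        col, scale = GYRO_RAD_COL, 1.0
    elif units in (None, "deg") and GYRO_DEG_COL in df.columns:
        col, scale = GYRO_DEG_COL, math.pi / 180.0
    if col is None:
        raise SchemaError(
            f"{path.name}: no gyro column found (expected {GYRO_RAD_COL} or "
            f"{GYRO_DEG_COL}, columns are {list(df.columns)})"
        )
    values = pd.to_numeric(df[col], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(values.to_numpy()))
    if bad.size:
        raise SchemaError(
            f"{path.name}: non-finite gyro values at rows {bad[:10].tolist()}"
            + ("…" if bad.size > 10 else "")
        )
    if "sample" in df.columns:
        expected = np.arange(len(df))
        if not np.array_equal(df["sample"].to_numpy(), expected):
            raise SamplingError(f"{path.name}: 'sample' column is not 0,1,2,…")
    if "time_s" in df.columns and len(df) > 1:
        dt = np.diff(df["time_s"].to_numpy(dtype=float))
        nominal = 1.0 / sampling_rate
        if np.any(np.abs(dt - nominal) > 0.01 * nominal):
            raise SamplingError(
                f"{path.name}: timestamps deviate >1% from uniform "
                f"{nominal:.6f} s spacing"
            )
    return GyroSeries(
        samples=values.to_numpy(dtype=float) * scale,
        sampling_rate=sampling_rate,
        side=side,
        source={"path": str(path), "units": "rad" if scale == 1.0 else "deg"},
    )


def write_gyro_csv(series: GyroSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample": np.arange(len(series)),
            "time_s": np.round(series.times, 6),
            GYRO_RAD_COL: series.samples,
        }
    )
    df.to_csv(path, index=False)


def write_events_csv(log: EventLog, path: str | Path) -> None:
    log.to_dataframe().to_csv(path, index=False)


def read_events_csv(path: str | Path, sampling_rate: float = 100.0) -> EventLog:
    """Read an events CSV in the standard schema into an EventLog."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path.name}: empty events file", stacklevel=2)
        return EventLog(side="", sampling_rate=sampling_rate)
    required = {"event", "sample_index"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path.name}: events CSV needs columns {sorted(required)}")
    bad_kinds = set(df["event"]) - set(EVENT_KINDS)
    if bad_kinds:
        raise SchemaError(f"{path.name}: unknown event kinds {sorted(bad_kinds)}")
    side = str(df["side"].iloc[0]) if "side" in df.columns and len(df) else ""
    log = EventLog(side=side, sampling_rate=sampling_rate)
    for _, row in df.iterrows():
        idx = int(row["sample_index"])
        t = float(row["time_s"]) if "time_s" in df.columns else idx / sampling_rate
        emit = int(row["emitted_at_index"]) if "emitted_at_index" in df.columns else idx
        log.append(
            GaitEvent(
                kind=str(row["event"]), sample_index=idx, time_s=t,
                side=str(row.get("side", side)), emitted_at_index=emit,
            )
        )
    if any(
        b.sample_index < a.sample_index for a, b in zip(log.events, log.events[1:])
    ):
        warnings.warn(f"{path.name}: events out of order; sorting", stacklevel=2)
        log.sort()
    return log


def read_foot_contact_xml(path: str | Path) -> EventLog:
    """Convert a per-frame foot-contact flag stream to FS/FO edge events.

    A 0→1 transition of the contact flag is a foot strike; 1→0 is a foot
    off.  The event index is the first frame of the new contact state.
    """
    path = Path(path)
    tree = etree.parse(str(path))
    root = tree.getroot()
    if root.tag != "footContacts":
        raise SchemaError(f"{path.name}: expected <footContacts> root, got <{root.tag}>")
    rate = float(root.get("sampling_rate", "100"))
    side = root.get("side", "")
    frames = sorted(
        ((int(f.get("index")), int(f.get("contact"))) for f in root.iter("frame")),
        key=lambda p: p[0],
    )
    log = EventLog(side=side, sampling_rate=rate)
    for (i0, c0), (i1, c1) in zip(frames, frames[1:]):
        if c0 == 0 and c1 == 1:
            log.append(GaitEvent("FS", i1, i1 / rate, side))
        elif c0 == 1 and c1 == 0:
            log.append(GaitEvent("FO", i1, i1 / rate, side))
    if not frames:
        warnings.warn(f"{path.name}: no frames in foot-contact file", stacklevel=2)
    return log


def read_reference_events(path: str | Path, sampling_rate: float = 100.0) -> EventLog:
    """Read reference events from an events CSV or a foot-contact XML."""
    path = Path(path)
    if path.suffix.lower() == ".xml":
        return read_foot_contact_xml(path)
    if path.suffix.lower() in (".csv", ".txt"):
        return read_events_csv(path, sampling_rate)
    raise SchemaError(f"{path.name}: unknown reference format {path.suffix!r}")
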