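"""Reading and writing CGM traces.

Two external dialects are supported: a two-column CSV
(``timestamp,glucose_mg_dl``, blank value = missing reading) and the
OhioT1DM-style XML dialect, where a ``glucose_level`` element holds ``event``
children with ``ts`` (``dd-mm-yyyy hh:mm:ss``) and ``value`` (mg/dL)
attributes.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .series import GlucoseSeries

logger = logging.getLogger(__name__)

CSV_HEADER = "timestamp,glucose_mg_dl"
OHIO_TS_FORMAT = "%d-%m-%Y %H:%M:%S"


class FormatError(ValueError):
    """Malformed input file."""


def write_cgm_csv(series: GlucoseSeries, path) -> None:
    """Write a series as UTF-8 CSV; missing readings become blank fields."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(CSV_HEADER + "\n")
        for ts, v in series.data.items():
            field = "" if np.isnan(v) else repr(float(v))
            fh.write(f"{ts.isoformat()},{field}\n")


def read_cgm_csv(path, *, patient_id: str | None = None, role: str = "train") -> GlucoseSeries:
    """Read a two-column CSV into a :class:`GlucoseSeries`.

    Raises :class:`FormatError` naming the 1-based line number of any
    unparseable row.
    """
    path = Path(path)
    timestamps, values = [], []
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    start = 1 if lines[0].lstrip("﻿").startswith("timestamp") else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
        ts_text, v_text = parts
        try:
            ts = pd.Timestamp(ts_text)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}:{lineno}: bad timestamp {ts_text!r}") from exc
        if v_text.strip() == "":
            v = np.nan
        else:
            try:
                v = float(v_text)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad value {v_text!r}") from exc
        timestamps.append(ts)
        values.append(v)
    if not timestamps:
        raise FormatError(f"{path}: no data rows")
    data = pd.Series(values, index=pd.DatetimeIndex(timestamps))
    return GlucoseSeries(data=data, patient_id=patient_id or path.stem, role=role)


def read_ohio_xml(path, *, role: str = "train") -> GlucoseSeries:
    """Read CGM events from an OhioT1DM-style XML file.

    Events are returned in timestamp order; duplicated timestamps keep the
    first occurrence (a warning is logged).
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise FormatError(f"{path}: not well-formed XML: {exc}") from exc
    root = tree.getroot()
    glucose = root if root.tag == "glucose_level" else root.find(".//glucose_level")
    if glucose is None:
        raise FormatError(f"{path}: no <glucose_level> element")
    patient_id = root.get("id") or path.stem

    rows = []
    for event in glucose.findall("event"):
        ts_text, v_text = event.get("ts"), event.get("value")
        if ts_text is None or v_text is None:
            raise FormatError(f"{path}: <event> missing ts/value attribute")
        try:
            ts = pd.Timestamp(pd.to_datetime(ts_text, format=OHIO_TS_FORMAT))
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: bad event timestamp {ts_text!r}") from exc
        try:
            v = float(v_text)
        except ValueError as exc:
            raise FormatError(f"{path}: bad event value {v_text!r}") from exc
        rows.append((ts, v))
    if not rows:
        raise FormatError(f"{path}: <glucose_level> holds no events")

    frame = pd.DataFrame(rows, columns=["ts", "value"]).sort_values("ts", kind="stable")
    n_dups = int(frame["ts"].duplicated().sum())
    if n_dups:
        logger.warning("%s: dropped %d duplicate-timestamp events (kept first)", path, n_dups)
        frame = frame[~frame["ts"].duplicated()]
    data = pd.Series(frame["value"].to_numpy(), index=pd.DatetimeIndex(frame["ts"]))
    return GlucoseSeries(data=data, patient_id=patient_id, role=role)
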