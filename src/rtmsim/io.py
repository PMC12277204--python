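"""Bit-exact CSV codecs for every file the artifact reads or writes.

Dialect: comma-separated, UTF-8, header row, '.' decimal; all times are
seconds from session start (no calendar timestamps). Device logs carry a
single ``#``-prefixed metadata line (key=value pairs) above the CSV header.
Every writer round-trips losslessly through its reader.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .accelerometry import DeviceLog, FormatError
from .engines import CueEvent

_FLOAT_FMT = "%.10g"


def _write_meta_line(handle, meta: dict) -> None:
    pairs = ",".join(f"{k}={v}" for k, v in meta.items())
    handle.write(f"# {pairs}\n")


def _read_meta_line(path: Path) -> tuple[dict, int]:
    """Parse the leading '#' metadata line; returns (meta, rows to skip)."""
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if not first.startswith("#"):
        return {}, 0
    meta = {}
    for pair in first[1:].strip().split(","):
        if "=" not in pair:
            raise FormatError(f"{path}:1: malformed metadata pair {pair!r}")
        k, v = pair.split("=", 1)
        meta[k.strip()] = v.strip()
    return meta, 1


def _read_csv(path: Path, required: Sequence[str], skiprows: int) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, skiprows=skiprows)
    except Exception as exc:  # malformed rows, bad column counts
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# raw 5 Hz sample streams


def write_samples_csv(path: str | Path, samples: pd.DataFrame,
                      meta: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if meta:
            _write_meta_line(fh, meta)
        samples.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_samples_csv(path: str | Path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta, skip = _read_meta_line(path)
    df = _read_csv(path, ["t_s", "ax", "ay", "az"], skip)
    t = df["t_s"].to_numpy(dtype=float)
    if t.size and (np.diff(t) <= 0).any():
        bad = int(np.argmax(np.diff(t) <= 0))
        raise FormatError(f"{path}: non-monotone time at row {bad + 2}")
    return df, meta


# ---------------------------------------------------------------------------
# epoch logs


EPOCH_COLUMNS = ["day", "epoch_index", "counts_x", "counts_y", "counts_z",
                 "counts_mag", "moved"]


def write_epoch_log(path: str | Path, log: DeviceLog) -> None:
    path = Path(path)
    df = log.epochs.copy()
    df.insert(0, "day", log.day)
    df["moved"] = df["moved"].astype(int)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        _write_meta_line(
            fh,
            {
                "subject_id": log.subject_id,
                "group": log.group,
                "fthue_level": log.fthue_level,
                "threshold": log.threshold,
                "session_hours": log.session_hours,
            },
        )
        df[EPOCH_COLUMNS].to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_epoch_log(path: str | Path) -> DeviceLog:
    path = Path(path)
    meta, skip = _read_meta_line(path)
    df = _read_csv(path, EPOCH_COLUMNS, skip)
    days = df["day"].unique()
    if len(days) != 1:
        raise FormatError(f"{path}: expected one day per epoch log, got {days}")
    idx = df["epoch_index"].to_numpy()
    if (np.diff(idx) != 1).any():
        bad = int(np.argmax(np.diff(idx) != 1))
        raise FormatError(f"{path}: non-consecutive epoch_index at row {bad + 3}")
    epochs = df.drop(columns="day").reset_index(drop=True)
    epochs["moved"] = epochs["moved"].astype(bool)
    return DeviceLog(
        subject_id=str(meta.get("subject_id", "")),
        day=int(days[0]),
        epochs=epochs,
        group=str(meta.get("group", "")),
        fthue_level=int(meta.get("fthue_level", 0)),
        threshold=float(meta.get("threshold", 1.0)),
        session_hours=float(meta.get("session_hours", 3.0)),
    )


# ---------------------------------------------------------------------------
# cue-event logs


def write_cue_log(path: str | Path, events_by_session: dict[str, Sequence[CueEvent]]) -> None:
    """Write cue events as session_id, cue_index, onset_s, ack_s, reaction_s
    (ack fields empty for never-acknowledged cues)."""
    rows = []
    for session_id, events in events_by_session.items():
        for i, ev in enumerate(events):
            rows.append(
                {
                    "session_id": session_id,
                    "cue_index": i,
                    "onset_s": ev.onset_s,
                    "ack_s": "" if ev.ack_s is None else ev.ack_s,
                    "reaction_s": "" if ev.reaction_s is None else ev.reaction_s,
                }
            )
    pd.DataFrame(
        rows, columns=["session_id", "cue_index", "onset_s", "ack_s", "reaction_s"]
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_cue_log(path: str | Path) -> dict[str, list[CueEvent]]:
    path = Path(path)
    df = _read_csv(path, ["session_id", "cue_index", "onset_s", "ack_s"], 0)
    out: dict[str, list[CueEvent]] = {}
    for _, row in df.iterrows():
        ack = row["ack_s"]
        ack_s = None if (pd.isna(ack) or ack == "") else float(ack)
        ev = CueEvent(onset_s=float(row["onset_s"]), ack_s=ack_s)
        out.setdefault(str(row["session_id"]), []).append(ev)
    for session_id, events in out.items():
        onsets = [e.onset_s for e in events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise FormatError(f"{path}: non-increasing onsets in {session_id}")
    return out


# ---------------------------------------------------------------------------
# outcome tables and reports


OUTCOME_COLUMNS = ["subject_id", "group", "fthue_level", "age",
                   "onset_months", "timepoint", "measure", "value"]


def write_outcome_table(path: str | Path, table: pd.DataFrame) -> None:
    table[OUTCOME_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_outcome_table(path: str | Path) -> pd.DataFrame:
    return _read_csv(Path(path), OUTCOME_COLUMNS, 0)


def write_daily_counts(path: str | Path, counts: pd.DataFrame) -> None:
    counts[["subject_id", "group", "day", "count"]].to_csv(path, index=False)


def read_daily_counts(path: str | Path) -> pd.DataFrame:
    return _read_csv(Path(path), ["subject_id", "group", "day", "count"], 0)


def write_json(path: str | Path, payload: dict) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
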